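"""Peptide-to-residue consolidation and structural annotation.

Converts peptide-level classifications into a per-residue map with four
labels — ``positive`` (more deuteration in the variant), ``negative``,
``none`` (covered but not significant), ``no_coverage`` — and writes the
binary color scheme into the B-factor column of a PDB so any molecular
viewer can render the differential map.  Also prepares Woods-plot tables
(per-peptide summed ΔHDX against sequence position with the global
confidence threshold as horizontal lines).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser, PDBIO

from .errors import FormatError, MappingError, ValidationError
from .stats import Classification

logger = logging.getLogger(__name__)

RESIDUE_LABELS = ("positive", "negative", "none", "no_coverage")

#: B-factor codes of the binary color scheme
BFACTOR_CODES = {
    "positive": 1.00,
    "negative": -1.00,
    "none": 0.00,
    "no_coverage": 99.00,
}
_CODE_TO_LABEL = {round(v, 2): k for k, v in BFACTOR_CODES.items()}


@dataclass
class ResidueClassificationMap:
    """Per-residue labels for residues 1..protein_length, with the
    supporting peptide counts per class and any majority-rule conflicts."""

    protein_length: int
    labels: tuple[str, ...]
    counts: dict[str, np.ndarray] = field(repr=False)
    conflicts: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if len(self.labels) != self.protein_length:
            raise ValidationError("labels must cover every residue")
        if any(l not in RESIDUE_LABELS for l in self.labels):
            raise ValidationError(f"labels must be in {RESIDUE_LABELS}")

    def label(self, residue: int) -> str:
        """Label of a 1-based residue index."""
        if not 1 <= residue <= self.protein_length:
            raise ValidationError(f"residue {residue} outside 1-{self.protein_length}")
        return self.labels[residue - 1]

    def summary(self) -> dict[str, int]:
        out = {l: 0 for l in RESIDUE_LABELS}
        for l in self.labels:
            out[l] += 1
        return out


def consolidate_to_residues(
    records, protein_length: int
) -> ResidueClassificationMap:
    """Collapse peptide classifications onto residues.

    A residue covered only by significant peptides of one sign takes that
    sign; conflicting coverage is resolved by majority among significant
    peptides (ties → ``none``, logged); coverage only by non-significant
    peptides → ``none``; no coverage at all → ``no_coverage``.
    Idempotent and order-invariant in the record list.
    """
    counts = {c.value: np.zeros(protein_length, dtype=int)
              for c in Classification}
    for r in records:
        if r.peptide.start < 1 or r.peptide.end > protein_length:
            raise ValidationError(
                f"peptide span {r.peptide.start}-{r.peptide.end} outside "
                f"1-{protein_length}"
            )
        counts[r.classification.value][r.peptide.start - 1: r.peptide.end] += 1
    labels: list[str] = []
    conflicts: list[int] = []
    for i in range(protein_length):
        pos, neg, non = counts["positive"][i], counts["negative"][i], counts["none"][i]
        if pos == neg == non == 0:
            labels.append("no_coverage")
        elif pos > neg:
            labels.append("positive")
        elif neg > pos:
            labels.append("negative")
        elif pos == neg > 0:
            labels.append("none")
            conflicts.append(i + 1)
        else:
            labels.append("none")
    if conflicts:
        logger.warning(
            "conflicting positive/negative coverage at residues %s "
            "(tie resolved to 'none')", conflicts,
        )
    return ResidueClassificationMap(
        protein_length=protein_length,
        labels=tuple(labels),
        counts=counts,
        conflicts=tuple(conflicts),
    )


def woods_plot_data(records, thresholds) -> pd.DataFrame:
    """Woods-plot table: one row per peptide (start, end, summed ΔHDX,
    class); the symmetric threshold is stored in a ``summed_ci`` column
    (the plot's horizontal lines) and in ``df.attrs``."""
    rows = [
        {
            "start": r.peptide.start,
            "end": r.peptide.end,
            "sequence": r.peptide.sequence,
            "summed_delta": r.summed_delta,
            "classification": r.classification.value,
            "summed_ci": thresholds.summed_ci,
        }
        for r in records
    ]
    df = pd.DataFrame(
        rows,
        columns=["start", "end", "sequence", "summed_delta",
                 "classification", "summed_ci"],
    )
    df.attrs["summed_ci"] = thresholds.summed_ci
    df.attrs["alpha"] = thresholds.alpha
    return df


def plot_woods(df: pd.DataFrame, ax=None, *, graded: bool = False):
    """Render a Woods plot (thin optional layer over the table).

    Each peptide is a horizontal segment at its summed ΔHDX; dashed lines
    mark ±summed CI.  ``graded=True`` colors by magnitude instead of the
    binary scheme (diagnostics only).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    ci = float(df["summed_ci"].iloc[0]) if len(df) else 0.0
    binary = {"positive": "red", "negative": "blue", "none": "0.6"}
    if graded and len(df):
        vmax = float(df["summed_delta"].abs().max()) or 1.0
        cmap = plt.get_cmap("coolwarm")
    for _, row in df.iterrows():
        if graded:
            color = cmap(0.5 + row["summed_delta"] / (2 * vmax))
        else:
            color = binary[row["classification"]]
        ax.plot([row["start"], row["end"]],
                [row["summed_delta"]] * 2, color=color, lw=2)
    ax.axhline(ci, ls="--", color="k", lw=0.8)
    ax.axhline(-ci, ls="--", color="k", lw=0.8)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("residue")
    ax.set_ylabel("summed ΔHDX (Da)")
    return ax


def write_woods_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.12g",
              lineterminator="\n")


# ----------------------------------------------------------------------
# PDB annotation

def write_structure_annotation(
    rmap: ResidueClassificationMap,
    pdb_in,
    pdb_out,
    *,
    tsv_out=None,
    chain_id: str | None = None,
    residue_offset: int = 0,
    strict: bool = False,
) -> pd.DataFrame:
    """Write the residue map into the B-factor column of a PDB.

    Codes: positive → 1.00, negative → −1.00, none → 0.00,
    no_coverage → 99.00 (PDB fixed-width %6.2f convention, so the output
    is byte-identical across runs).  The map residue number of a PDB
    residue is its author number plus ``residue_offset``; residues
    falling outside the map get ``no_coverage`` (or raise, if
    ``strict``).  Returns (and optionally writes) the per-residue TSV
    mirroring the codes.
    """
    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure("hdx", str(pdb_in))
    except Exception as exc:
        raise FormatError(f"unreadable PDB {pdb_in}: {exc}") from exc
    unmatched: list[int] = []
    rows: list[dict] = []
    n_matched = 0
    for model in structure:
        for chain in model:
            if chain_id is not None and chain.id != chain_id:
                continue
            for residue in chain:
                het, resseq, _ = residue.id
                if het.strip():
                    continue  # skip waters/ligands
                mapped = resseq + residue_offset
                if 1 <= mapped <= rmap.protein_length:
                    label = rmap.label(mapped)
                    n_matched += 1
                else:
                    label = "no_coverage"
                    unmatched.append(resseq)
                code = BFACTOR_CODES[label]
                for atom in residue:
                    atom.set_bfactor(code)
                if model.id == 0:
                    rows.append({
                        "chain": chain.id,
                        "pdb_residue": resseq,
                        "map_residue": mapped,
                        "label": label,
                        "bfactor_code": "%.2f" % code,
                    })
    if not rows:
        raise MappingError("no polymer residues matched the selection")
    if unmatched:
        msg = (f"{len(unmatched)} PDB residue(s) outside the map after "
               f"offset {residue_offset:+d}: {sorted(set(unmatched))}")
        if strict or n_matched == 0:
            raise MappingError(msg)
        logger.warning("%s; coded as no_coverage", msg)
    io = PDBIO()
    io.set_structure(structure)
    io.save(str(pdb_out))
    df = pd.DataFrame(rows)
    if tsv_out is not None:
        df.to_csv(tsv_out, sep="\t", index=False, lineterminator="\n")
    return df


def read_annotation_codes(pdb_path, chain_id: str | None = None) -> dict[int, str]:
    """Read back per-residue labels from an annotated PDB's B-factors
    (first atom of each residue)."""
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("hdx", str(pdb_path))
    out: dict[int, str] = {}
    model = next(iter(structure))
    for chain in model:
        if chain_id is not None and chain.id != chain_id:
            continue
        for residue in chain:
            het, resseq, _ = residue.id
            if het.strip():
                continue
            code = round(next(iter(residue)).get_bfactor(), 2)
            label = _CODE_TO_LABEL.get(code)
            if label is None:
                raise MappingError(
                    f"unrecognized B-factor code {code} at residue {resseq}"
                )
            out[resseq] = label
    return out


def write_pymol_script(rmap: ResidueClassificationMap, path,
                       object_name: str = "structure") -> None:
    """Write a PyMOL coloring macro for the binary scheme: red/blue for
    positive/negative, white for none, gray for no coverage."""
    colors = {"positive": "red", "negative": "blue",
              "none": "white", "no_coverage": "gray70"}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# binary differential-HDX color scheme for {object_name}\n")
        fh.write(f"color gray70, {object_name}\n")
        for label in ("none", "negative", "positive"):
            resids = [str(i + 1) for i, l in enumerate(rmap.labels) if l == label]
            if resids:
                fh.write(
                    f"color {colors[label]}, {object_name} and resi "
                    + "+".join(resids) + "\n"
                )
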