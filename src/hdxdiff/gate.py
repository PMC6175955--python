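"""Intracellular gate-distance geometry on coordinate trajectories.

The gate metric is the center-of-mass (COM) distance between two groups
of Cα atoms flanking the cytoplasmic opening of a transporter, tracked
frame by frame.  For XylE the canonical groups are residues 75–80,
149–154, 160–165 (N-lobe) versus 332–337, 391–397, 404–410 (C-lobe); an
outward-facing-like closed intracellular gate sits near 9 Å, an
inward-open one near 13 Å.  Trajectories come in as multi-model PDB
(each MODEL a frame) or as a plain-text frames table; frame times are
taken from an explicit list or a stated frame interval, never guessed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError, SelectionError, ValidationError

logger = logging.getLogger(__name__)

#: standard atomic masses (u) for the elements found in protein backbones
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971,
}


def parse_residue_ranges(text: str) -> tuple[int, ...]:
    """Parse compact residue-range syntax, e.g. ``"75-80,149-154"``."""
    out: list[int] = []
    for part in str(text).split(","):
        part = part.strip()
        if not part:
            continue
        if "-" in part:
            a, b = part.split("-", 1)
            lo, hi = int(a), int(b)
            if hi < lo:
                raise ParameterError(f"descending residue range {part!r}")
            out.extend(range(lo, hi + 1))
        else:
            out.append(int(part))
    if not out:
        raise ParameterError(f"empty residue range {text!r}")
    return tuple(out)


@dataclass(frozen=True)
class GateDefinition:
    """Two disjoint Cα residue groups defining a gate distance."""

    group1: tuple[int, ...]
    group2: tuple[int, ...]
    atom_name: str = "CA"

    def __post_init__(self) -> None:
        g1, g2 = tuple(self.group1), tuple(self.group2)
        if not g1 or not g2:
            raise ValidationError("gate groups must be non-empty")
        if set(g1) & set(g2):
            raise ValidationError(
                f"gate groups overlap: {sorted(set(g1) & set(g2))}"
            )
        object.__setattr__(self, "group1", g1)
        object.__setattr__(self, "group2", g2)

    @classmethod
    def from_ranges(cls, group1: str, group2: str) -> "GateDefinition":
        return cls(parse_residue_ranges(group1), parse_residue_ranges(group2))


#: XylE intracellular gate (N-lobe vs C-lobe Cα groups)
XYLE_INTRACELLULAR_GATE = GateDefinition.from_ranges(
    "75-80,149-154,160-165", "332-337,391-397,404-410"
)

#: trailing window over which the gate-distance distribution is taken
DEFAULT_TRAILING_WINDOW_NS = 200.0


@dataclass
class FrameSeries:
    """A coordinate trajectory restricted to what the gate metric needs:
    positions (Å), residue ids, atom names, elements and frame times (ns)."""

    coordinates: np.ndarray      # (n_frames, n_atoms, 3), Å
    resids: np.ndarray           # (n_atoms,)
    atom_names: np.ndarray       # (n_atoms,)
    elements: np.ndarray         # (n_atoms,)
    times_ns: np.ndarray         # (n_frames,)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValidationError("coordinates must have shape (F, N, 3)")
        n = self.coordinates.shape[1]
        for name in ("resids", "atom_names", "elements"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise ValidationError(f"{name} must have length {n}")
            setattr(self, name, arr)
        self.times_ns = np.asarray(self.times_ns, dtype=float)
        if self.times_ns.shape != (self.coordinates.shape[0],):
            raise ValidationError("times_ns must have one entry per frame")
        if (np.diff(self.times_ns) < 0).any():
            raise ValidationError("frame times must be non-decreasing")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    def masses(self) -> np.ndarray:
        out = np.empty(len(self.elements), dtype=float)
        for i, el in enumerate(self.elements):
            key = str(el).strip().upper()
            if key not in ATOMIC_MASSES:
                raise ValidationError(f"no standard mass for element {el!r}")
            out[i] = ATOMIC_MASSES[key]
        return out

    # -- readers ------------------------------------------------------

    @classmethod
    def from_multimodel_pdb(
        cls,
        path,
        *,
        frame_interval_ns: float | None = None,
        times_ns=None,
    ) -> "FrameSeries":
        """Read a MODEL/ENDMDL multi-model PDB via MDAnalysis.

        Exactly one of ``frame_interval_ns`` / ``times_ns`` must be given
        (frame times are metadata PDB does not carry).
        """
        import MDAnalysis as mda

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                u = mda.Universe(str(path))
            except Exception as exc:
                raise FormatError(f"unreadable trajectory {path}: {exc}") from exc
            coords = np.stack(
                [u.atoms.positions.copy() for _ in u.trajectory]
            ).astype(float)
            resids = u.atoms.resids.copy()
            names = np.array([n.strip() for n in u.atoms.names])
            try:
                elements = np.array(
                    [e.strip() or n[0] for e, n in zip(u.atoms.elements, names)]
                )
            except Exception:
                elements = np.array([n[0] for n in names])
        n_frames = coords.shape[0]
        times = _resolve_times(n_frames, frame_interval_ns, times_ns)
        return cls(coords, resids, names, elements, times)

    @classmethod
    def from_frames_table(cls, path) -> "FrameSeries":
        """Read the documented plain-text format: a TSV with columns
        ``frame, time_ns, resid, atom_name, element, x_A, y_A, z_A``."""
        df = pd.read_csv(path, sep="\t")
        required = ["frame", "time_ns", "resid", "atom_name",
                    "element", "x_A", "y_A", "z_A"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise FormatError(f"frames table missing column(s) {missing}")
        frames = sorted(df["frame"].unique())
        first = df[df["frame"] == frames[0]].reset_index(drop=True)
        n_atoms = len(first)
        coords = np.empty((len(frames), n_atoms, 3))
        times = np.empty(len(frames))
        for k, f in enumerate(frames):
            sub = df[df["frame"] == f]
            if len(sub) != n_atoms:
                raise FormatError(
                    f"frame {f} has {len(sub)} atoms, expected {n_atoms}"
                )
            coords[k] = sub[["x_A", "y_A", "z_A"]].to_numpy(dtype=float)
            times[k] = float(sub["time_ns"].iloc[0])
        return cls(
            coords,
            first["resid"].to_numpy(dtype=int),
            first["atom_name"].astype(str).to_numpy(),
            first["element"].astype(str).to_numpy(),
            times,
        )

    def to_frames_table(self, path) -> None:
        rows = []
        for k in range(self.n_frames):
            for a in range(self.coordinates.shape[1]):
                rows.append({
                    "frame": k,
                    "time_ns": self.times_ns[k],
                    "resid": self.resids[a],
                    "atom_name": self.atom_names[a],
                    "element": self.elements[a],
                    "x_A": self.coordinates[k, a, 0],
                    "y_A": self.coordinates[k, a, 1],
                    "z_A": self.coordinates[k, a, 2],
                })
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False,
                                  float_format="%.6f", lineterminator="\n")


def _resolve_times(n_frames, frame_interval_ns, times_ns) -> np.ndarray:
    if (frame_interval_ns is None) == (times_ns is None):
        raise ParameterError(
            "frame times are never guessed: give exactly one of "
            "frame_interval_ns or times_ns"
        )
    if times_ns is not None:
        times = np.asarray(times_ns, dtype=float)
        if times.shape != (n_frames,):
            raise ParameterError(
                f"times_ns has {times.size} entries for {n_frames} frames"
            )
        return times
    if frame_interval_ns <= 0:
        raise ParameterError("frame_interval_ns must be > 0")
    return np.arange(n_frames, dtype=float) * frame_interval_ns


# ----------------------------------------------------------------------
# geometry

def center_of_mass(coordinates, masses) -> np.ndarray:
    """Mass-weighted mean position of a set of atoms (Å)."""
    xyz = np.asarray(coordinates, dtype=float)
    m = np.asarray(masses, dtype=float)
    if xyz.ndim != 2 or xyz.shape[1] != 3 or xyz.shape[0] == 0:
        raise SelectionError("empty or malformed coordinate selection")
    if m.shape != (xyz.shape[0],) or (m <= 0).any():
        raise ValidationError("masses must be positive, one per atom")
    return (m[:, None] * xyz).sum(axis=0) / m.sum()


def _gate_indices(series: FrameSeries, gate: GateDefinition):
    name_ok = np.char.strip(series.atom_names.astype(str)) == gate.atom_name
    idx = []
    for group in (gate.group1, gate.group2):
        sel = name_ok & np.isin(series.resids, group)
        present = set(series.resids[sel].tolist())
        absent = sorted(set(group) - present)
        if absent:
            raise SelectionError(
                f"residues missing a {gate.atom_name} atom: {absent}"
            )
        idx.append(np.where(sel)[0])
    return idx


def gate_distance(
    series: FrameSeries, gate: GateDefinition, frame_index: int = 0
) -> float:
    """COM distance (Å) between the two gate groups in one frame;
    invariant under rigid-body transforms of the frame."""
    i1, i2 = _gate_indices(series, gate)
    masses = series.masses()
    xyz = series.coordinates[frame_index]
    com1 = center_of_mass(xyz[i1], masses[i1])
    com2 = center_of_mass(xyz[i2], masses[i2])
    return float(np.linalg.norm(com1 - com2))


def distance_trace(series: FrameSeries, gate: GateDefinition) -> pd.DataFrame:
    """Per-frame gate distance: columns ``time_ns``, ``distance_A``."""
    i1, i2 = _gate_indices(series, gate)
    masses = series.masses()
    m1, m2 = masses[i1], masses[i2]
    com1 = (m1[None, :, None] * series.coordinates[:, i1]).sum(1) / m1.sum()
    com2 = (m2[None, :, None] * series.coordinates[:, i2]).sum(1) / m2.sum()
    dist = np.linalg.norm(com1 - com2, axis=1)
    return pd.DataFrame({"time_ns": series.times_ns, "distance_A": dist})


def trailing_distribution(
    trace: pd.DataFrame,
    window_ns: float = DEFAULT_TRAILING_WINDOW_NS,
    bins: int | str = 40,
) -> pd.DataFrame:
    """Normalized histogram of the gate distance over the trailing
    ``window_ns`` of the trace (frames with t ≥ t_end − window).

    Returns columns ``bin_left_A``, ``bin_right_A``, ``density`` with
    sum(density × width) == 1.
    """
    if trace.empty:
        raise ParameterError("empty trace")
    t = trace["time_ns"].to_numpy(dtype=float)
    span = t[-1] - t[0]
    if window_ns <= 0:
        raise ParameterError("window must be > 0")
    if window_ns > span and len(t) > 1:
        raise ParameterError(
            f"window {window_ns} ns exceeds trace span {span} ns"
        )
    sel = t >= t[-1] - window_ns
    values = trace["distance_A"].to_numpy(dtype=float)[sel]
    if values.size == 0:
        raise ParameterError("no frames inside the trailing window")
    if values.min() == values.max():
        # single-valued trace: one occupied unit-width bin
        edges = np.array([values[0] - 0.5, values[0] + 0.5])
        density = np.array([1.0])
    else:
        density, edges = np.histogram(values, bins=bins, density=True)
    return pd.DataFrame({
        "bin_left_A": edges[:-1],
        "bin_right_A": edges[1:],
        "density": density,
    })


def distribution_mode(hist: pd.DataFrame) -> float:
    """Midpoint of the highest-density bin (Å)."""
    i = int(hist["density"].to_numpy().argmax())
    return float((hist["bin_left_A"].iloc[i] + hist["bin_right_A"].iloc[i]) / 2)
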