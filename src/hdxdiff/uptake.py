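"""Peptide-level deuterium uptake data model and delimited-text I/O.

The central container is :class:`PeptideUptakeDataset`: every replicate
uptake measurement (in Da) for one protein, keyed by (peptide, state,
exposure).  Two table dialects are supported:

``cluster_csv``
    DynamX-cluster-like wide CSV, one row per replicate (or one row per
    group with ``Uptake SD``, in which case replicates are reconstructed
    as mean and mean +/- SD placeholders and flagged).  Bare exposure
    numbers are minutes, the DynamX convention.

``long_tsv``
    Tidy TSV, one row per replicate with an explicit replicate id.  Bare
    exposure numbers are seconds.

All residue numbering is 1-based inclusive; exposures are stored in
seconds internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .errors import (
    FormatError,
    IntegrityError,
    ParseError,
    ValidationError,
)

logger = logging.getLogger(__name__)

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: labeling schemes used for detergent-micelle and nanodisc experiments
DETERGENT_TIMEPOINTS_S: tuple[float, ...] = (30.0, 300.0, 1800.0)
NANODISC_TIMEPOINTS_S: tuple[float, ...] = (300.0, 1800.0, 9000.0)

#: deuterium fraction after 5 uL sample + 95 uL labeling buffer
DEFAULT_DEUTERIUM_FRACTION = 0.95

#: peptide length window applied by the standard identification filter
DEFAULT_LENGTH_FILTER: tuple[int, int] = (5, 25)


def compute_max_uptake(sequence: str) -> int:
    """Number of backbone amides of a peptide that can retain deuterium.

    The N-terminal amide back-exchanges essentially instantly and proline
    has no backbone amide hydrogen, so the count is
    ``len(sequence) - 1 - (#prolines at positions 2..len)``.

    Parameters
    ----------
    sequence:
        Peptide sequence in standard one-letter code.

    Raises
    ------
    ValidationError
        If the sequence is empty or contains a non-standard letter.
    """
    if not sequence:
        raise ValidationError("empty peptide sequence")
    bad = set(sequence) - AMINO_ACIDS
    if bad:
        raise ValidationError(
            f"unknown residue letter(s) {sorted(bad)} in sequence {sequence!r}"
        )
    return len(sequence) - 1 - sequence[1:].count("P")


@dataclass(frozen=True, order=True)
class Peptide:
    """One proteolytic peptide, located on the parent protein.

    ``start``/``end`` are 1-based inclusive residue indices; ``max_uptake``
    is the number of exchangeable backbone amides (see
    :func:`compute_max_uptake`).
    """

    protein_id: str
    start: int
    end: int
    sequence: str
    max_uptake: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValidationError(f"peptide end {self.end} < start {self.start}")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValidationError(
                f"sequence length {len(self.sequence)} does not match span "
                f"{self.start}-{self.end}"
            )
        expected = compute_max_uptake(self.sequence)
        if not 0 <= self.max_uptake <= len(self.sequence) - 1:
            raise ValidationError(
                f"max_uptake {self.max_uptake} outside [0, {len(self.sequence) - 1}]"
            )
        if self.max_uptake != expected:
            raise ValidationError(
                f"max_uptake {self.max_uptake} inconsistent with sequence "
                f"{self.sequence!r} (expected {expected})"
            )

    @classmethod
    def from_sequence(cls, protein_id: str, start: int, sequence: str) -> "Peptide":
        """Build a peptide with ``max_uptake`` derived from the sequence."""
        return cls(
            protein_id=protein_id,
            start=start,
            end=start + len(sequence) - 1,
            sequence=sequence,
            max_uptake=compute_max_uptake(sequence),
        )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def exchangeable_positions(self) -> tuple[int, ...]:
        """1-based protein residue indices contributing to uptake
        (everything except the peptide's first residue and prolines)."""
        return tuple(
            self.start + i
            for i, aa in enumerate(self.sequence)
            if i > 0 and aa != "P"
        )


@dataclass(frozen=True)
class LabelingConditions:
    """Deuteration conditions shared by a whole dataset."""

    deuterium_fraction: float = DEFAULT_DEUTERIUM_FRACTION
    timepoints: tuple[float, ...] = DETERGENT_TIMEPOINTS_S
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.deuterium_fraction <= 1:
            raise ValidationError(
                f"deuterium_fraction {self.deuterium_fraction} outside (0, 1]"
            )
        tps = tuple(float(t) for t in self.timepoints)
        if not tps or any(t <= 0 for t in tps) or any(
            b <= a for a, b in zip(tps, tps[1:])
        ):
            raise ValidationError(
                f"timepoints must be positive and strictly increasing: {tps}"
            )
        object.__setattr__(self, "timepoints", tps)
        if self.n_replicates < 2:
            raise ValidationError("n_replicates must be >= 2")

    @classmethod
    def detergent(cls, **kw) -> "LabelingConditions":
        """30 s / 5 min / 30 min scheme used in detergent micelles."""
        return cls(timepoints=DETERGENT_TIMEPOINTS_S, **kw)

    @classmethod
    def nanodisc(cls, **kw) -> "LabelingConditions":
        """5 / 30 / 150 min scheme used for lipid nanodiscs."""
        return cls(timepoints=NANODISC_TIMEPOINTS_S, **kw)


@dataclass(frozen=True)
class UptakeMeasurement:
    """Replicate deuterium uptake values (Da) for one peptide, state and
    exposure time."""

    peptide: Peptide
    state_label: str
    exposure_s: float
    replicate_values: tuple[float, ...]
    reconstructed: bool = False  # rebuilt from mean +/- SD, not raw replicates

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.replicate_values)
        if any(v < 0 for v in vals):
            raise ValidationError(
                f"negative uptake in {self.peptide.sequence} @ {self.exposure_s}s"
            )
        object.__setattr__(self, "replicate_values", vals)

    @property
    def mean(self) -> float:
        return sum(self.replicate_values) / len(self.replicate_values)


class PeptideUptakeDataset:
    """All uptake measurements for one protein under one labeling scheme.

    Measurements are keyed by ``(peptide, state_label, exposure_s)``.
    Groups whose replicate count differs from
    ``conditions.n_replicates`` are retained but reported by
    :meth:`incomplete_keys`; downstream statistics skip them with a
    logged warning.
    """

    #: slack on the physical upper bound max_uptake * D to absorb noise
    NOISE_TOLERANCE = 0.15

    def __init__(self, conditions: LabelingConditions):
        self.conditions = conditions
        self._measurements: dict[tuple[Peptide, str, float], UptakeMeasurement] = {}

    # -- construction -------------------------------------------------

    def add(self, measurement: UptakeMeasurement) -> None:
        key = (measurement.peptide, measurement.state_label, measurement.exposure_s)
        if key in self._measurements:
            raise IntegrityError(
                f"duplicate measurement for {measurement.peptide.sequence} "
                f"state={measurement.state_label} exposure={measurement.exposure_s}s"
            )
        self._measurements[key] = measurement

    # -- access -------------------------------------------------------

    def __len__(self) -> int:
        return len(self._measurements)

    def __iter__(self):
        return iter(sorted(self._measurements.values(),
                           key=lambda m: (m.peptide, m.state_label, m.exposure_s)))

    def get(self, peptide: Peptide, state: str, exposure_s: float) -> UptakeMeasurement:
        try:
            return self._measurements[(peptide, state, float(exposure_s))]
        except KeyError:
            raise KeyError(
                f"no measurement for {peptide.sequence} / {state} / {exposure_s}s"
            ) from None

    def has(self, peptide: Peptide, state: str, exposure_s: float) -> bool:
        return (peptide, state, float(exposure_s)) in self._measurements

    @property
    def states(self) -> tuple[str, ...]:
        return tuple(sorted({k[1] for k in self._measurements}))

    def peptides(self, state: str | None = None) -> tuple[Peptide, ...]:
        peps = {
            k[0]
            for k in self._measurements
            if state is None or k[1] == state
        }
        return tuple(sorted(peps))

    def incomplete_keys(self) -> list[tuple[Peptide, str, float]]:
        n = self.conditions.n_replicates
        return sorted(
            (k for k, m in self._measurements.items()
             if len(m.replicate_values) != n),
            key=lambda k: (k[0], k[1], k[2]),
        )

    def is_complete(self, peptide: Peptide, state: str) -> bool:
        """True iff every timepoint is present with a full replicate set."""
        n = self.conditions.n_replicates
        for t in self.conditions.timepoints:
            key = (peptide, state, t)
            m = self._measurements.get(key)
            if m is None or len(m.replicate_values) != n:
                return False
        return True

    # -- validation ---------------------------------------------------

    def validate(self) -> None:
        """Check physical bounds: uptake cannot exceed
        ``max_uptake * deuterium_fraction`` beyond the noise tolerance."""
        d = self.conditions.deuterium_fraction
        for m in self._measurements.values():
            ceiling = m.peptide.max_uptake * d * (1 + self.NOISE_TOLERANCE)
            for v in m.replicate_values:
                if v > ceiling:
                    raise ValidationError(
                        f"uptake {v:.3f} Da exceeds physical ceiling "
                        f"{ceiling:.3f} Da for {m.peptide.sequence} "
                        f"({m.state_label}, {m.exposure_s}s)"
                    )
        for k in self.incomplete_keys():
            logger.warning(
                "incomplete replicate set for %s / %s / %gs",
                k[0].sequence, k[1], k[2],
            )

    def equals(self, other: "PeptideUptakeDataset", sig: int = 6) -> bool:
        """Equality up to ``sig`` significant digits on float fields."""
        if self.conditions != other.conditions:
            return False
        if set(self._measurements) != set(other._measurements):
            return False

        def rnd(x: float) -> float:
            return float(f"%.{sig}g" % x)

        for key, m in self._measurements.items():
            o = other._measurements[key]
            if len(m.replicate_values) != len(o.replicate_values):
                return False
            # replicate identity is a multiset property: cluster tables
            # carry no replicate ids, so compare order-free
            if any(rnd(a) != rnd(b)
                   for a, b in zip(sorted(m.replicate_values),
                                   sorted(o.replicate_values))):
                return False
        return True


# ----------------------------------------------------------------------
# exposure parsing

_SECONDS_PER_UNIT = {
    "s": 1.0, "sec": 1.0, "secs": 1.0, "second": 1.0, "seconds": 1.0,
    "min": 60.0, "mins": 60.0, "minute": 60.0, "minutes": 60.0, "m": 60.0,
    "h": 3600.0, "hr": 3600.0, "hour": 3600.0, "hours": 3600.0,
}


def parse_exposure(text: object, bare_unit: str) -> float:
    """Parse an exposure value to seconds.

    ``bare_unit`` ("min" or "s") applies when no unit suffix is given —
    DynamX cluster tables use bare minutes, the long dialect bare seconds.
    """
    s = str(text).strip().lower()
    for unit in sorted(_SECONDS_PER_UNIT, key=len, reverse=True):
        if s.endswith(unit):
            head = s[: -len(unit)].strip()
            if head:
                try:
                    return float(head) * _SECONDS_PER_UNIT[unit]
                except ValueError:
                    break
            # a bare "s"/"m" with no number falls through to the error
    try:
        return float(s) * _SECONDS_PER_UNIT[bare_unit]
    except ValueError:
        raise ParseError(f"cannot parse exposure value {text!r}") from None


def _format_exposure_min(seconds: float) -> str:
    return "%.6g" % (seconds / 60.0)


# ----------------------------------------------------------------------
# dialects

_CLUSTER_COLUMNS = {
    "protein": "protein", "start": "start", "end": "end",
    "sequence": "sequence", "state": "state", "exposure": "exposure",
    "maxuptake": "maxuptake", "uptake": "uptake",
}
_LONG_COLUMNS = (
    "protein", "start", "end", "sequence", "state",
    "exposure_s", "max_uptake", "replicate", "uptake_da",
)

DIALECTS = ("cluster_csv", "long_tsv")


def _require_columns(df: pd.DataFrame, required: list[str], dialect: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(
            f"{dialect}: missing required column(s) {missing}; "
            f"found {list(df.columns)}"
        )


def _numeric(df: pd.DataFrame, column: str) -> pd.Series:
    out = pd.to_numeric(df[column], errors="coerce")
    bad = out.isna() & df[column].notna()
    if bad.any():
        row = int(df.index[bad][0]) + 2  # 1-based + header row
        raise ParseError(
            f"non-numeric value {df[column][bad].iloc[0]!r} in column "
            f"{column!r} at row {row}"
        )
    return out


def read_uptake_table(
    path,
    dialect: str = "cluster_csv",
    *,
    deuterium_fraction: float = DEFAULT_DEUTERIUM_FRACTION,
    n_replicates: int | None = None,
    length_filter: tuple[int, int] | None = None,
) -> PeptideUptakeDataset:
    """Read a peptide uptake table.

    Parameters
    ----------
    path:
        Input file (CSV for ``cluster_csv``, TSV for ``long_tsv``).
    dialect:
        One of :data:`DIALECTS`.
    deuterium_fraction:
        Deuterium fraction D of the labeling buffer after mixing (not
        stored in either dialect).
    n_replicates:
        Expected replicates per group; inferred (modal count) if None.
    length_filter:
        Optional ``(min, max)`` peptide length window; excluded peptides
        are logged.  Pass :data:`DEFAULT_LENGTH_FILTER` for the standard
        5–25 filter.
    """
    if dialect not in DIALECTS:
        raise FormatError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    sep = "," if dialect == "cluster_csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise FormatError("no measurements: file is empty") from None
    df.columns = [str(c).strip().lower().replace(" ", "_") for c in df.columns]
    if dialect == "cluster_csv":
        # DynamX writes "MaxUptake"; accept either spelling
        df = df.rename(columns={"max_uptake": "maxuptake"})
        required = list(_CLUSTER_COLUMNS)
    else:
        required = list(_LONG_COLUMNS)
    _require_columns(df, required, dialect)
    df = df.dropna(how="all")
    if df.empty:
        raise FormatError("no measurements: data section is empty")

    starts = _numeric(df, "start").astype(int)
    ends = _numeric(df, "end").astype(int)
    uptake_col = "uptake" if dialect == "cluster_csv" else "uptake_da"
    uptakes = _numeric(df, uptake_col)
    bare_unit = "min" if dialect == "cluster_csv" else "s"
    exposure_col = "exposure" if dialect == "cluster_csv" else "exposure_s"
    exposures = [parse_exposure(v, bare_unit) for v in df[exposure_col]]

    peptide_cache: dict[tuple[str, int, str], Peptide] = {}
    excluded: set[str] = set()
    groups: dict[tuple[Peptide, str, float], list[tuple[float, float]]] = {}
    sd_groups: dict[tuple[Peptide, str, float], float] = {}
    has_sd = dialect == "cluster_csv" and "uptake_sd" in df.columns
    sds = _numeric(df, "uptake_sd") if has_sd else None

    for i, (_, row) in enumerate(df.iterrows()):
        seq = str(row["sequence"]).strip()
        if length_filter is not None and not (
            length_filter[0] <= len(seq) <= length_filter[1]
        ):
            if seq not in excluded:
                logger.info(
                    "excluding peptide %s (length %d outside %s)",
                    seq, len(seq), length_filter,
                )
                excluded.add(seq)
            continue
        key3 = (str(row["protein"]).strip(), int(starts.iloc[i]), seq)
        pep = peptide_cache.get(key3)
        if pep is None:
            pep = Peptide.from_sequence(*key3)
            if pep.end != int(ends.iloc[i]):
                raise ValidationError(
                    f"row {i + 2}: end {ends.iloc[i]} inconsistent with "
                    f"start+len(sequence) for {seq!r}"
                )
            mu_col = "maxuptake" if dialect == "cluster_csv" else "max_uptake"
            stated = row.get(mu_col)
            if stated is not None and not pd.isna(stated):
                if int(float(stated)) != pep.max_uptake:
                    raise ValidationError(
                        f"row {i + 2}: stated max uptake {stated} differs from "
                        f"computed {pep.max_uptake} for {seq!r}"
                    )
            peptide_cache[key3] = pep
        state = str(row["state"]).strip()
        gkey = (pep, state, exposures[i])
        if dialect == "long_tsv":
            rep = float(_numeric(df, "replicate").iloc[i])
        else:
            rep = float(i)  # file order; values are sorted later anyway
        entries = groups.setdefault(gkey, [])
        if dialect == "long_tsv" and any(r == rep for r, _ in entries):
            raise IntegrityError(
                f"duplicate replicate {int(rep)} for {seq} / {state} / "
                f"{exposures[i]}s"
            )
        if has_sd:
            if gkey in sd_groups:
                raise IntegrityError(
                    f"duplicate mean+SD row for {seq} / {state} / {exposures[i]}s"
                )
            sd_groups[gkey] = float(sds.iloc[i])
        entries.append((rep, float(uptakes.iloc[i])))

    if not groups:
        raise FormatError("no measurements after filtering")

    counts = [len(v) for v in groups.values()]
    if n_replicates is None:
        if has_sd:
            n_replicates = 3
        else:
            n_replicates = max(set(counts), key=counts.count)
    timepoints = tuple(sorted({k[2] for k in groups}))
    ds = PeptideUptakeDataset(
        LabelingConditions(
            deuterium_fraction=deuterium_fraction,
            timepoints=timepoints,
            n_replicates=n_replicates,
        )
    )
    for gkey, entries in groups.items():
        pep, state, exp = gkey
        if has_sd:
            # one mean(+SD) row per group: reconstruct placeholder replicates
            mean = entries[0][1]
            sd = sd_groups.get(gkey, 0.0)
            vals = tuple(max(0.0, v) for v in (mean - sd, mean, mean + sd))
            logger.warning(
                "replicates for %s / %s / %gs reconstructed from mean +/- SD",
                pep.sequence, state, exp,
            )
            ds.add(UptakeMeasurement(pep, state, exp, vals, reconstructed=True))
        elif dialect == "long_tsv":
            vals = tuple(v for _, v in sorted(entries))
            ds.add(UptakeMeasurement(pep, state, exp, vals))
        else:
            # cluster rows carry no replicate id: store sorted for
            # order-invariance
            vals = tuple(sorted(v for _, v in entries))
            ds.add(UptakeMeasurement(pep, state, exp, vals))
    ds.validate()
    return ds


def write_uptake_table(
    dataset: PeptideUptakeDataset, path, dialect: str = "cluster_csv"
) -> None:
    """Write a dataset to disk; ``read_uptake_table`` round-trips it at
    6 significant digits."""
    if dialect not in DIALECTS:
        raise FormatError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    for k in dataset.incomplete_keys():
        logger.warning(
            "writing incomplete replicate set for %s / %s / %gs",
            k[0].sequence, k[1], k[2],
        )
    rows: list[dict] = []
    for m in dataset:
        for j, v in enumerate(m.replicate_values, start=1):
            if dialect == "cluster_csv":
                rows.append({
                    "Protein": m.peptide.protein_id,
                    "Start": m.peptide.start,
                    "End": m.peptide.end,
                    "Sequence": m.peptide.sequence,
                    "State": m.state_label,
                    "Exposure": _format_exposure_min(m.exposure_s),
                    "MaxUptake": m.peptide.max_uptake,
                    "Uptake": "%.6g" % v,
                })
            else:
                rows.append({
                    "protein": m.peptide.protein_id,
                    "start": m.peptide.start,
                    "end": m.peptide.end,
                    "sequence": m.peptide.sequence,
                    "state": m.state_label,
                    "exposure_s": "%.6g" % m.exposure_s,
                    "max_uptake": m.peptide.max_uptake,
                    "replicate": j,
                    "uptake_da": "%.6g" % v,
                })
    out = pd.DataFrame(rows)
    sep = "," if dialect == "cluster_csv" else "\t"
    try:
        out.to_csv(path, sep=sep, index=False, lineterminator="\n")
    except OSError as exc:
        raise IOError(f"cannot write uptake table to {path}: {exc}") from exc
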