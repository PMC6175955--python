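"""Differential uptake statistics.

Implements the peptide-level comparison between two protein states:
relative fractional uptake, per-timepoint and summed ΔHDX (variant minus
control, in Da), a Houde-style global confidence threshold on the summed
difference built from a pooled replicate standard deviation, and a
two-sided unpaired Student t-test on per-replicate summed uptake.  A
peptide is called significant only if it clears *both* gates:

    |summed ΔHDX| > summed CI   and   p <= alpha .

The pooled SD is the root mean square of the replicate SDs of every
complete (peptide, timepoint, state) group; the standard error of one
ΔHDX is sqrt(2)/sqrt(n) times that, and the threshold on the sum over k
timepoints is t_{1-alpha/2, df} * sqrt(k) * SE with df = sum(n-1) over
all contributing groups.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    CoverageError,
    FormatError,
    InsufficientDataError,
    ParameterError,
    ValidationError,
)
from .uptake import Peptide, PeptideUptakeDataset

logger = logging.getLogger(__name__)


class Classification(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    NONE = "none"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class DifferentialConfig:
    """Statistical options for a differential run."""

    alpha: float = 0.01
    welch: bool = False          # unequal-variance t-test
    fdr_bh: bool = False         # Benjamini-Hochberg adjust p before gating

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ParameterError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class SignificanceThresholds:
    """Global significance threshold for summed ΔHDX."""

    alpha: float
    pooled_sd: float     # Da, RMS of per-group replicate SDs
    summed_ci: float     # Da, symmetric threshold on summed ΔHDX
    df: int              # degrees of freedom, sum(n-1) over groups
    n_replicates: int
    n_timepoints: int


@dataclass(frozen=True)
class TimepointDelta:
    exposure_s: float
    mean: float   # Da, variant - control
    se: float     # Da


@dataclass(frozen=True)
class DifferentialRecord:
    """Per-peptide differential result."""

    peptide: Peptide
    deltas: tuple[TimepointDelta, ...]
    summed_delta: float
    t_statistic: float
    p_value: float
    classification: Classification
    rfu_control: float = float("nan")   # auxiliary, at the longest exposure
    rfu_variant: float = float("nan")

    def __post_init__(self) -> None:
        s = sum(d.mean for d in self.deltas)
        if abs(s - self.summed_delta) > 1e-9:
            raise ValidationError(
                "summed_delta inconsistent with per-timepoint means"
            )


@dataclass
class DifferentialResult:
    """Output of :func:`run_differential`."""

    records: list[DifferentialRecord]
    thresholds: SignificanceThresholds
    no_coverage: list[Peptide] = field(default_factory=list)
    skipped_incomplete: list[Peptide] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        out = {c.value: 0 for c in Classification}
        for r in self.records:
            out[r.classification.value] += 1
        out["no_coverage"] = len(self.no_coverage)
        return out


def relative_fractional_uptake(
    uptake_da: float, max_uptake: int, deuterium_fraction: float
) -> float:
    """RFU = Y / (MaxUptake × D).

    ``Y`` is the deuterium uptake of the peptide (Da), ``MaxUptake`` its
    exchangeable-amide count and ``D`` the deuterium fraction of the
    labeling buffer after mixing (0.95 for a 5 µL into 95 µL dilution).
    """
    if max_uptake < 1:
        raise ParameterError(
            "RFU undefined: peptide has no exchangeable amides (max_uptake == 0)"
        )
    if not 0 < deuterium_fraction <= 1:
        raise ParameterError("deuterium_fraction must lie in (0, 1]")
    if uptake_da < 0:
        raise ParameterError("uptake must be >= 0")
    return uptake_da / (max_uptake * deuterium_fraction)


def _replicates(
    ds: PeptideUptakeDataset, peptide: Peptide, state: str, exposure_s: float
) -> np.ndarray:
    try:
        m = ds.get(peptide, state, exposure_s)
    except KeyError as exc:
        raise CoverageError(str(exc)) from None
    if len(m.replicate_values) != ds.conditions.n_replicates:
        raise CoverageError(
            f"incomplete replicates for {peptide.sequence} / {state} / "
            f"{exposure_s}s"
        )
    return np.asarray(m.replicate_values, dtype=float)


def _single_state(ds: PeptideUptakeDataset) -> str:
    states = ds.states
    if len(states) != 1:
        raise ValidationError(
            f"dataset must contain exactly one state, found {states}"
        )
    return states[0]


def delta_uptake(
    control: PeptideUptakeDataset,
    variant: PeptideUptakeDataset,
    peptide: Peptide,
    exposure_s: float,
) -> tuple[float, float]:
    """Mean ΔHDX (variant − control) and its standard error at one
    exposure, from replicate values.  SE = sqrt(s_v²/n_v + s_c²/n_c)
    with sample (ddof=1) variances."""
    c = _replicates(control, peptide, _single_state(control), exposure_s)
    v = _replicates(variant, peptide, _single_state(variant), exposure_s)
    mean = float(v.mean() - c.mean())
    se = float(math.sqrt(v.var(ddof=1) / v.size + c.var(ddof=1) / c.size))
    return mean, se


def houde_threshold(
    control: PeptideUptakeDataset,
    variant: PeptideUptakeDataset,
    alpha: float = 0.01,
) -> SignificanceThresholds:
    """Global confidence threshold for the summed ΔHDX.

    Pools the replicate SD over every complete (peptide, timepoint,
    state) group as a root mean square, propagates it to the SE of one
    ΔHDX (sqrt(2)·sd/sqrt(n)) and of the sum over k timepoints
    (·sqrt(k)), and scales by the two-sided Student t critical value at
    df = Σ(n−1).
    """
    if control.conditions.timepoints != variant.conditions.timepoints:
        raise ValidationError("timepoint schemes differ between states")
    n = control.conditions.n_replicates
    if variant.conditions.n_replicates != n:
        raise ValidationError("replicate counts differ between states")
    variances: list[float] = []
    for ds in (control, variant):
        state = _single_state(ds)
        for pep in ds.peptides(state):
            if not ds.is_complete(pep, state):
                continue
            for t in ds.conditions.timepoints:
                vals = np.asarray(
                    ds.get(pep, state, t).replicate_values, dtype=float
                )
                variances.append(float(vals.var(ddof=1)))
    if not variances:
        raise InsufficientDataError(
            "no complete replicate groups shared by the two states"
        )
    # fsum keeps the pooled SD exactly invariant under state swap
    pooled_sd = math.sqrt(math.fsum(variances) / len(variances))
    df = len(variances) * (n - 1)
    k = len(control.conditions.timepoints)
    se_one = math.sqrt(2.0) * pooled_sd / math.sqrt(n)
    t_crit = float(sps.t.ppf(1.0 - alpha / 2.0, df)) if pooled_sd > 0 else 0.0
    summed_ci = t_crit * math.sqrt(k) * se_one
    return SignificanceThresholds(
        alpha=alpha,
        pooled_sd=pooled_sd,
        summed_ci=summed_ci,
        df=df,
        n_replicates=n,
        n_timepoints=k,
    )


def _ttest_summed(
    c_sums: np.ndarray, v_sums: np.ndarray, welch: bool
) -> tuple[float, float]:
    """Two-sided unpaired t-test on per-replicate summed uptake, with an
    explicit zero-variance convention (identical groups → p = 1)."""
    if c_sums.var(ddof=1) == 0 and v_sums.var(ddof=1) == 0:
        if math.isclose(c_sums.mean(), v_sums.mean(), abs_tol=1e-12):
            return 0.0, 1.0
        sign = 1.0 if v_sums.mean() > c_sums.mean() else -1.0
        return sign * math.inf, 0.0
    res = sps.ttest_ind(v_sums, c_sums, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def classify_peptide(
    control: PeptideUptakeDataset,
    variant: PeptideUptakeDataset,
    peptide: Peptide,
    thresholds: SignificanceThresholds,
    config: DifferentialConfig = DifferentialConfig(),
) -> DifferentialRecord:
    """Build the differential record for one peptide and apply the dual
    significance gate (summed CI and t-test)."""
    c_state = _single_state(control)
    v_state = _single_state(variant)
    times = control.conditions.timepoints
    deltas = []
    c_sums = np.zeros(control.conditions.n_replicates)
    v_sums = np.zeros(variant.conditions.n_replicates)
    for t in times:
        c = _replicates(control, peptide, c_state, t)
        v = _replicates(variant, peptide, v_state, t)
        c_sums += c
        v_sums += v
        mean = float(v.mean() - c.mean())
        se = float(math.sqrt(v.var(ddof=1) / v.size + c.var(ddof=1) / c.size))
        deltas.append(TimepointDelta(exposure_s=t, mean=mean, se=se))
    summed = sum(d.mean for d in deltas)
    t_stat, p = _ttest_summed(c_sums, v_sums, config.welch)
    cls = _gate(summed, p, thresholds, config.alpha)
    d = control.conditions.deuterium_fraction
    longest = times[-1]
    rfu_c = rfu_v = float("nan")
    if peptide.max_uptake >= 1:
        rfu_c = relative_fractional_uptake(
            float(_replicates(control, peptide, c_state, longest).mean()),
            peptide.max_uptake, d,
        )
        rfu_v = relative_fractional_uptake(
            float(_replicates(variant, peptide, v_state, longest).mean()),
            peptide.max_uptake, d,
        )
    return DifferentialRecord(
        peptide=peptide,
        deltas=tuple(deltas),
        summed_delta=summed,
        t_statistic=t_stat,
        p_value=p,
        classification=cls,
        rfu_control=rfu_c,
        rfu_variant=rfu_v,
    )


def _gate(
    summed: float, p: float, thresholds: SignificanceThresholds, alpha: float
) -> Classification:
    if p <= alpha and summed > thresholds.summed_ci:
        return Classification.POSITIVE
    if p <= alpha and summed < -thresholds.summed_ci:
        return Classification.NEGATIVE
    return Classification.NONE


def run_differential(
    control: PeptideUptakeDataset,
    variant: PeptideUptakeDataset,
    config: DifferentialConfig = DifferentialConfig(),
) -> DifferentialResult:
    """Compare two single-state datasets peptide by peptide.

    Produces one record per peptide present with complete replicates in
    both states; peptides present in only one state are reported as
    ``no_coverage``, incomplete ones as ``skipped_incomplete`` (with a
    warning).  Deterministic: records are ordered by peptide.
    """
    if control.conditions.timepoints != variant.conditions.timepoints:
        raise ValidationError(
            "timepoint mismatch between states: "
            f"{control.conditions.timepoints} vs {variant.conditions.timepoints}"
        )
    c_state = _single_state(control)
    v_state = _single_state(variant)
    c_peps = set(control.peptides(c_state))
    v_peps = set(variant.peptides(v_state))
    shared = sorted(c_peps & v_peps)
    no_coverage = sorted(c_peps ^ v_peps)
    if not shared:
        logger.warning("peptide sets are disjoint; empty differential result")
    thresholds = houde_threshold(control, variant, config.alpha)
    records: list[DifferentialRecord] = []
    skipped: list[Peptide] = []
    for pep in shared:
        if not (control.is_complete(pep, c_state)
                and variant.is_complete(pep, v_state)):
            logger.warning(
                "skipping %s: incomplete replicate set", pep.sequence
            )
            skipped.append(pep)
            continue
        records.append(
            classify_peptide(control, variant, pep, thresholds, config)
        )
    if config.fdr_bh and records:
        adj = sps.false_discovery_control(
            [r.p_value for r in records], method="bh"
        )
        records = [
            DifferentialRecord(
                peptide=r.peptide,
                deltas=r.deltas,
                summed_delta=r.summed_delta,
                t_statistic=r.t_statistic,
                p_value=float(q),
                classification=_gate(r.summed_delta, float(q), thresholds,
                                     config.alpha),
                rfu_control=r.rfu_control,
                rfu_variant=r.rfu_variant,
            )
            for r, q in zip(records, adj)
        ]
    return DifferentialResult(
        records=records,
        thresholds=thresholds,
        no_coverage=no_coverage,
        skipped_incomplete=skipped,
    )


# ----------------------------------------------------------------------
# power analysis

def dual_gate_power(
    summed_delta: float,
    replicate_sd: float,
    n_replicates: int = 3,
    n_timepoints: int = 3,
    alpha: float = 0.01,
) -> float:
    """Probability that a true summed ΔHDX of the given size passes the
    t-test gate, from the noncentral t distribution.

    The t-test compares per-replicate summed uptake (SD = replicate_sd ×
    sqrt(k)), two groups of n, df = 2(n−1).  At n = 3 and alpha = 0.01
    this gate dominates the CI gate, so it approximates the power of the
    dual criterion.
    """
    if replicate_sd <= 0:
        return 1.0 if summed_delta != 0 else 0.0
    sigma_sum = replicate_sd * math.sqrt(n_timepoints)
    se = sigma_sum * math.sqrt(2.0 / n_replicates)
    df = 2 * (n_replicates - 1)
    t_crit = float(sps.t.ppf(1.0 - alpha / 2.0, df))
    ncp = abs(summed_delta) / se  # power is symmetric in the sign
    upper = float(sps.nct.sf(t_crit, df, ncp))
    lower = float(sps.nct.cdf(-t_crit, df, ncp))
    if math.isnan(lower):  # numerically negligible far tail
        lower = 0.0
    return upper + lower


def minimum_detectable_summed_delta(
    replicate_sd: float,
    n_replicates: int = 3,
    n_timepoints: int = 3,
    alpha: float = 0.01,
    power: float = 0.9,
) -> float:
    """Smallest true summed ΔHDX (Da) detected with the requested power
    under the dual significance gate — the design's sensitivity limit."""
    if replicate_sd <= 0:
        return 0.0
    lo, hi = 0.0, 200.0 * replicate_sd
    for _ in range(80):
        mid = (lo + hi) / 2.0
        if dual_gate_power(mid, replicate_sd, n_replicates,
                           n_timepoints, alpha) < power:
            lo = mid
        else:
            hi = mid
    return hi


# ----------------------------------------------------------------------
# tabular output

def differential_table(result: DifferentialResult) -> pd.DataFrame:
    """One row per peptide with per-timepoint Δ, summed Δ, statistics,
    classification and the threshold used."""
    rows = []
    for r in result.records:
        row = {
            "protein": r.peptide.protein_id,
            "start": r.peptide.start,
            "end": r.peptide.end,
            "sequence": r.peptide.sequence,
            "max_uptake": r.peptide.max_uptake,
        }
        for d in r.deltas:
            row[f"delta_{d.exposure_s:g}s"] = d.mean
            row[f"se_{d.exposure_s:g}s"] = d.se
        row.update({
            "summed_delta": r.summed_delta,
            "t_statistic": r.t_statistic,
            "p_value": r.p_value,
            "classification": r.classification.value,
            "summed_ci": result.thresholds.summed_ci,
            "rfu_control": r.rfu_control,
            "rfu_variant": r.rfu_variant,
        })
        rows.append(row)
    return pd.DataFrame(rows)


def write_differential_tsv(result: DifferentialResult, path) -> None:
    differential_table(result).to_csv(
        path, sep="\t", index=False, float_format="%.12g", lineterminator="\n"
    )


def read_differential_tsv(path) -> tuple[list[DifferentialRecord], float]:
    """Read back a differential TSV (as written by
    :func:`write_differential_tsv`); returns the records and the summed
    CI threshold stored in the table."""
    df = pd.read_csv(path, sep="\t")
    required = {"protein", "start", "sequence", "summed_delta",
                "t_statistic", "p_value", "classification", "summed_ci"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"differential TSV missing column(s) {sorted(missing)}")
    delta_cols = sorted(
        (c for c in df.columns if c.startswith("delta_") and c.endswith("s")),
        key=lambda c: float(c[6:-1]),
    )
    records = []
    for _, row in df.iterrows():
        pep = Peptide.from_sequence(
            str(row["protein"]), int(row["start"]), str(row["sequence"])
        )
        deltas = tuple(
            TimepointDelta(
                exposure_s=float(c[6:-1]),
                mean=float(row[c]),
                se=float(row.get("se_" + c[6:], float("nan"))),
            )
            for c in delta_cols
        )
        records.append(DifferentialRecord(
            peptide=pep,
            deltas=deltas,
            summed_delta=float(row["summed_delta"]),
            t_statistic=float(row["t_statistic"]),
            p_value=float(row["p_value"]),
            classification=Classification(row["classification"]),
            rfu_control=float(row.get("rfu_control", float("nan"))),
            rfu_variant=float(row.get("rfu_variant", float("nan"))),
        ))
    ci = float(df["summed_ci"].iloc[0]) if len(df) else 0.0
    return records, ci
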