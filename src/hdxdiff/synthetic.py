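"""Two-state conformational-equilibrium HDX simulator.

Generates peptide uptake datasets from a Linderstrom-Lang kinetic model of
a 12-TM transporter whose outward-facing (OF) and inward-facing (IF)
conformations interconvert rapidly (EX2 limit).  Each residue *i* carries
a protection factor in each conformation; with an IF population ``f`` the
observed exchange rate is the population-weighted mixture

    k_obs,i = k_int,i * ( f / P_IF,i + (1 - f) / P_OF,i )

and the deuterated fraction after exposure ``t`` is ``1 - exp(-k_obs t)``.

The default scenario encodes the alternating-access diagnostic geometry:
intracellular loops are protected in the OF state and exposed in the IF
state, extracellular loops the converse, transmembrane helices equally
(and strongly) protected in both.  Shifting the IF population between a
control and a variant condition therefore produces anti-correlated uptake
changes on the two faces of the protein — the pattern a differential
HDX-MS experiment reads out.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, ValidationError
from .uptake import (
    LabelingConditions,
    Peptide,
    PeptideUptakeDataset,
    UptakeMeasurement,
)

logger = logging.getLogger(__name__)

REGIONS = ("intracellular", "transmembrane", "extracellular")

#: residues per loop / helix block in the default 12-helix-like topology
_LOOP_LEN = 8
_TM_LEN = 17

_AA_ALPHABET = "ACDEFGHIKLMNQRSTVWY"  # proline inserted separately


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian replicate noise (truncated at zero uptake)."""

    replicate_sd: float = 0.05  # Da, typical instrument repeatability
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicate_sd < 0:
            raise ValidationError("replicate_sd must be >= 0")


@dataclass(frozen=True)
class ConformationalScenario:
    """Ground truth for one simulated two-condition experiment.

    Arrays are per-residue over ``sequence``; protection factors are
    stored as log10 (>= 0, i.e. P >= 1), intrinsic rates in 1/min.
    ``population_IF_*`` are the equilibrium IF fractions of the control
    and variant conditions.
    """

    sequence: str
    log10_protection_OF: np.ndarray
    log10_protection_IF: np.ndarray
    intrinsic_rates_per_min: np.ndarray
    population_IF_control: float
    population_IF_variant: float
    region_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for name in ("log10_protection_OF", "log10_protection_IF",
                     "intrinsic_rates_per_min"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValidationError(f"{name} must have length {n}")
            object.__setattr__(self, name, arr)
        if len(self.region_labels) != n:
            raise ValidationError("region_labels must match sequence length")
        if any(r not in REGIONS for r in self.region_labels):
            raise ValidationError(f"region labels must be in {REGIONS}")
        if (self.log10_protection_OF < 0).any() or (
            self.log10_protection_IF < 0
        ).any():
            raise ValidationError("log10 protection factors must be >= 0")
        if (self.intrinsic_rates_per_min <= 0).any():
            raise ValidationError("intrinsic rates must be > 0")
        for p in (self.population_IF_control, self.population_IF_variant):
            if not 0 <= p <= 1:
                raise ValidationError(f"population {p} outside [0, 1]")

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    def population(self, which: str) -> float:
        if which == "control":
            return self.population_IF_control
        if which == "variant":
            return self.population_IF_variant
        raise ParameterError(f"condition must be 'control' or 'variant', got {which!r}")


def default_transporter_scenario(
    n_residues: int = 300,
    shift: str = "toward_IF",
    seed: int = 0,
    *,
    delta_population: float = 0.3,
    protection_contrast_log10: float = 1.0,
    loop_baseline_log10: float = 1.0,
    tm_log10: float = 3.0,
    log10_rate_range_per_min: tuple[float, float] = (0.0, 3.0),
    proline_fraction: float = 0.05,
) -> ConformationalScenario:
    """Build the default 12-helix-like two-state scenario.

    Residues are partitioned into alternating
    extracellular-loop / TM / intracellular-loop / TM blocks.  In the OF
    state the intracellular face is closed (protected) and the
    extracellular face open; the IF state mirrors this.  The control
    condition sits at a 50/50 OF/IF equilibrium; the variant is displaced
    by ``delta_population`` toward the requested state (``shift`` in
    {"toward_IF", "toward_OF", "none"}).

    Deterministic given ``seed``: the sequence, intrinsic rates and
    proline placement are drawn from a seeded generator.
    """
    if shift not in ("toward_IF", "toward_OF", "none"):
        raise ParameterError(f"unknown shift {shift!r}")
    if n_residues < 50:
        raise ParameterError("n_residues must be >= 50 to hold the topology")
    if not 0 <= delta_population <= 0.5:
        raise ParameterError("delta_population must lie in [0, 0.5]")

    rng = np.random.default_rng(seed)

    # region labels: EC loop, TM, IC loop, TM, ... starting extracellular
    labels: list[str] = []
    block = 0
    while len(labels) < n_residues:
        kind = ("extracellular", "transmembrane",
                "intracellular", "transmembrane")[block % 4]
        length = _LOOP_LEN if kind != "transmembrane" else _TM_LEN
        labels.extend([kind] * length)
        block += 1
    labels = labels[:n_residues]
    for region in REGIONS:
        if region not in labels:
            raise ParameterError(
                f"n_residues={n_residues} too small for one {region} block"
            )
    labels_arr = np.array(labels)

    # random sequence with a sprinkling of prolines (non-exchanging sites)
    seq = rng.choice(list(_AA_ALPHABET), size=n_residues)
    pro = rng.random(n_residues) < proline_fraction
    seq[pro] = "P"
    sequence = "".join(seq)

    lo, hi = log10_rate_range_per_min
    rates = 10.0 ** rng.uniform(lo, hi, size=n_residues)

    p_of = np.full(n_residues, loop_baseline_log10)
    p_if = np.full(n_residues, loop_baseline_log10)
    ic = labels_arr == "intracellular"
    ec = labels_arr == "extracellular"
    tm = labels_arr == "transmembrane"
    # OF: closed inside, open outside; IF mirrors it
    p_of[ic] += protection_contrast_log10
    p_if[ec] += protection_contrast_log10
    p_of[tm] = tm_log10
    p_if[tm] = tm_log10

    f_control = 0.5
    if shift == "toward_IF":
        f_variant = f_control + delta_population
    elif shift == "toward_OF":
        f_variant = f_control - delta_population
    else:
        f_variant = f_control

    return ConformationalScenario(
        sequence=sequence,
        log10_protection_OF=p_of,
        log10_protection_IF=p_if,
        intrinsic_rates_per_min=rates,
        population_IF_control=f_control,
        population_IF_variant=f_variant,
        region_labels=tuple(labels),
    )


def residue_uptake_fraction(
    scenario: ConformationalScenario,
    residue_index: int,
    state_population_IF: float,
    time_s: float,
) -> float:
    """Deuterated fraction of one residue after ``time_s`` seconds.

    ``residue_index`` is 1-based.  Fast-exchange (EX2) mixture of the two
    conformations: the observed rate is the population-weighted sum of
    the per-state rates ``k_int / P``.
    """
    if time_s < 0:
        raise ParameterError("time must be >= 0")
    if not 0 <= state_population_IF <= 1:
        raise ParameterError("population must lie in [0, 1]")
    i = residue_index - 1
    if not 0 <= i < scenario.n_residues:
        raise ParameterError(f"residue index {residue_index} out of range")
    k_int = scenario.intrinsic_rates_per_min[i]
    p_of = 10.0 ** scenario.log10_protection_OF[i]
    p_if = 10.0 ** scenario.log10_protection_IF[i]
    f = state_population_IF
    k_obs_per_min = k_int * (f / p_if + (1.0 - f) / p_of)
    return 1.0 - math.exp(-k_obs_per_min * time_s / 60.0)


def _uptake_fraction_matrix(
    scenario: ConformationalScenario, f_if: float, times_s: np.ndarray
) -> np.ndarray:
    """(n_residues, n_times) deuterated-fraction matrix (vectorized)."""
    k_int = scenario.intrinsic_rates_per_min
    p_of = 10.0 ** scenario.log10_protection_OF
    p_if = 10.0 ** scenario.log10_protection_IF
    k_obs = k_int * (f_if / p_if + (1.0 - f_if) / p_of)  # 1/min
    t_min = np.asarray(times_s, dtype=float) / 60.0
    return 1.0 - np.exp(-np.outer(k_obs, t_min))


@dataclass(frozen=True)
class DigestResult:
    """In-silico digestion output with its achieved residue coverage."""

    peptides: tuple[Peptide, ...]
    achieved_coverage: float
    attempts: int


def digest_in_silico(
    sequence: str,
    target_coverage: float = 0.8,
    length_range: tuple[int, int] = (5, 25),
    seed: int = 0,
    *,
    protein_id: str = "SYN",
    min_peptides: int | None = None,
    max_attempts: int = 100_000,
) -> DigestResult:
    """Sample overlapping peptides until the residue coverage target
    (and optionally a minimum peptide count) is reached.

    Peptide lengths are uniform over ``length_range`` and start positions
    uniform over the admissible window; duplicate spans are discarded.
    Deterministic given ``seed``.  If the target is unreachable within
    ``max_attempts`` draws a warning is logged and the partial result
    returned (never silent).
    """
    if not 0 < target_coverage <= 1:
        raise ParameterError("target_coverage must lie in (0, 1]")
    lo, hi = length_range
    n = len(sequence)
    if lo > n:
        raise ParameterError("protein shorter than the minimum peptide length")
    rng = np.random.default_rng(seed)
    covered = np.zeros(n, dtype=bool)
    spans: set[tuple[int, int]] = set()
    peptides: list[Peptide] = []
    attempts = 0
    need_more = True
    while need_more and attempts < max_attempts:
        attempts += 1
        length = int(rng.integers(lo, min(hi, n) + 1))
        start = int(rng.integers(1, n - length + 2))
        span = (start, start + length - 1)
        if span in spans:
            continue
        spans.add(span)
        peptides.append(
            Peptide.from_sequence(protein_id, start, sequence[start - 1: span[1]])
        )
        covered[start - 1: span[1]] = True
        coverage = covered.mean()
        need_more = coverage < target_coverage or (
            min_peptides is not None and len(peptides) < min_peptides
        )
    coverage = float(covered.mean())
    if need_more:
        logger.warning(
            "digestion stopped after %d attempts at coverage %.3f "
            "(target %.3f)", attempts, coverage, target_coverage,
        )
    peptides.sort()
    return DigestResult(tuple(peptides), coverage, attempts)


def simulate_dataset(
    scenario: ConformationalScenario,
    peptides,
    conditions: LabelingConditions,
    which: str = "control",
    noise: NoiseModel = NoiseModel(),
    *,
    state_label: str | None = None,
) -> PeptideUptakeDataset:
    """Simulate replicate uptake tables for one condition.

    Noiseless uptake of a peptide is the deuterium fraction D times the
    sum of per-residue deuterated fractions over its exchangeable amides
    (first residue and prolines excluded).  Replicates add i.i.d.
    Gaussian noise, truncated at zero.  The replicate stream is seeded by
    ``(noise.seed, which)`` so control and variant draws are independent
    but reproducible.
    """
    f_if = scenario.population(which)
    label = state_label or which
    times = np.asarray(conditions.timepoints, dtype=float)
    frac = _uptake_fraction_matrix(scenario, f_if, times)
    rng = np.random.default_rng(
        np.random.SeedSequence([int(noise.seed), 0 if which == "control" else 1])
    )
    ds = PeptideUptakeDataset(conditions)
    d = conditions.deuterium_fraction
    n_rep = conditions.n_replicates
    for pep in peptides:
        if pep.start < 1 or pep.end > scenario.n_residues:
            raise ParameterError(
                f"peptide {pep.sequence} ({pep.start}-{pep.end}) outside "
                f"sequence bounds 1-{scenario.n_residues}"
            )
        if pep.sequence != scenario.sequence[pep.start - 1: pep.end]:
            raise ParameterError(
                f"peptide sequence {pep.sequence!r} does not match scenario "
                f"residues {pep.start}-{pep.end}"
            )
        idx = np.array(pep.exchangeable_positions(), dtype=int) - 1
        for j, t in enumerate(times):
            clean = d * float(frac[idx, j].sum()) if idx.size else 0.0
            reps = clean + rng.normal(0.0, noise.replicate_sd, size=n_rep)
            reps = np.maximum(reps, 0.0)
            ds.add(UptakeMeasurement(pep, label, float(t), tuple(reps)))
    return ds


def noiseless_summed_delta(
    scenario: ConformationalScenario,
    peptide: Peptide,
    conditions: LabelingConditions,
) -> float:
    """Closed-form summed ΔHDX (variant − control, Da) for one peptide —
    the ground truth the statistical pipeline should recover."""
    times = np.asarray(conditions.timepoints, dtype=float)
    idx = np.array(peptide.exchangeable_positions(), dtype=int) - 1
    if idx.size == 0:
        return 0.0
    fv = _uptake_fraction_matrix(scenario, scenario.population_IF_variant, times)
    fc = _uptake_fraction_matrix(scenario, scenario.population_IF_control, times)
    return float(
        conditions.deuterium_fraction * (fv[idx].sum() - fc[idx].sum())
    )


#: minimum exchangeable amides inside an affected loop for a peptide to
#: count as an affected-region peptide (one amide contributes ~0.1-0.2 Da
#: of summed ΔHDX under the default scenario, comparable to the global
#: threshold, so a single-amide overlap is not reliably detectable)
MIN_AFFECTED_AMIDES = 3


def expected_sign(scenario: ConformationalScenario, peptide: Peptide) -> int:
    """Expected ΔHDX sign of an affected-region peptide.

    A peptide reports on exactly one face of the transporter when its
    exchangeable amides overlap intracellular *or* extracellular loops
    (not both) with at least :data:`MIN_AFFECTED_AMIDES` amides;
    transmembrane residues are equally protected in both states and
    contribute no difference.  Returns +1/−1 for such peptides (sign of
    the true uptake change in the variant), 0 for transmembrane-only or
    mixed-face peptides and for a null scenario.
    """
    dpop = scenario.population_IF_variant - scenario.population_IF_control
    if dpop == 0:
        return 0
    counts = {r: 0 for r in REGIONS}
    for pos in peptide.exchangeable_positions():
        counts[scenario.region_labels[pos - 1]] += 1
    ic, ec = counts["intracellular"], counts["extracellular"]
    if ic >= MIN_AFFECTED_AMIDES and ec == 0:
        side = 1  # IF opens the intracellular face
    elif ec >= MIN_AFFECTED_AMIDES and ic == 0:
        side = -1
    else:
        return 0
    return side if dpop > 0 else -side


def affected_peptides(scenario: ConformationalScenario, peptides):
    """Peptides with a non-zero expected ΔHDX sign, with that sign."""
    out = []
    for pep in peptides:
        s = expected_sign(scenario, pep)
        if s != 0:
            out.append((pep, s))
    return out


def recoverable_peptides(
    scenario: ConformationalScenario,
    peptides,
    conditions: LabelingConditions,
    noise: NoiseModel,
    *,
    alpha: float = 0.01,
    power: float = 0.9,
):
    """Affected-region peptides whose ground-truth effect is detectable.

    Restricts :func:`affected_peptides` to peptides whose noiseless
    summed ΔHDX magnitude reaches the design's minimum detectable effect
    at the requested power (noncentral-t power analysis of the dual
    significance gate).  Peptides below that sensitivity limit cannot be
    recovered by *any* procedure at the stated noise level, so recovery
    rates are meaningful only over this set.
    """
    from .stats import minimum_detectable_summed_delta

    mde = minimum_detectable_summed_delta(
        noise.replicate_sd,
        n_replicates=conditions.n_replicates,
        n_timepoints=len(conditions.timepoints),
        alpha=alpha,
        power=power,
    )
    out = []
    for pep, sign in affected_peptides(scenario, peptides):
        true = noiseless_summed_delta(scenario, pep, conditions)
        if abs(true) >= mde:
            out.append((pep, sign))
    return out
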