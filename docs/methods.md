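# Methods

## The differential measurement

The package compares peptide-level deuterium uptake between two protein
states ("control" and "variant"; the sign convention is always variant
minus control). Uptake is used as measured — no back-exchange correction
is applied, because only relative differences between states enter the
analysis and both states lose deuterium identically during workup.

For peptide *a* at exposure *t* the relative fractional uptake is

    RFU_a = Y_{a,t} / (MaxUptake_a × D)

with Y the centroid uptake in Da, D the deuterium fraction of the
labeling buffer after mixing (default 0.95, the 5 µL → 95 µL dilution)
and MaxUptake the count of exchangeable backbone amides. MaxUptake
follows the DynamX convention: peptide length − 1 − number of internal
prolines; the N-terminal amide back-exchanges essentially instantly and
proline has no amide hydrogen. ΔHDX itself is computed in Da, not RFU —
summing absolute mass differences over timepoints is what the
significance machinery operates on; RFU is carried as an auxiliary
column.

## Significance: the dual gate

Two criteria must both hold for a peptide to be called significant.

**Pooled-SD confidence threshold.** The replicate standard deviations of
every complete (peptide, timepoint, state) group are pooled as a root
mean square s_p (equivalently, the mean of the group variances). The
standard error of one ΔHDX is √2·s_p/√n, the SE of the sum over k
independent timepoints √k times that, and the symmetric threshold is

    summed CI = t_{1−α/2, df} · √k · √2 · s_p / √n ,   df = Σ_groups (n−1).

The global pooling follows the standard error-propagation logic for HDX
difference data: a single experiment-wide precision estimate is both
more stable than per-peptide SDs at n = 3 and conservative for the
quietest peptides. Accumulation uses exact summation (`math.fsum`) so
the threshold is bit-identical under control/variant swap.

**t-test.** A two-sided, unpaired, equal-variance Student t-test on the
per-replicate summed uptake (each replicate's uptake summed across
timepoints), df = n_v + n_c − 2 = 4 at triplicates, α = 0.01. Identical
zero-variance groups are assigned p = 1 (p = 0 if the means differ) —
scipy returns NaN there. A Welch option and a Benjamini–Hochberg
correction exist behind flags; both default off, matching common
practice for HDX screening where the CI gate already controls the bulk
of false positives (the measured null false-positive rate of the dual
gate is well below α; see the null-calibration test).

Requiring both gates is deliberately conservative. At n = 3 the t-gate
is the binding one: its minimum detectable summed ΔHDX at 90% power
(noncentral-t calculation, `minimum_detectable_summed_delta`) is about
0.48 Da at 0.05 Da replicate noise, versus a CI threshold near 0.18 Da.
Peptides whose true effect falls between those two values are real but
under-powered; they come out "none", never with the wrong sign.

## Peptide-to-residue consolidation

A residue takes the sign of the significant peptides covering it;
conflicting coverage is resolved by majority among significant peptides,
with ties going to "none" and logged loudly (real datasets rarely show
conflicting segments; the simulator produces them at face boundaries
where long peptides straddle two loops). Residues covered only by
non-significant peptides are "none"; residues with no peptide at all are
"no_coverage". Full peptide spans are mapped, not redundancy-reduced
overlaps. The binary color scheme (no magnitude gradient) is written
into PDB B-factors as +1.00 / −1.00 / 0.00 / 99.00 using the fixed-width
%6.2f convention, which makes the writer byte-reproducible; a
magnitude-graded Woods-plot rendering exists for diagnostics only.

## The synthetic two-state model

The simulator emulates a 12-TM alternating-access transporter whose
outward-facing (OF) and inward-facing (IF) conformations interconvert
fast relative to intrinsic exchange (EX2 limit), so each residue
exchanges with the population-weighted rate

    k_obs,i = k_int,i · [ f_IF / P_IF,i + (1 − f_IF) / P_OF,i ],
    uptake fraction(t) = 1 − exp(−k_obs,i · t),

and a peptide's noiseless uptake is D times the sum over its
exchangeable amides. EX1 bimodality is intentionally out of scope: the
analysis consumes centroid uptake only.

Defaults, and why:

- **Topology**: alternating 8-residue loops (extracellular,
  intracellular) and 17-residue TM helices, starting extracellular —
  loop and helix lengths typical of MFS transporters.
- **Protection factors (log10)**: loops 1.0 baseline; the face that is
  closed in a given conformation gets +1.0 (intracellular face protected
  in OF, extracellular in IF); TM helices 3.0 in both states, i.e.
  strongly protected and state-independent, so they contribute no
  differential signal. The 1.0 contrast was chosen by design
  calculation: with a 0.3 population shift it yields per-amide summed
  ΔHDX contributions of ~0.1–0.2 Da, putting multi-amide loop peptides
  comfortably above the ~0.18 Da threshold at 0.05 Da noise. It is a
  tunable, not a measured quantity.
- **Intrinsic rates**: log-uniform in 1–1000 min⁻¹ per residue, spanning
  the 30 s–150 min observation window; a hook accepts user-supplied
  per-residue rate tables (e.g. sequence-based reference rates), none is
  bundled. A consequence of the wide range is that some residues are
  fully exchanged by the first timepoint in both states and carry no
  differential information — as in real data.
- **Populations**: control at f_IF = 0.5; variant shifted ±0.3
  ("toward_IF"/"toward_OF") or equal ("none").
- **Noise**: i.i.d. Gaussian per replicate, SD 0.05 Da (typical
  instrument repeatability), truncated at zero. Back-exchange is not
  simulated.
- **Digestion**: overlapping peptides, lengths uniform in 5–25, random
  starts, drawn until a residue-coverage target (default 80%, matching
  realistic membrane-protein coverage) and optionally a minimum peptide
  count are reached; the achieved coverage is reported and a bounded
  attempt count prevents silent infinite loops.
- **Timepoint schemes**: 30 s / 5 min / 30 min (detergent micelles) and
  5 / 30 / 150 min (nanodiscs).

What the simulator does *not* reproduce about real data: correlated
replicate errors, back-exchange, EX1 envelopes, peptide-dependent
ionization or retention effects, and carry-over. Passing tests therefore
demonstrate that the statistics and mapping are correct and calibrated
under the stated noise model, not that any instrument artifact is
handled.

**Affected-region peptides and recovery rates.** For validation, a
peptide "reads" one face when its exchangeable amides overlap
intracellular or extracellular loops (not both) with at least 3 amides —
one amide's contribution is comparable to the threshold, so smaller
overlaps are not reliably informative. Recovery statistics are evaluated
over the subset of those peptides whose noiseless summed ΔHDX reaches
the design's 90%-power minimum detectable effect: effects below the
sensitivity limit cannot be recovered by any procedure at the stated
noise level, so recall is only meaningful above it. Both definitions are
fixed by the power analysis, not fitted to outcomes.

## Gate geometry

The intracellular gate distance is the center-of-mass distance between
two groups of Cα atoms on opposite lobes; the bundled XylE definition is
residues 75–80, 149–154, 160–165 versus 332–337, 391–397, 404–410.
Masses are standard atomic masses by element — for Cα-only selections
this is nearly uniform weighting, but mass weighting is kept for
fidelity to the COM definition. Trajectories are read from multi-model
PDB (MODEL/ENDMDL, via MDAnalysis) or from a documented plain-text
frames table; binary MD formats are out of scope, as cluster-scale
trajectories are not desk-reproducible anyway. Frame times come from an
explicit list or a stated frame interval and are never guessed. The
trailing distribution (default window 200 ns) is a density-normalized
histogram over frames with t ≥ t_end − window; a single-valued window
degenerates to one unit-width bin of density 1.

## Numerical and interface choices

- Exposures are stored in seconds; readers accept "s"/"min"/"h" suffixes,
  bare numbers meaning minutes in the DynamX-style cluster dialect and
  seconds in the long dialect.
- Cluster tables carry no replicate ids, so replicate values are stored
  sorted within each group, making parsing order-invariant; the long
  dialect orders by its explicit replicate id. This only affects the
  (arbitrary) pairing of replicates across timepoints in the summed
  t-test.
- Tables round-trip at 6 significant digits; differential and Woods
  tables are written at 12 significant digits so re-reading preserves
  the summed-delta/per-timepoint consistency invariant (1e-9 Da).
- Mean+SD cluster rows (no raw replicates) are expanded to
  {mean − SD, mean, mean + SD} placeholders and flagged; incomplete
  replicate groups are kept but skipped by the statistics with a logged
  warning.
- Timepoint-scheme mismatches between the two compared states are a hard
  error, never silently intersected.
- Simulation sizes used in the validation suite — 300 residues, ~60
  peptides for the shift studies, 1000 peptides for the null
  calibration, 500-frame toy trajectories — were chosen as the smallest
  sizes at which the binomial error bands and pattern statistics are
  meaningful.

## Known limitations

- The pooled-SD threshold assumes homoscedastic replicate noise across
  peptides and timepoints; strongly heteroscedastic data would make it
  anti-conservative for the noisiest peptides (the t-gate mitigates
  this).
- Residue-level output is a consolidation of peptide spans, not a
  residue-resolved exchange-rate fit; resolution is limited by peptide
  overlap.
- The t-test at n = 3 has low power; effects below ~0.5 Da summed ΔHDX
  at 0.05 Da noise are frequently (and silently) classified "none".
- The simulator's EX2 assumption means slow conformational exchange
  (EX1) data would violate the model; the analysis side is agnostic but
  the calibration results would not transfer.
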