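"""Differential statistics: RFU, ΔHDX, pooled-SD threshold, dual gate."""

import math

import numpy as np
import pytest
import scipy.stats as sps

import hdxdiff as hd
from hdxdiff.errors import ParameterError, ValidationError


def _dataset(groups, timepoints=(30.0, 300.0, 1800.0), state="S", n_rep=3):
    """Build a single-state dataset from {(start, seq): {t: replicates}}."""
    cond = hd.LabelingConditions(timepoints=timepoints, n_replicates=n_rep)
    ds = hd.PeptideUptakeDataset(cond)
    for (start, seq), per_t in groups.items():
        pep = hd.Peptide.from_sequence("P1", start, seq)
        for t, reps in per_t.items():
            ds.add(hd.UptakeMeasurement(pep, state, float(t), tuple(reps)))
    return ds


def _pair(c_reps, v_reps, seq="GASPLKA", start=1):
    """Control/variant datasets with the same replicate set per timepoint."""
    tps = (30.0, 300.0, 1800.0)
    c = _dataset({(start, seq): {t: c_reps for t in tps}}, tps, state="ctrl")
    v = _dataset({(start, seq): {t: v_reps for t in tps}}, tps, state="var")
    return c, v


class TestRFU:
    def test_zero_uptake(self):
        assert hd.relative_fractional_uptake(0.0, 10, 0.95) == 0.0

    def test_saturation_is_one(self):
        assert hd.relative_fractional_uptake(9.5, 10, 0.95) == pytest.approx(1.0)

    def test_formula_arithmetic(self):
        assert hd.relative_fractional_uptake(2.0, 10, 0.95) == pytest.approx(
            2.0 / 9.5
        )

    def test_no_exchangeable_amides_is_undefined(self):
        with pytest.raises(ParameterError):
            hd.relative_fractional_uptake(1.0, 0, 0.95)


class TestDeltaUptake:
    def test_identical_replicates_give_zero(self):
        c, v = _pair([1.0, 1.1, 0.9], [1.0, 1.1, 0.9])
        pep = c.peptides()[0]
        mean, se = hd.delta_uptake(c, v, pep, 30.0)
        assert mean == 0.0

    def test_constant_shift(self):
        c, v = _pair([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])
        mean, se = hd.delta_uptake(c, v, c.peptides()[0], 30.0)
        assert (mean, se) == (1.0, 0.0)

    def test_against_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            cr = rng.uniform(0, 3, 3)
            vr = rng.uniform(0, 3, 3)
            c, v = _pair(list(cr), list(vr))
            mean, se = hd.delta_uptake(c, v, c.peptides()[0], 30.0)
            # independent elementwise formulas
            mc = sum(cr) / 3
            mv = sum(vr) / 3
            s2c = sum((x - mc) ** 2 for x in cr) / 2
            s2v = sum((x - mv) ** 2 for x in vr) / 2
            assert mean == pytest.approx(mv - mc, abs=1e-10)
            assert se == pytest.approx(math.sqrt(s2v / 3 + s2c / 3), abs=1e-10)


class TestHoudeThreshold:
    def test_zero_spread_gives_zero_threshold(self):
        c, v = _pair([1.0, 1.0, 1.0], [1.5, 1.5, 1.5])
        th = hd.houde_threshold(c, v)
        assert th.pooled_sd == 0.0
        assert th.summed_ci == 0.0

    def test_threshold_linear_in_sd(self):
        c1, v1 = _pair([1.0, 1.1, 1.2], [2.0, 2.1, 2.2])
        c2, v2 = _pair([1.0, 1.2, 1.4], [2.0, 2.2, 2.4])
        a = hd.houde_threshold(c1, v1).summed_ci
        b = hd.houde_threshold(c2, v2).summed_ci
        assert b == pytest.approx(2 * a)

    def test_closed_form_on_constructed_input(self):
        """Every group has SD 0.1; n=3, k=3, so the threshold is
        t_{0.995, df} * sqrt(3) * sqrt(2/3) * 0.1."""
        c, v = _pair([1.0, 1.1, 1.2], [2.0, 2.1, 2.2])
        th = hd.houde_threshold(c, v, alpha=0.01)
        sd = np.std([1.0, 1.1, 1.2], ddof=1)
        df = 6 * (3 - 1)  # 2 states x 3 timepoints x (n-1)
        expected = sps.t.ppf(0.995, df) * math.sqrt(3) * math.sqrt(2 / 3) * sd
        assert th.pooled_sd == pytest.approx(sd, abs=1e-12)
        assert th.df == df
        assert th.summed_ci == pytest.approx(expected, abs=1e-12)


class TestClassification:
    def test_identical_datasets_are_none_with_p_one(self):
        c, v = _pair([1.0, 1.1, 1.2], [1.0, 1.1, 1.2])
        th = hd.houde_threshold(c, v)
        rec = hd.classify_peptide(c, v, c.peptides()[0], th)
        assert rec.classification is hd.Classification.NONE
        assert rec.p_value == pytest.approx(1.0)
        assert rec.summed_delta == pytest.approx(0.0)

    def test_large_separation_is_positive(self):
        c, v = _pair([1.0, 1.001, 0.999], [3.0, 3.001, 2.999])
        th = hd.houde_threshold(c, v)
        rec = hd.classify_peptide(c, v, c.peptides()[0], th)
        assert rec.classification is hd.Classification.POSITIVE
        assert rec.p_value < 1e-6

    def test_borderline_p_fails_the_dual_gate(self):
        """summed Δ above the CI but p ≈ 0.02 > 0.01 → not significant.

        Replicates [x−d, x, x+d] at every timepoint give per-replicate
        summed-uptake SD 3d in each group; choosing the per-timepoint
        shift m = t* · d·√(2/3) makes the t statistic exactly t*, i.e.
        two-sided p exactly 0.02.
        """
        t_star = sps.t.ppf(1 - 0.02 / 2, 4)  # df = 2(n-1) = 4
        d = 0.05
        m = t_star * d * math.sqrt(2 / 3)  # shift per timepoint
        c, v = _pair([1.0 - d, 1.0, 1.0 + d],
                     [1.0 + m - d, 1.0 + m, 1.0 + m + d])
        th = hd.houde_threshold(c, v)
        rec = hd.classify_peptide(c, v, c.peptides()[0], th)
        assert rec.p_value == pytest.approx(0.02, abs=1e-9)
        assert abs(rec.summed_delta) > th.summed_ci
        assert rec.classification is hd.Classification.NONE

    def test_summed_delta_consistent_with_per_timepoint(self, simulated_pair):
        res = hd.run_differential(*simulated_pair)
        for r in res.records:
            assert r.summed_delta == pytest.approx(
                sum(d.mean for d in r.deltas), abs=1e-9
            )


class TestTTestOracle:
    def test_pvalues_match_textbook_formula(self):
        """Equal-variance two-sample t on 100 random replicate sets,
        against an explicit pooled-variance implementation."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            cr = rng.normal(1.0, 0.3, 3)
            vr = rng.normal(1.2, 0.3, 3)
            c, v = _pair(list(cr), list(vr))
            th = hd.houde_threshold(c, v)
            rec = hd.classify_peptide(c, v, c.peptides()[0], th)
            cs, vs = 3 * cr, 3 * vr  # summed uptake over 3 equal timepoints
            sp2 = (np.var(vs, ddof=1) * 2 + np.var(cs, ddof=1) * 2) / 4
            t = (vs.mean() - cs.mean()) / math.sqrt(sp2 * (2 / 3))
            p = 2 * sps.t.sf(abs(t), 4)
            assert rec.t_statistic == pytest.approx(t, abs=1e-10)
            assert rec.p_value == pytest.approx(p, abs=1e-10)

    def test_welch_option(self):
        rng = np.random.default_rng(8)
        cr = rng.normal(1.0, 0.1, 3)
        vr = rng.normal(1.5, 0.5, 3)
        c, v = _pair(list(cr), list(vr))
        th = hd.houde_threshold(c, v)
        rec = hd.classify_peptide(
            c, v, c.peptides()[0], th, hd.DifferentialConfig(welch=True)
        )
        ref = sps.ttest_ind(3 * vr, 3 * cr, equal_var=False)
        assert rec.p_value == pytest.approx(ref.pvalue, abs=1e-12)


class TestRunDifferential:
    def test_self_comparison_all_none(self, simulated_pair):
        control, _ = simulated_pair
        res = hd.run_differential(control, control)
        assert all(r.classification is hd.Classification.NONE
                   for r in res.records)

    def test_antisymmetry(self, simulated_pair):
        control, variant = simulated_pair
        fwd = hd.run_differential(control, variant)
        rev = hd.run_differential(variant, control)
        assert fwd.thresholds.summed_ci == pytest.approx(
            rev.thresholds.summed_ci, abs=1e-12
        )
        f = {r.peptide: r for r in fwd.records}
        for r in rev.records:
            assert r.summed_delta == pytest.approx(
                -f[r.peptide].summed_delta, abs=1e-9
            )
        cf, cr = fwd.counts(), rev.counts()
        assert cf["positive"] == cr["negative"]
        assert cf["negative"] == cr["positive"]
        assert cf["none"] == cr["none"]

    def test_timepoint_mismatch_is_hard_error(self):
        tps1, tps2 = (30.0, 300.0, 1800.0), (300.0, 1800.0, 9000.0)
        c = _dataset({(1, "GASPLKA"): {t: [1, 1, 1] for t in tps1}}, tps1, "c")
        v = _dataset({(1, "GASPLKA"): {t: [1, 1, 1] for t in tps2}}, tps2, "v")
        with pytest.raises(ValidationError, match="mismatch"):
            hd.run_differential(c, v)

    def test_unshared_peptides_reported_as_no_coverage(self):
        tps = (30.0, 300.0, 1800.0)
        c = _dataset({(1, "GASPLKA"): {t: [1, 1, 1] for t in tps},
                      (10, "AAAAAA"): {t: [1, 1, 1] for t in tps}}, tps, "c")
        v = _dataset({(1, "GASPLKA"): {t: [1, 1, 1] for t in tps}}, tps, "v")
        res = hd.run_differential(c, v)
        assert len(res.records) == 1
        assert [p.sequence for p in res.no_coverage] == ["AAAAAA"]

    def test_shift_monotonicity_noise_free(self):
        """A larger population shift never yields fewer correctly-signed
        significant peptides (noise-free uptake, fixed threshold scale)."""
        base = hd.default_transporter_scenario(200, "toward_IF", seed=9,
                                               delta_population=0.1)
        dig = hd.digest_in_silico(base.sequence, 0.8, seed=9)
        cond = hd.LabelingConditions.detergent()
        counts = []
        for dpop in (0.1, 0.2, 0.3, 0.4):
            scen = hd.default_transporter_scenario(
                200, "toward_IF", seed=9, delta_population=dpop
            )
            c = hd.simulate_dataset(scen, dig.peptides, cond, "control",
                                    hd.NoiseModel(0.0, 0))
            v = hd.simulate_dataset(scen, dig.peptides, cond, "variant",
                                    hd.NoiseModel(0.0, 0))
            # noise-free data: gate on a fixed nominal threshold instead of
            # the degenerate zero-variance one
            thr = 0.18
            ok = 0
            for pep, sign in hd.affected_peptides(scen, dig.peptides):
                true = hd.noiseless_summed_delta(scen, pep, cond)
                if sign > 0 and true > thr or sign < 0 and true < -thr:
                    ok += 1
            counts.append(ok)
        assert counts == sorted(counts)

    def test_fdr_option_only_reduces_calls(self, simulated_pair):
        plain = hd.run_differential(*simulated_pair)
        fdr = hd.run_differential(
            *simulated_pair, hd.DifferentialConfig(fdr_bh=True)
        )
        n_sig = lambda r: sum(
            rec.classification is not hd.Classification.NONE
            for rec in r.records
        )
        assert n_sig(fdr) <= n_sig(plain)

    def test_tsv_round_trip(self, tmp_path, simulated_pair):
        res = hd.run_differential(*simulated_pair)
        path = tmp_path / "diff.tsv"
        hd.write_differential_tsv(res, path)
        records, ci = hd.read_differential_tsv(path)
        assert ci == pytest.approx(res.thresholds.summed_ci, rel=1e-9)
        assert len(records) == len(res.records)
        for a, b in zip(records, res.records):
            assert a.peptide == b.peptide
            assert a.summed_delta == pytest.approx(b.summed_delta, rel=1e-9)
            assert a.classification == b.classification


class TestPowerAnalysis:
    def test_mde_reaches_requested_power(self):
        mde = hd.minimum_detectable_summed_delta(0.05)
        assert hd.dual_gate_power(mde, 0.05) == pytest.approx(0.9, abs=1e-3)
        # effects below the MDE have less power
        assert hd.dual_gate_power(0.5 * mde, 0.05) < 0.9

    def test_power_increases_with_effect(self):
        grid = [hd.dual_gate_power(d, 0.05) for d in (0.1, 0.3, 0.5, 0.8)]
        assert all(b > a for a, b in zip(grid, grid[1:]))
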