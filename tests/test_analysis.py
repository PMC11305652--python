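"""Tests for β estimation, baseline selection, derivation and statistics."""

import math

import numpy as np
import pytest

from sidexp import core
from sidexp.analysis import (
    DegenerateVarianceError,
    FenclVariant,
    InsufficientDataError,
    MissingBaselineError,
    bland_altman,
    compare_groups,
    derive_series,
    estimate_beta,
    fencl_stewart_partition,
    pearson_corr,
    run_experiment,
    select_baseline,
)
from sidexp.types import ElectrolytePanel

from conftest import make_series


class TestEstimateBeta:
    def test_noiseless_line(self):
        pairs = [(ph, 250.0 - 30.0 * ph) for ph in (7.1, 7.25, 7.4, 7.55)]
        assert estimate_beta(make_series(pairs)) == pytest.approx(30.0)

    def test_two_point_slope(self):
        series = make_series([(7.2, 27.0), (7.6, 15.0)])
        assert estimate_beta(series) == pytest.approx(30.0)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            estimate_beta(make_series([(7.4, 24.0)]))
        with pytest.raises(InsufficientDataError):
            estimate_beta(make_series([(7.4, 24.0), (7.4, 25.0)]))

    def test_monte_carlo_recovery(self):
        """β̂ over noisy titration curves: central 95% within ±2, median < 1."""
        rng = np.random.default_rng(42)
        true_beta = 28.5
        ph = np.linspace(7.0, 7.6, 10)
        errors = []
        for _ in range(1000):
            hco3 = 235.0 - true_beta * ph + rng.normal(0, 0.3, ph.size)
            slope, _ = np.polyfit(ph, hco3, 1)
            errors.append(-slope - true_beta)
        errors = np.abs(errors)
        assert np.median(errors) < 1.0
        assert np.quantile(errors, 0.95) < 2.0


class TestSelectBaseline:
    def test_exp1_takes_5pct_step(self, table1):
        step = select_baseline(table1["healthy_mean"], "exp1")
        assert step.fco2 == pytest.approx(0.05)

    def test_exp2_takes_12pct_step(self, table2):
        step = select_baseline(table2["diluted_mean"], "exp2")
        assert step.fco2 == pytest.approx(0.12)

    def test_exp3_takes_pco2_nearest_40(self):
        series = make_series([(7.60, 18.0), (7.40, 24.5), (7.10, 33.0)],
                             pco2=(18.2, 39.9, 79.9))
        assert select_baseline(series, "exp3").gas.pco2 == pytest.approx(39.9)

    def test_exp3_single_step(self, table3):
        ctr = next(s for s in table3 if s.is_control)
        assert select_baseline(ctr, "exp3") is ctr.steps[0]

    def test_missing_co2_level_raises(self):
        series = make_series([(7.6, 18.0), (7.1, 33.0)], fco2_start=0.10)
        with pytest.raises(MissingBaselineError):
            select_baseline(series, "exp1")


class TestDeriveSeries:
    def test_baseline_identities(self, table1, params):
        derived = derive_series(table1["healthy_mean"], params,
                                experiment="exp1")
        base = [d for d in derived if d.is_baseline]
        assert len(base) == 1
        d = base[0]
        assert d.sid_exp == d.sid
        assert d.sid_exp_beta == d.sid
        assert d.sid_exp_clsi == d.sid
        assert d.delta_sid == 0.0
        assert d.delta_be == pytest.approx(0.0, abs=1e-12)
        assert d.delta_sid_wb == pytest.approx(0.0, abs=1e-12)

    def test_acid_load_rows_reproduce_published_deltas(self, table3, params):
        """Group-mean pseudo-series reproduce the published ΔBE and ΔSID_wb."""
        report = run_experiment(table3, "exp3", params)
        d = report.derived.set_index(["acid_kind", "acid_load"])
        published = {("lactic", 7.5): (-6.6, -6.7), ("hcl", 7.5): (-6.8, -6.7),
                     ("lactic", 15.0): (-13.4, -14.0), ("hcl", 15.0): (-13.6, -13.5)}
        for key, (dbe, dsid_wb) in published.items():
            row = d.loc[key]
            assert row["delta_be"] == pytest.approx(dbe, abs=0.15)
            assert row["delta_sid_wb"] == pytest.approx(dsid_wb, abs=0.2)

    def test_isolated_plasma_skips_beta_route(self, params):
        series = make_series([(7.6, 18.0), (7.46, 22.8), (7.2, 30.0)],
                             fco2_start=0.01)  # steps at 1/3/5% CO2
        plasma_steps = tuple(
            type(s)(fco2=s.fco2, gas=s.gas, electrolytes=s.electrolytes,
                    sample_kind=type(s.sample_kind).isolated_plasma)
            for s in series.steps)
        plasma = type(series)(subject_id="pl", group=series.group,
                              proteins=type(series.proteins)(4.8, 0.0),
                              steps=plasma_steps)
        derived = derive_series(plasma, params, experiment="exp1")
        for d in derived:
            assert d.z_hemoglobin == 0.0
            assert d.sid_exp_beta is None and d.be is None
            assert d.delta_sid_wb is None


class TestBlandAltman:
    def test_known_small_case(self):
        res = bland_altman([(1, 2), (2, 2), (3, 2)])
        assert res.bias == pytest.approx(0.0)
        assert res.sd_diff == pytest.approx(1.0)
        assert (res.loa_low, res.loa_high) == (pytest.approx(-1.96),
                                               pytest.approx(1.96))
        assert res.max_abs_diff == 1.0
        assert res.acceptable

    def test_identical_vectors(self):
        res = bland_altman([(x, x) for x in (1.0, 2.0, 5.0)])
        assert res.bias == 0.0 and res.sd_diff == 0.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        pairs = list(zip(rng.normal(10, 2, 100), rng.normal(9, 2, 100)))
        res = bland_altman(pairs)
        diffs = [a - b for a, b in pairs]
        mean = sum(diffs) / len(diffs)
        var = sum((d - mean) ** 2 for d in diffs) / (len(diffs) - 1)
        assert res.bias == pytest.approx(mean)
        assert res.sd_diff == pytest.approx(math.sqrt(var))
        assert res.loa_high == pytest.approx(mean + 1.96 * math.sqrt(var))
        assert res.max_abs_diff == pytest.approx(max(abs(d) for d in diffs))

    def test_acceptability_thresholds(self):
        ok = bland_altman([(1.5, 1.0), (2.5, 2.0), (0.5, 0.0)])
        assert ok.acceptable  # bias 0.5, max diff 0.5
        big = bland_altman([(4.0, 0.0), (0.0, 0.0), (0.1, 0.0)])
        assert not big.acceptable  # max diff 4 >= 3

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            bland_altman([(1, 1)])


class TestCompareGroups:
    def test_identical_groups(self):
        assert compare_groups([1, 2, 3], [1, 2, 3]) == (0.0, 1.0)

    def test_clear_separation(self):
        _, p = compare_groups([1, 2, 3], [11, 12, 13])
        assert p < 0.001

    def test_matches_textbook_formula(self):
        a, b = [4.1, 5.2, 6.3, 5.8], [3.0, 3.9, 4.4]
        t, p = compare_groups(a, b)
        na, nb = len(a), len(b)
        ma, mb = np.mean(a), np.mean(b)
        sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) \
            / (na + nb - 2)
        t_manual = (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))
        assert t == pytest.approx(t_manual)
        assert 0 < p < 1

    def test_degenerate_variance(self):
        with pytest.raises(DegenerateVarianceError):
            compare_groups([1.0, 1.0], [2.0, 2.0])


def test_pearson_matches_manual():
    rng = np.random.default_rng(8)
    x = rng.normal(size=50)
    y = 0.6 * x + rng.normal(scale=0.5, size=50)
    r, p = pearson_corr(x, y)
    r_manual = float(np.corrcoef(x, y)[0, 1])
    assert r == pytest.approx(r_manual)
    assert p < 0.001


class TestFenclStewart:
    def test_reference_state_all_zero(self):
        e = ElectrolytePanel(140, 4.0, 1.2, 2.0, 102, 0.0)
        part = fencl_stewart_partition(e, 4.2, 0.0)
        assert part.sodium_chloride_effect == pytest.approx(0.0)
        assert part.albumin_effect == pytest.approx(0.0)
        assert part.lactate_effect == 0.0
        assert part.unmeasured_ions == pytest.approx(0.0)

    def test_components_sum_to_be(self):
        e = ElectrolytePanel(138, 4.0, 1.2, 2.0, 115, 2.5)
        part = fencl_stewart_partition(e, 3.0, -10.0)
        total = (part.sodium_chloride_effect + part.albumin_effect
                 + part.lactate_effect + part.unmeasured_ions)
        assert total == pytest.approx(-10.0)
        assert part.sodium_chloride_effect < 0  # hyperchloremia

    def test_mixed_acidosis_fakes_unmeasured_ions(self, params):
        """At high CO2 with hyperchloremia the bedside partition leaves a
        spurious unmeasured-ion residual, while the redistribution-aware
        route attributes the whole BE to strong ions."""
        e = ElectrolytePanel(151.0, 4.2, 1.3, 2.0, 118.0, 1.5)  # SID 40.3
        be = -10.0
        part = fencl_stewart_partition(e, 4.8, be)
        assert abs(part.unmeasured_ions) >= 1.5
        # redistribution-aware accounting: SID deviation from its
        # β-expectation, converted to whole blood, recovers BE
        sid = core.compute_sid(e)
        sid_exp = core.expected_sid_beta(42.9, 7.40, 7.05,
                                         core.beta_clsi(13.9, params))
        r = core.bicarbonate_ratio(13.9, params)
        assert core.delta_sid_wb(sid, sid_exp, r) == pytest.approx(be, abs=3.0)

    def test_variant_without_lactate(self):
        e = ElectrolytePanel(140, 4.0, 1.2, 2.0, 102, 3.0)
        part = fencl_stewart_partition(e, 4.2, 0.0,
                                       FenclVariant(include_lactate=False))
        assert part.lactate_effect == 0.0


class TestRunExperiment:
    def test_fixture_agreement_bias_small(self, table3, params):
        report = run_experiment(table3, "exp3", params)
        res = report.agreements["dsidwb_vs_dbe_metabolic"]
        assert abs(res.bias) < 0.3
        assert res.n_pairs == 4

    def test_baseline_steps_excluded(self, table1, params):
        report = run_experiment(list(table1.values()), "exp1", params)
        # 2 groups x 4 steps, minus one baseline each
        assert report.agreements["sid_vs_sid_exp"].n_pairs == 6
        assert report.derived["is_baseline"].sum() == 2

    def test_identical_model_consistent_series(self, exp3_noiseless, params):
        """Replicating one noiseless simulated subject gives zero spread in
        every agreement and zero bias on the β-consistent routes."""
        series, _ = exp3_noiseless
        subject = [s for s in series if s.subject_id == "S001"]
        dataset = []
        for i in range(3):
            for s in subject:
                dataset.append(type(s)(subject_id=f"R{i}", group=s.group,
                                       proteins=s.proteins, steps=s.steps))
        report = run_experiment(dataset, "exp3", params, beta_mode="clsi")
        for key in ("sid_vs_sid_exp_beta", "dsidwb_vs_dbe_metabolic",
                    "dsidwb_vs_dbe_mixed"):
            res = report.agreements[key]
            assert res.bias == pytest.approx(0.0, abs=1e-9)
            assert res.max_abs_diff == pytest.approx(0.0, abs=1e-9)

    def test_group_comparison_present(self, table2, params):
        report = run_experiment(list(table2.values()), "exp2", params)
        assert "pearson_sid_vs_sid_exp" in report.group_stats
        r = report.group_stats["pearson_sid_vs_sid_exp"]["r"]
        assert r > 0.95
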