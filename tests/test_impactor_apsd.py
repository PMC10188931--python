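"""Unit and property tests for cascade-impactor APSD metrics."""

import math

import numpy as np
import pytest
from scipy.stats import norm

from ebcbe.impactor_apsd import (
    ImpactorRun,
    StageDeposit,
    apsd_metrics,
    compare_fpd,
    compute_fpd,
    compute_fpf,
    cumulative_undersize,
    estimate_gsd,
    estimate_mmad,
    fine_particle_percent,
    read_impactor_csv,
)
from ebcbe.synthetic_data import ImpactorSimConfig, simulate_impactor_run


def simple_run(masses, cuts=(8.0, 4.0, 2.0, 1.0), throat=50.0, **kw):
    deposits = [StageDeposit("Throat", None, throat)] + [
        StageDeposit(f"Stage {i+1}", c, m) for i, (c, m) in enumerate(zip(cuts, masses))
    ]
    return ImpactorRun("X", deposits, **kw)


class TestCumulativeUndersize:
    def test_bundled_reference_formulation_values(self, ngi_runs):
        curve = dict(cumulative_undersize(ngi_runs["MDI-1"]))
        # hand sums over the deposition table: 35.0/49.4 below the 4.0 um cut
        assert curve[4.0] == pytest.approx(100 * 35.0 / 49.4, abs=0.01)
        assert curve[0.4] == 0.0
        assert curve[11.8] == pytest.approx(100 * 44.4 / 49.4, abs=0.01)

    def test_single_sized_stage_is_zero_undersize(self):
        run = ImpactorRun(
            "X", [StageDeposit("Stage 1", 5.0, 10.0)]
        )
        assert cumulative_undersize(run) == [(5.0, 0.0)]

    def test_scale_invariance(self, ngi_runs):
        run = ngi_runs["MDI-1"]
        doubled = ImpactorRun(
            run.formulation_id,
            [
                StageDeposit(
                    d.stage_label, d.cut_size_um, d.amount * 2, d.amount_unit,
                    d.recovery_volume_ml,
                )
                for d in run.deposits
            ],
            n_actuations=run.n_actuations,
        )
        for (c1, p1), (c2, p2) in zip(
            cumulative_undersize(run), cumulative_undersize(doubled)
        ):
            assert c1 == c2 and p1 == pytest.approx(p2)

    def test_monotone_nonincreasing_in_cut_order(self, ngi_runs):
        for run in ngi_runs.values():
            pct = [p for _, p in cumulative_undersize(run)]
            assert all(a >= b for a, b in zip(pct, pct[1:]))

    def test_zero_sized_mass_rejected(self):
        with pytest.raises(ValueError, match="zero sized mass"):
            cumulative_undersize(simple_run([0, 0, 0, 0]))

    def test_mass_conservation(self, ngi_runs):
        run = ngi_runs["MDI-1"]
        assert run.sized_mass_ug + run.throat_mass_ug == pytest.approx(
            run.total_recovered_ug
        )
        assert run.sized_mass_ug == pytest.approx(494.0)  # 49.4 mg/L x 10 mL


class TestMMADAndGSD:
    def test_reference_formulation_mmad(self, ngi_runs):
        curve = cumulative_undersize(ngi_runs["MDI-1"])
        assert estimate_mmad(curve) == pytest.approx(2.85, abs=0.01)

    def test_test_formulation_mmad(self, ngi_runs):
        # hand interpolation between the 4.0 um (72.2%) and 2.3 um (44.0%) stages
        curve = cumulative_undersize(ngi_runs["MDI-2"])
        assert estimate_mmad(curve) == pytest.approx(2.59, abs=0.01)

    def test_mmad_between_bracketing_cuts(self, ngi_runs):
        for run in ngi_runs.values():
            curve = cumulative_undersize(run)
            mmad = estimate_mmad(curve)
            assert 2.3 < mmad < 4.0

    def test_synthetic_lognormal_recovery(self):
        cfg = ImpactorSimConfig(true_mmad_um=3.0, true_gsd=2.0, noise_cv=0.0)
        curve = cumulative_undersize(simulate_impactor_run(cfg))
        assert estimate_mmad(curve) == pytest.approx(3.0, rel=0.05)
        assert estimate_gsd(curve) == pytest.approx(2.0, rel=0.05)

    def test_scale_invariance_of_mmad_gsd(self, ngi_runs):
        run = ngi_runs["MDI-1"]
        curve = cumulative_undersize(run)
        tripled = ImpactorRun(
            "X",
            [
                StageDeposit(d.stage_label, d.cut_size_um, d.mass_ug * 3)
                for d in run.deposits
            ],
        )
        curve3 = cumulative_undersize(tripled)
        assert estimate_mmad(curve3) == pytest.approx(estimate_mmad(curve))
        assert estimate_gsd(curve3) == pytest.approx(estimate_gsd(curve))

    def test_unresolved_distribution_raises(self):
        # all mass on a single stage: neither tail quantile is bracketed
        curve = cumulative_undersize(simple_run([0, 100.0, 0, 0]))
        with pytest.raises(ValueError, match="not resolved"):
            estimate_gsd(curve)

    def test_median_not_bracketed_raises(self):
        # nearly all mass above the top cut
        curve = [(8.0, 10.0), (4.0, 5.0), (2.0, 1.0)]
        with pytest.raises(ValueError, match="not resolved"):
            estimate_mmad(curve)

    def test_probit_agrees_with_loglinear_on_lognormal_curves(self):
        for mmad, gsd in [(2.0, 1.8), (3.0, 2.0), (4.0, 2.2)]:
            cfg = ImpactorSimConfig(true_mmad_um=mmad, true_gsd=gsd, noise_cv=0.0)
            curve = cumulative_undersize(simulate_impactor_run(cfg))
            assert estimate_mmad(curve, "probit") == pytest.approx(
                estimate_mmad(curve, "loglinear"), rel=0.10
            )


class TestFPD:
    def test_all_mass_below_cutoff(self):
        run = simple_run([0.0, 10.0, 20.0, 30.0], throat=0.0)
        with pytest.warns(UserWarning, match="above largest cut"):
            fpd = compute_fpd(run, cutoff_um=20.0, dose_basis=None)
        assert fpd == pytest.approx(60.0)

    def test_cutoff_at_stage_cut_needs_no_interpolation(self):
        run = simple_run([10.0, 20.0, 30.0, 40.0], throat=0.0)
        # strictly below the 4.0 um cut: stages at 2.0 and 1.0
        assert compute_fpd(run, cutoff_um=4.0, dose_basis=None) == pytest.approx(70.0)

    def test_synthetic_lognormal_against_cdf_oracle(self):
        cfg = ImpactorSimConfig(
            true_mmad_um=3.0, true_gsd=2.0, noise_cv=0.0, throat_fraction=0.5,
            total_mass_ug=1000.0,
        )
        run = simulate_impactor_run(cfg)
        fpd = compute_fpd(run, cutoff_um=5.0, dose_basis=None)
        analytic = 500.0 * norm.cdf(math.log(5.0 / 3.0) / math.log(2.0))
        assert fpd == pytest.approx(analytic, rel=0.05)

    def test_dose_basis_scaling(self, ngi_runs):
        run = ngi_runs["MDI-1"]  # 10 actuations
        whole = compute_fpd(run, dose_basis=None)
        per_act = compute_fpd(run, dose_basis="per_actuation")
        per_two = compute_fpd(run, dose_basis=("per_dose", 2))
        assert per_act == pytest.approx(whole / 10)
        assert per_two == pytest.approx(whole / 5)


class TestFPF:
    @pytest.mark.parametrize(
        "fpd, dose, expected", [(37.4, 200.0, 18.7), (33.9, 200.0, 16.95)]
    )
    def test_percent_of_administered_dose(self, fpd, dose, expected):
        assert fine_particle_percent(fpd, dose) == pytest.approx(expected)

    def test_fpd_equal_to_denominator_is_100(self):
        assert fine_particle_percent(5.0, 5.0) == 100.0

    def test_metered_dose_denominator(self, ngi_runs):
        run = ngi_runs["MDI-1"]  # label claim 100 ug/actuation
        fpd = compute_fpd(run, dose_basis="per_actuation")
        fpf = compute_fpf(fpd, run, "metered_dose", dose_basis="per_actuation")
        assert fpf == pytest.approx(100 * fpd / 100.0)

    def test_total_recovered_denominator(self, ngi_runs):
        run = ngi_runs["MDI-1"]
        fpd = compute_fpd(run, dose_basis=None)
        fpf = compute_fpf(fpd, run, "total_recovered", dose_basis=None)
        assert fpf == pytest.approx(100 * fpd / run.total_recovered_ug)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            fine_particle_percent(1.0, 0.0)


class TestCompareFPD:
    def test_identical_groups_not_significant(self):
        res = compare_fpd([30.0, 31.0, 29.0], [30.0, 31.0, 29.0])
        assert not res.significant
        assert res.p_value > 0.9

    def test_separated_groups_significant(self):
        res = compare_fpd([30.0, 30.1, 29.9], [50.0, 50.1, 49.9])
        assert res.significant and res.p_value < 1e-4

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            compare_fpd([1.0], [2.0, 3.0])


class TestRunConstruction:
    def test_increasing_cut_sizes_rejected(self):
        with pytest.raises(ValueError, match="strictly decreasing"):
            simple_run([1, 2, 3, 4], cuts=(1.0, 2.0, 3.0, 4.0))

    def test_two_throats_rejected(self):
        with pytest.raises(ValueError, match="one throat"):
            ImpactorRun(
                "X",
                [StageDeposit("Throat", None, 1.0), StageDeposit("Throat2", None, 1.0)],
            )

    def test_concentration_amounts_convert_via_recovery_volume(self):
        d = StageDeposit("Stage 1", 5.0, 12.5, "mg_per_L", recovery_volume_ml=10.0)
        assert d.mass_ug == pytest.approx(125.0)

    def test_csv_reader_roundtrip(self, tmp_path, ngi_runs):
        from ebcbe.datasets import ngi_stage_deposition_path

        runs = read_impactor_csv(ngi_stage_deposition_path())
        assert [r.formulation_id for r in runs] == ["MDI-1", "MDI-2"]
        assert runs[0].n_actuations == 10
        m = apsd_metrics(runs[0])
        assert m.mmad_um == pytest.approx(2.85, abs=0.01)
        assert 1.0 <= m.gsd <= 3.5
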