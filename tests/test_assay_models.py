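"""Polarization, competition/melt fitting and fold-change classification."""

import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from erdesign.assay_models import (
    AffinityTable,
    AnisotropyReading,
    CompetitionCurve,
    MeltCurve,
    competition_model,
    fit_competition,
    fit_melt,
    fold_change,
    load_published_affinities,
    polarization,
    read_melt_table,
    read_plate_table,
)
from erdesign.synthetic_data import AssaySpec, MeltSpec, make_competition_curve, make_melt_curve


class TestPolarization:
    @pytest.mark.parametrize(
        "fp,fq,expected",
        [(100, 100, 0.0), (300, 100, 0.5), (100, 0, 1.0), (0, 100, -1.0)],
    )
    def test_examples(self, fp, fq, expected):
        assert polarization((fp, fq)) == pytest.approx(expected)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            polarization((0, 0))

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            AnisotropyReading(-1, 10)

    @settings(max_examples=50, deadline=None)
    @given(
        st.floats(min_value=0.01, max_value=1e6),
        st.floats(min_value=0.01, max_value=1e6),
    )
    def test_antisymmetric_and_bounded(self, fp, fq):
        p = polarization((fp, fq))
        assert polarization((fq, fp)) == pytest.approx(-p)
        assert -1.0 <= p <= 1.0


class TestFitCompetition:
    def test_noiseless_recovery(self):
        curve = make_competition_curve(AssaySpec(true_ic50=1e-8))[0]
        fit = fit_competition(curve)
        assert fit.converged
        assert fit.log_ic50 == pytest.approx(-8.0, abs=1e-4)
        assert fit.min == pytest.approx(50.0, abs=1e-3)
        assert fit.max == pytest.approx(300.0, abs=1e-3)

    def test_four_param_mode_recovers_hill(self):
        curve = make_competition_curve(AssaySpec(true_ic50=1e-8, hill=1.6))[0]
        fit = fit_competition(curve, mode="four_param")
        assert fit.converged
        assert fit.hill == pytest.approx(1.6, abs=1e-3)
        assert fit.log_ic50 == pytest.approx(-8.0, abs=1e-4)

    def test_constant_signal_flagged_not_raised(self):
        curve = CompetitionCurve(np.logspace(-11, -5, 12), np.full(12, 100.0))
        fit = fit_competition(curve)
        assert not fit.converged or abs(fit.max - fit.min) < 1e-6

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            CompetitionCurve(np.logspace(-9, -6, 4), np.zeros(4))

    def test_fitted_model_is_monotone_decreasing(self):
        curve = make_competition_curve(AssaySpec(true_ic50=3e-9, noise_sd=0.02, seed=5))[0]
        fit = fit_competition(curve)
        x = np.linspace(-11, -5, 200)
        y = competition_model(x, fit.min, fit.max, fit.log_ic50, fit.hill)
        assert np.all(np.diff(y) <= 1e-12)

    def test_midpoint_at_ic50(self):
        spec = AssaySpec(true_ic50=1e-8)
        y = competition_model(np.array([-8.0]), spec.min, spec.max, -8.0, 1.0)
        assert y[0] == pytest.approx((spec.min + spec.max) / 2)

    def test_noisy_recovery_small_scale(self):
        # 50 replicates at 10 nM with 3%-of-range noise: median within 5%
        ic50s = []
        for seed in range(50):
            curve = make_competition_curve(
                AssaySpec(true_ic50=1e-8, noise_sd=0.03, seed=seed)
            )[0]
            fit = fit_competition(curve)
            if fit.converged:
                ic50s.append(fit.ic50)
        med = np.median(ic50s)
        assert abs(med - 1e-8) / 1e-8 < 0.05


class TestFitMelt:
    def test_noiseless_recovery(self):
        curve = make_melt_curve(MeltSpec(true_tm=65.8, slope_width=2.0))
        fit = fit_melt(curve)
        assert fit.converged
        assert fit.tm == pytest.approx(65.8, abs=0.01)
        assert fit.slope_width == pytest.approx(2.0, abs=0.01)

    def test_signal_at_tm_is_baseline_midpoint(self):
        curve = make_melt_curve(MeltSpec(true_tm=59.5))
        fit = fit_melt(curve)
        from erdesign.assay_models import melt_model

        at_tm = melt_model(
            np.array([fit.tm]), fit.tm, fit.slope_width,
            fit.folded_baseline, fit.unfolded_baseline,
        )[0]
        assert at_tm == pytest.approx(
            (fit.folded_baseline + fit.unfolded_baseline) / 2, abs=1e-6
        )

    def test_noisy_recovery_small_scale(self):
        tms = []
        for seed in range(40):
            fit = fit_melt(make_melt_curve(MeltSpec(true_tm=59.5, noise_sd=0.02, seed=seed)))
            if fit.converged:
                tms.append(fit.tm)
        assert abs(np.median(tms) - 59.5) < 0.5

    def test_non_sigmoidal_flagged(self):
        t = np.linspace(25, 90, 66)
        rng = np.random.default_rng(0)
        curve = MeltCurve(t, rng.normal(0, 1, t.shape))
        fit = fit_melt(curve)  # must not raise
        assert isinstance(fit.converged, bool)

    def test_tm_within_range_required_for_convergence(self):
        curve = make_melt_curve(MeltSpec(true_tm=110.0))
        assert curve.warnings  # generator flags it
        fit = fit_melt(curve)
        assert not fit.converged


class TestFoldChange:
    def table(self):
        return load_published_affinities()

    def test_ethinylestradiol_example(self):
        entries = fold_change(self.table(), "wt", "M421F")
        ee2 = next(e for e in entries if e.ligand == "17alpha-ethinylestradiol")
        assert ee2.fold == pytest.approx(2.1 / 12)
        assert ee2.direction == "improved"

    def test_tamoxifen_not_significant(self):
        entries = fold_change(self.table(), "wt", "M421F")
        tam = next(e for e in entries if e.ligand == "tamoxifen")
        assert tam.direction == "ns"

    def test_self_comparison_all_unit_folds(self):
        entries = fold_change(self.table(), "wt", "wt")
        assert all(e.fold == 1.0 and e.direction == "ns" for e in entries)

    def test_reciprocal_under_receptor_exchange(self):
        fwd = {e.ligand: e for e in fold_change(self.table(), "wt", "M421F")}
        rev = {e.ligand: e for e in fold_change(self.table(), "M421F", "wt")}
        flip = {"improved": "worsened", "worsened": "improved", "ns": "ns"}
        for ligand, e in fwd.items():
            assert rev[ligand].fold == pytest.approx(1.0 / e.fold)
            assert rev[ligand].direction == flip[e.direction]

    def test_units_normalized_before_division(self):
        t = AffinityTable()
        t.add("wt", "x", 1000, 10, "nM")
        t.add("mut", "x", 1, 0.01, "uM")
        (e,) = fold_change(t, "wt", "mut")
        assert e.fold == pytest.approx(1.0)

    def test_bad_unit_rejected(self):
        t = AffinityTable()
        with pytest.raises(ValueError, match="unit"):
            t.add("wt", "x", 1, 0.1, "furlongs")


class TestTableIO:
    def test_plate_table_round_trip(self):
        spec = AssaySpec(true_ic50=1e-8, noise_sd=0.0)
        curve = make_competition_curve(spec)[0]
        rows = ["receptor\tligand\tconcentration\tunit\tF_parallel\tF_perpendicular"]
        for c, p in zip(curve.concentrations, curve.polarizations):
            # choose intensities reproducing P = p/1000 (plate P in mP here)
            fp = 1000 * (1 + p / 1000)
            fq = 1000 * (1 - p / 1000)
            rows.append(f"wt\tx\t{c}\tM\t{fp}\t{fq}")
        curves = read_plate_table(io.StringIO("\n".join(rows)))
        assert len(curves) == 1
        np.testing.assert_allclose(
            curves[0].polarizations * 1000, curve.polarizations, rtol=1e-9
        )

    def test_zero_concentration_wells_excluded(self):
        rows = ["receptor\tligand\tconcentration\tunit\tP"]
        for c in np.logspace(-10, -6, 6):
            rows.append(f"wt\tx\t{c}\tM\t0.1")
        rows.append("wt\tx\t0\tM\t0.3")
        curves = read_plate_table(io.StringIO("\n".join(rows)))
        assert len(curves[0].concentrations) == 6

    def test_melt_table(self):
        curve = make_melt_curve(MeltSpec(true_tm=61.5))
        text = "temperature\tsignal\n" + "\n".join(
            f"{t}\t{s}" for t, s in zip(curve.temperatures, curve.signals)
        )
        again = read_melt_table(io.StringIO(text), receptor="wt")
        fit = fit_melt(again)
        assert fit.tm == pytest.approx(61.5, abs=0.01)
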