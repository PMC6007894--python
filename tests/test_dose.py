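"""Dose-response characterisation, Hill fitting and synergy indices."""

import math

import numpy as np
import pytest

from pykmet.dose import (
    DoseResponseCurve,
    NoTransition,
    NotAchievable,
    bi_score,
    cdi_score,
    ci_score,
    combo_scores,
    compute_ICx,
    dose_matrix,
    dose_response,
    fit_hill,
    median_effect_fit,
    rank_combinations,
)


def hill_curve(doses, ymax=1.0, ymin=0.0, ic50=1.0, h=1.0, drug="X", readout="pERK"):
    doses = np.asarray(doses, float)
    resp = (ymax - ymin) / (1.0 + (doses / ic50) ** h) + ymin
    return DoseResponseCurve(drug, readout, doses, resp)


class TestSynergyScores:
    def test_bi_hand_value(self):
        assert bi_score(0.2, 0.3, 0.72) == pytest.approx(0.28 / 0.56, abs=1e-12)

    def test_bi_additive_inputs_give_exactly_one(self):
        for ea, eb in [(0.2, 0.3), (0.0, 0.0), (0.5, 0.7)]:
            eab = ea + eb - ea * eb
            assert bi_score(ea, eb, eab) == pytest.approx(1.0, abs=1e-9)

    def test_cdi_hand_value_and_additivity(self):
        assert cdi_score(0.8, 0.7, 0.28) == pytest.approx(0.5, abs=1e-12)
        assert cdi_score(0.6, 0.5, 0.3) == pytest.approx(1.0, abs=1e-9)

    def test_bi_equals_cdi_under_complement_mapping(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            fa, fb, fab = rng.uniform(0.05, 0.95, 3)
            assert bi_score(1 - fa, 1 - fb, 1 - fab) == pytest.approx(
                cdi_score(fa, fb, fab), rel=1e-12
            )

    def test_bi_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bi_score(1.0, 0.2, 0.3)
        with pytest.raises(ZeroDivisionError):
            bi_score(0.999999999999, 0.999999999999, 0.5)

    def test_ci_self_combination_is_one(self):
        doses = np.geomspace(0.01, 100, 25)
        a = hill_curve(doses, ic50=1.0, h=1.5)
        b = hill_curve(doses, ic50=2.0, h=1.5)
        # drug B absent; combination effect equals A alone at dA = its IC30
        dA = 1.0 * (0.3 / 0.7) ** (1 / 1.5)
        fa_combo = 1.0 / (1.0 + (dA / 1.0) ** 1.5)
        assert ci_score(a, b, (dA, 0.0), fa_combo) == pytest.approx(1.0, rel=1e-6)

    def test_ci_loewe_additive_identical_drugs(self):
        """Two copies of one drug split half/half give CI = 1 exactly."""
        doses = np.geomspace(0.01, 100, 25)
        a = hill_curve(doses, ic50=1.0, h=2.0)
        dx = 1.0 * (0.6 / 0.4) ** (1 / 2.0)  # dose alone for 60% inhibition
        combo_resp = 1.0 / (1.0 + (dx / 1.0) ** 2.0)
        ci = ci_score(a, a, (dx / 2, dx / 2), combo_resp)
        assert ci == pytest.approx(1.0, rel=1e-6)

    def test_median_effect_fit_recovers_parameters(self):
        doses = np.geomspace(0.01, 100, 25)
        c = hill_curve(doses, ic50=0.7, h=2.5)
        dm, m = median_effect_fit(c)
        assert dm == pytest.approx(0.7, rel=1e-6)
        assert m == pytest.approx(2.5, rel=1e-6)


class TestHillFit:
    def test_exact_recovery_from_model_class(self):
        doses = np.geomspace(0.01, 100, 21)
        fit = fit_hill(hill_curve(doses, ymax=1.0, ymin=0.0, ic50=1.0, h=1.0))
        assert fit.y_max == pytest.approx(1.0, abs=1e-6)
        assert fit.y_min == pytest.approx(0.0, abs=1e-6)
        assert fit.ic50 == pytest.approx(1.0, rel=1e-6)
        assert fit.hill == pytest.approx(1.0, rel=1e-6)

    def test_noisy_recovery_of_steep_coefficient(self):
        """Median |H - 4| < 0.3 over 50 seeded noisy replicates."""
        rng = np.random.default_rng(2024)
        doses = np.geomspace(0.01, 10, 15)
        errs = []
        for _ in range(50):
            clean = hill_curve(doses, ic50=0.5, h=4.0)
            noisy = DoseResponseCurve(
                "X", "pERK", doses,
                clean.responses * (1 + 0.01 * rng.standard_normal(len(doses))),
            )
            errs.append(abs(fit_hill(noisy).hill - 4.0))
        assert np.median(errs) < 0.3

    def test_flat_curve_raises_no_transition(self):
        doses = np.geomspace(0.01, 100, 11)
        flat = DoseResponseCurve("X", "pERK", doses, np.full(11, 0.98))
        with pytest.raises(NoTransition):
            fit_hill(flat)

    def test_dose_unit_rescaling_leaves_h_invariant(self):
        doses = np.geomspace(0.01, 100, 21)
        base = fit_hill(hill_curve(doses, ic50=2.0, h=3.0))
        scaled = fit_hill(hill_curve(doses * 1000, ic50=2000.0, h=3.0))
        assert scaled.hill == pytest.approx(base.hill, rel=1e-6)
        assert scaled.ic50 == pytest.approx(base.ic50 * 1000, rel=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_hill(hill_curve([0.1, 1.0, 10.0]))


class TestICx:
    def test_icx_ordering_and_target_accuracy(self, egf_ctx):
        ic25 = compute_ICx(egf_ctx, "Gefitinib", "pERK", 25)
        ic50 = compute_ICx(egf_ctx, "Gefitinib", "pERK", 50)
        ic75 = compute_ICx(egf_ctx, "Gefitinib", "pERK", 75)
        assert ic25 <= ic50 <= ic75
        # response at the returned IC50 reproduces the target level
        assert egf_ctx.response({"Gefitinib": ic50}, "pERK") == pytest.approx(
            0.50, abs=0.001
        )

    def test_small_inhibition_needs_small_dose(self, egf_ctx):
        tiny = compute_ICx(egf_ctx, "Gefitinib", "pERK", 0.5)
        ic25 = compute_ICx(egf_ctx, "Gefitinib", "pERK", 25)
        assert tiny < 0.2 * ic25

    def test_unreachable_target_reported(self, egf_ctx):
        with pytest.raises(NotAchievable):
            compute_ICx(egf_ctx, "Gefitinib", "pSTAT3", 99.99, max_expand=0)

    def test_invalid_percent_rejected(self, egf_ctx):
        with pytest.raises(ValueError):
            compute_ICx(egf_ctx, "Gefitinib", "pERK", 0.0)


class TestDoseResponse:
    def test_empty_dose_list_gives_empty_curve(self, egf_ctx):
        curve = dose_response(egf_ctx, "Gefitinib", "pERK", [])
        assert curve.doses.size == 0 and curve.responses.size == 0

    def test_curve_reproduces_context_responses_pointwise(self, egf_ctx):
        doses = [0.1, 1.0]
        curve = dose_response(egf_ctx, "PF396", "pSTAT3", doses)
        for d, r in zip(curve.doses, curve.responses):
            assert r == egf_ctx.response({"PF396": d}, "pSTAT3")

    def test_matrix_margins_equal_1d_curves(self, egf_ctx):
        da, db = [0.0, 0.3], [0.0, 2.0]
        surf = dose_matrix(egf_ctx, "Gefitinib", "PF396", "pERK", da, db)
        assert surf[0, 0] == pytest.approx(1.0, abs=1e-9)
        row = dose_response(egf_ctx, "Gefitinib", "pERK", da).responses
        col = dose_response(egf_ctx, "PF396", "pERK", db).responses
        np.testing.assert_allclose(surf[:, 0], row, rtol=1e-9)
        np.testing.assert_allclose(surf[0, :], col, rtol=1e-9)

    def test_gef_pf_surface_monotone_non_increasing(self, egf_ctx):
        da = [0.0, 0.3, 1.0, 3.0]
        db = [0.0, 1.0, 3.0, 10.0]
        surf = dose_matrix(egf_ctx, "Gefitinib", "PF396", "pERK", da, db)
        # sub-percent hormetic bumps from feedback compensation are tolerated
        assert np.all(np.diff(surf, axis=0) <= 0.01)
        assert np.all(np.diff(surf, axis=1) <= 0.01)

    def test_gefitinib_sensitises_to_pf396(self, ref_model, egf):
        """A Gefitinib background shifts the PF396 curve left (lower IC50)."""
        from pykmet.dose import Context

        alone = compute_ICx(Context(ref_model, stimulus=egf), "PF396", "pERK", 50)
        with_gef = compute_ICx(
            Context(ref_model, stimulus=egf, background={"Gefitinib": 0.3}),
            "PF396", "pERK", 50,
        )
        assert with_gef < alone


class TestRanking:
    def test_single_pair_table(self, egf_ctx):
        df = rank_combinations(egf_ctx, pairs=[("Gefitinib", "PF396")], level=25.0)
        assert len(df) == 1
        assert df.loc[0, "rank"] == 1
        assert df.loc[0, "BI_pERK"] < 1.0
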