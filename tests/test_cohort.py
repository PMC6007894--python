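"""Cohort normalisation, patient personalisation and stratification."""

import numpy as np
import pandas as pd
import pytest

from pykmet import cohort as co
from pykmet.cohort import (
    NODES,
    enrichment_test,
    normalize_cohort,
    responder_filter,
    stratify_quartiles,
    subtype_anova,
    StratificationResult,
)
from pykmet.simulate import simulate, steady_state


def make_cohort(values_by_sample, subtype="BL1"):
    rows = []
    for sid, vals in values_by_sample.items():
        row = {"sample_id": sid, "subtype": subtype}
        row.update({n: vals.get(n, 1.0) for n in NODES})
        rows.append(row)
    return pd.DataFrame(rows)


class TestNormalisation:
    def test_self_reference_gives_all_ones(self):
        cohort = make_cohort({"s1": {n: 2.0 for n in NODES}})
        out = normalize_cohort(cohort, mode="reference_sample", reference="s1")
        assert np.allclose(out[list(NODES)].to_numpy(), 1.0)

    def test_two_fold_over_bl1_median(self):
        cohort = make_cohort(
            {"a": {"EGFR": 1.0}, "b": {"EGFR": 3.0}, "c": {"EGFR": 2.0}}
        )
        cohort.loc[3] = {"sample_id": "x", "subtype": "M",
                         **{n: 1.0 for n in NODES}}
        cohort.loc[3, "EGFR"] = 4.0
        out = normalize_cohort(cohort)  # BL1 median of EGFR = 2.0
        assert out.loc[out["sample_id"] == "x", "EGFR"].iloc[0] == pytest.approx(2.0)

    @pytest.mark.parametrize("n_bl1", [3, 4])
    def test_median_matches_sorted_oracle(self, n_bl1):
        rng = np.random.default_rng(n_bl1)
        vals = rng.uniform(0.5, 3.0, n_bl1)
        cohort = make_cohort(
            {f"s{i}": {"PYK2": v} for i, v in enumerate(vals)}
        )
        srt = np.sort(vals)
        med = srt[n_bl1 // 2] if n_bl1 % 2 else 0.5 * (
            srt[n_bl1 // 2 - 1] + srt[n_bl1 // 2]
        )
        out = normalize_cohort(cohort)
        np.testing.assert_allclose(out["PYK2"], vals / med)

    def test_missing_value_imputed_and_flagged(self):
        cohort = make_cohort({"a": {}, "b": {}})
        cohort.loc[0, "CBL"] = np.nan
        out = normalize_cohort(cohort)
        assert out.loc[0, "CBL"] == 1.0
        assert bool(out.loc[0, "imputed_CBL"])

    def test_no_bl1_sample_rejected(self):
        cohort = make_cohort({"a": {}}, subtype="M")
        with pytest.raises(ValueError, match="BL1"):
            normalize_cohort(cohort)


class TestReverseFunction:
    def test_base_point_maps_to_unit_fold(self, reverse_tables):
        assert reverse_tables["PYK2"].predict(1.0, 1.0) == pytest.approx(1.0, rel=0.02)

    def test_linear_birth_death_doubles_with_synthesis(self, ref_model):
        """With the transcriptional feedback silenced, Y is exactly ks/kd."""
        quiet = ref_model.with_params(
            ref_model.params.scaled({"w_f2": 1e-9})
        )
        t = co.build_reverse_function(quiet, "PYK2", scale_range=(0.5, 2.0),
                                      n_grid=5)
        assert t.predict(2.0, 1.0) == pytest.approx(2.0, rel=1e-3)
        assert t.predict(1.0, 2.0) == pytest.approx(0.5, rel=1e-3)

    def test_out_of_range_fold_reported(self, reverse_tables):
        with pytest.raises(ValueError, match="range"):
            reverse_tables["PYK2"].invert(1e9)

    def test_single_axis_rules(self, reverse_tables):
        t = reverse_tables["PYK2"]
        ks, kd = t.invert(3.0, rule="synthesis_only")
        assert kd == t.kd_base and ks > t.ks_base
        ks2, kd2 = t.invert(3.0, rule="degradation_only")
        assert ks2 == t.ks_base and kd2 < t.kd_base


class TestPatientModels:
    def test_all_ones_vector_gives_identical_dynamics(self, ref_model,
                                                      reverse_tables,
                                                      basal_state):
        pm = co.build_patient_model(
            ref_model, {n: 1.0 for n in NODES}, reverse_tables
        )
        grid = np.linspace(0, 10, 6)
        a = simulate(ref_model, basal_state, t_grid=grid)
        b = simulate(pm, basal_state, t_grid=grid)
        np.testing.assert_array_equal(a.states, b.states)

    def test_egfr_fold_doubles_total_abundance(self, ref_model, reverse_tables):
        pm = co.build_patient_model(ref_model, {"EGFR": 2.0}, reverse_tables)
        assert pm.params["EGFR_tot"] == pytest.approx(
            2.0 * ref_model.params["EGFR_tot"]
        )

    def test_mrna_fold_fidelity_across_sweep(self, ref_model, reverse_tables,
                                             basal_state):
        """Requested PYK2 transcript folds are realised within 2%."""
        from pykmet.reference import readout_value

        base_level = readout_value(ref_model, basal_state, "mRNA_PYK2")
        for fold in (0.2, 1.0, 5.0, 30.0):
            pm = co.build_patient_model(ref_model, {"PYK2": fold}, reverse_tables)
            y = steady_state(pm, init=basal_state, continuation=True)
            achieved = readout_value(pm, y, "mRNA_PYK2") / base_level
            assert achieved == pytest.approx(fold, rel=0.02)

    def test_degenerate_egfr_patient_is_non_responder(self, ref_model,
                                                      reverse_tables):
        pm = co.build_patient_model(ref_model, {"EGFR": 1e-3}, reverse_tables)
        kept, report = responder_filter({"p": pm}, drugs=("Gefitinib",),
                                        readout="pERK", level=50.0)
        assert not kept
        assert not report.iloc[0]["responder"]


class TestQuartiles:
    @staticmethod
    def scores(values):
        return pd.DataFrame(
            {"sample_id": [f"s{i:02d}" for i in range(len(values))], "BI": values}
        )

    def test_eight_distinct_values(self):
        res = stratify_quartiles(self.scores([0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8]))
        assert len(res.q1) == 2 and len(res.q3) == 2
        assert res.q1 == ["s00", "s01"] and res.q3 == ["s06", "s07"]

    def test_percentile_oracle_one_to_twelve(self):
        res = stratify_quartiles(self.scores(list(range(1, 13))))
        assert res.q1 == ["s00", "s01", "s02"]
        assert res.q3 == ["s09", "s10", "s11"]

    def test_boundary_ties_flagged_and_stable(self):
        vals = [0.1, 0.2, 0.2, 0.4, 0.5, 0.6, 0.7, 0.8]
        res = stratify_quartiles(self.scores(vals))
        assert res.boundary_ties
        assert res.q1 == ["s00", "s01"]  # stable sample-id order at the tie

    def test_fewer_than_eight_rejected(self):
        with pytest.raises(ValueError, match=">= 8"):
            stratify_quartiles(self.scores([1, 2, 3, 4, 5, 6, 7]))


class TestEnrichment:
    @staticmethod
    def fake_result(q1_ids, q3_ids):
        table = pd.DataFrame(
            {"sample_id": q1_ids + q3_ids,
             "BI": list(range(len(q1_ids) + len(q3_ids)))}
        )
        return StratificationResult(table, q1_ids, q3_ids, False)

    def test_null_distribution_not_significant(self):
        rng = np.random.default_rng(0)
        n = 15
        ids = [f"s{i}" for i in range(2 * n)]
        cohort = make_cohort({sid: {"PYK2": rng.lognormal(0, 0.3)} for sid in ids})
        res = self.fake_result(ids[:n], ids[n:])
        out = enrichment_test(cohort, res)
        assert (out["p_adj"] > 0.05).all()

    def test_constant_expression_flagged(self):
        ids = [f"s{i}" for i in range(16)]
        cohort = make_cohort({sid: {} for sid in ids})  # all nodes constant 1.0
        res = self.fake_result(ids[:8], ids[8:])
        out = enrichment_test(cohort, res)
        assert out["constant"].all()
        assert (out["pvalue"] == 1.0).all()

    def test_planted_two_fold_shift_power(self):
        """A 2-fold PYK2 shift (n=15/group, sigma=0.3) is detected in >= 90%
        of 100 seeded replicates after BH adjustment."""
        hits = 0
        n = 15
        for seed in range(100):
            rng = np.random.default_rng(seed)
            q1 = {f"a{i}": {"PYK2": 2.0 * rng.lognormal(0, 0.3)} for i in range(n)}
            q3 = {f"b{i}": {"PYK2": rng.lognormal(0, 0.3)} for i in range(n)}
            cohort = make_cohort({**q1, **q3})
            res = self.fake_result(list(q1), list(q3))
            out = enrichment_test(cohort, res)
            row = out[out["node"] == "PYK2"].iloc[0]
            if row["p_adj"] < 0.05 and row["direction"] > 0:
                hits += 1
        assert hits >= 90

    def test_subtype_anova_null(self):
        rng = np.random.default_rng(1)
        rows = []
        for i in range(30):
            rows.append({"sample_id": f"s{i}",
                         "subtype": ["BL1", "M", "LAR"][i % 3],
                         **{n: 1.0 for n in NODES}})
        cohort = pd.DataFrame(rows)
        scores = pd.DataFrame(
            {"sample_id": cohort["sample_id"], "BI": rng.uniform(0, 1, 30)}
        )
        _, p = subtype_anova(cohort, scores)
        assert p > 0.05


class TestDeterminism:
    def test_patient_synergy_reproducible(self, ref_model, reverse_tables):
        pm = co.build_patient_model(ref_model, {"PYK2": 2.0}, reverse_tables)
        kept, _ = responder_filter({"p": pm})
        a = co.patient_synergy(kept)
        b = co.patient_synergy(kept)
        assert a.loc[0, "BI"] == b.loc[0, "BI"]
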