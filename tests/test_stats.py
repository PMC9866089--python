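"""Normality-gated comparisons, two-way ANOVA, Grubbs, ΔΔCt."""

import numpy as np
import pandas as pd
import pytest

from cardiocal.stats import (
    ddct_fold_change,
    grubbs_outlier,
    normality_gated_test,
    organ_culture_anova,
)


class TestGatedTest:
    def test_identical_normal_groups_not_significant(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 30)
        res = normality_gated_test(a, a.copy())
        assert res.test == "t"
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_separated_normals_detected_with_power(self):
        """N(0,1) vs N(2,1) at n=30: significant at alpha 0.001 in at least
        95 of 100 seeded runs."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            res = normality_gated_test(rng.normal(0, 1, 30), rng.normal(2, 1, 30))
            hits += res.p < 0.001
        assert hits >= 95

    def test_heavy_tails_route_to_mann_whitney(self):
        rng = np.random.default_rng(3)
        heavy = rng.standard_cauchy(40)
        res = normality_gated_test(heavy, rng.normal(0, 1, 40))
        assert res.test == "Mann-Whitney"
        assert res.normal[0] is False

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            normality_gated_test([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_paired_needs_equal_n(self):
        with pytest.raises(ValueError):
            normality_gated_test([1, 2, 3, 4], [1, 2, 3], paired=True)

    def test_type_one_error_controlled_under_null(self):
        """Gated procedure keeps the type-I rate near nominal 5% (≤ 7%)
        over 2000 null replicates."""
        rng = np.random.default_rng(42)
        false_pos = 0
        n_rep = 2000
        for _ in range(n_rep):
            res = normality_gated_test(rng.normal(0, 1, 12), rng.normal(0, 1, 12))
            false_pos += res.p < 0.05
        assert false_pos / n_rep <= 0.07


class TestAnova:
    def _table(self, offset, seed=0, n_a=10, n_b=17, n_time=4):
        rng = np.random.default_rng(seed)
        rows = []
        for t in range(n_time):
            for _ in range(n_a):
                rows.append({"group": "ko", "time": t,
                             "bpm": 90 + offset + rng.normal(0, 8)})
            for _ in range(n_b):
                rows.append({"group": "wt", "time": t,
                             "bpm": 90 + rng.normal(0, 8)})
        return pd.DataFrame(rows)

    def test_identical_curves_have_negligible_group_effect(self):
        table = self._table(offset=0.0, seed=1)
        res = organ_culture_anova(table)
        assert res.loc["C(group)", "PR(>F)"] > 0.05

    def test_offset_group_detected_at_papers_design(self):
        """+30 bpm at every time point with 10 vs 17 hearts: group effect
        p < 0.0001 in ≥ 90% of seeded runs."""
        hits = 0
        for seed in range(50):
            res = organ_culture_anova(self._table(offset=30.0, seed=seed))
            hits += res.loc["C(group)", "PR(>F)"] < 1e-4
        assert hits >= 45

    def test_permuting_labels_destroys_significance(self):
        ps = []
        for seed in range(11):
            table = self._table(offset=30.0, seed=0)
            rng = np.random.default_rng(seed + 100)
            table["group"] = rng.permutation(table["group"].to_numpy())
            ps.append(organ_culture_anova(table).loc["C(group)", "PR(>F)"])
        assert np.median(ps) > 0.05

    def test_single_level_factor_rejected(self):
        table = self._table(0.0).assign(group="wt")
        with pytest.raises(ValueError):
            organ_culture_anova(table)


class TestGrubbs:
    def test_small_clean_sample_has_no_outlier(self):
        out, idx, g, crit = grubbs_outlier([1.0, 2.0, 3.0])
        assert not out
        assert idx is None

    def test_gross_outlier_flagged(self):
        out, idx, g, crit = grubbs_outlier([1.0, 1.1, 0.9, 50.0])
        assert out
        assert idx == 3
        assert g > crit

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError):
            grubbs_outlier([2.0, 2.0, 2.0, 2.0])

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            grubbs_outlier([1.0, 2.0])


class TestDdct:
    def _table(self, ct_target_ko):
        rows = []
        for grp, ct_ref, ct_tgt in (("wt", 15.0, 20.0), ("ko", 15.0, ct_target_ko)):
            for rep in range(3):
                rows.append({"gene": "actin", "group": grp, "ct": ct_ref})
                rows.append({"gene": "tgt", "group": grp, "ct": ct_tgt})
        return pd.DataFrame(rows)

    @pytest.mark.parametrize(
        "ct_ko, fold",
        [(20.0, 1.0), (21.0, 0.5), (18.0, 4.0)],
        ids=["ddct=0", "ddct=1", "ddct=-2"],
    )
    def test_fold_change_definition(self, ct_ko, fold):
        res = ddct_fold_change(
            self._table(ct_ko), reference_gene="actin", control_group="wt"
        )
        assert len(res) == 1
        assert res[0].fold_change == pytest.approx(fold)

    def test_missing_reference_rejected(self):
        table = self._table(20.0)
        table = table[~((table.group == "ko") & (table.gene == "actin"))]
        with pytest.raises(ValueError):
            ddct_fold_change(table, reference_gene="actin", control_group="wt")
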