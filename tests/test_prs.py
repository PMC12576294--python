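"""Polygenic scores: weighted sums, clumping, risk groups, discrimination."""

import numpy as np
import pandas as pd
import pytest

from ediirisk import prs
from ediirisk.errors import (
    DegenerateScoreError,
    HarmonizationError,
    UndefinedMetricError,
)


def _effects(ids, betas, ps=None, chrom=1, pos=None):
    n = len(ids)
    return pd.DataFrame(
        {
            "id": ids,
            "chr": chrom if np.isscalar(chrom) else chrom,
            "pos": pos if pos is not None else np.arange(n) * 10_000,
            "a1": "A",
            "a2": "G",
            "beta": betas,
            "p": ps if ps is not None else [1e-8] * n,
        }
    )


class TestWeightedPrs:
    def test_worked_sum(self):
        dosages = pd.DataFrame([[0, 1, 2]], columns=["v1", "v2", "v3"])
        eff = _effects(["v1", "v2", "v3"], [0.1, -0.2, 0.3])
        assert prs.weighted_prs(dosages, eff).iloc[0] == pytest.approx(0.4)

    def test_zero_dosages_score_zero(self):
        dosages = pd.DataFrame([[0, 0]], columns=["v1", "v2"])
        eff = _effects(["v1", "v2"], [0.5, -0.5])
        assert prs.weighted_prs(dosages, eff).iloc[0] == 0.0

    def test_allele_flip_with_negated_beta_is_identity(self):
        rng = np.random.default_rng(2)
        dosages = pd.DataFrame(
            rng.integers(0, 3, (20, 3)), columns=["v1", "v2", "v3"]
        )
        eff = _effects(["v1", "v2", "v3"], [0.1, -0.2, 0.3])
        counted = {"v1": ("A", "G"), "v2": ("A", "G"), "v3": ("A", "G")}
        base = prs.weighted_prs(dosages, eff, counted_alleles=counted)
        flipped = eff.copy()
        flipped.loc[1, ["a1", "a2"]] = ["G", "A"]
        flipped.loc[1, "beta"] = 0.2
        out = prs.weighted_prs(dosages, flipped, counted_alleles=counted)
        np.testing.assert_allclose(base, out)

    def test_unalignable_variant_reported(self):
        dosages = pd.DataFrame([[1]], columns=["v1"])
        eff = _effects(["v1"], [0.1])
        with pytest.raises(HarmonizationError, match="v1"):
            prs.weighted_prs(dosages, eff, counted_alleles={"v1": ("C", "T")})

    def test_linearity_over_effect_tables(self):
        rng = np.random.default_rng(3)
        dosages = pd.DataFrame(
            rng.integers(0, 3, (15, 4)), columns=[f"v{i}" for i in range(4)]
        )
        b1 = rng.normal(size=4)
        b2 = rng.normal(size=4)
        ids = [f"v{i}" for i in range(4)]
        s1 = prs.weighted_prs(dosages, _effects(ids, b1))
        s2 = prs.weighted_prs(dosages, _effects(ids, b2))
        s12 = prs.weighted_prs(dosages, _effects(ids, b1 + b2))
        np.testing.assert_allclose(s12, s1 + s2, rtol=1e-12)

    def test_missing_dosage_imputed_to_mean(self):
        dosages = pd.DataFrame({"v1": [0.0, 2.0, np.nan]})
        eff = _effects(["v1"], [1.0])
        out = prs.weighted_prs(dosages, eff)
        assert out.iloc[2] == pytest.approx(1.0)  # mean dosage of observed


class TestClumping:
    def _pair(self, dist_bp, r2, ps):
        eff = _effects(["a", "b"], [0.1, 0.1], ps=ps, pos=[0, dist_bp])
        ld = pd.DataFrame(
            [[1.0, r2], [r2, 1.0]], index=["a", "b"], columns=["a", "b"]
        )
        return eff, ld

    def test_high_ld_within_window_keeps_most_significant(self):
        eff, ld = self._pair(500_000, 0.5, [1e-8, 1e-6])
        kept = prs.clump_and_threshold(eff, ld, p_max=1e-5)
        assert kept["id"].tolist() == ["a"]

    def test_low_ld_pair_both_kept(self):
        eff, ld = self._pair(500_000, 0.05, [1e-8, 1e-6])
        kept = prs.clump_and_threshold(eff, ld, p_max=1e-5)
        assert sorted(kept["id"]) == ["a", "b"]

    def test_outside_window_both_kept(self):
        eff, ld = self._pair(1_500_000, 0.5, [1e-8, 1e-6])
        kept = prs.clump_and_threshold(eff, ld, p_max=1e-5)
        assert sorted(kept["id"]) == ["a", "b"]

    def test_p_threshold_filters(self):
        eff, ld = self._pair(1_500_000, 0.0, [1e-8, 1e-3])
        kept = prs.clump_and_threshold(eff, ld, p_max=1e-5)
        assert kept["id"].tolist() == ["a"]

    def test_row_order_invariance(self):
        rng = np.random.default_rng(9)
        n = 12
        eff = _effects(
            [f"v{i}" for i in range(n)],
            rng.normal(size=n),
            ps=rng.uniform(1e-10, 1e-4, n),
            pos=rng.integers(0, 3_000_000, n),
        )
        ids = eff["id"].tolist()
        r = rng.uniform(0, 1, (n, n))
        r2 = (r + r.T) / 2
        np.fill_diagonal(r2, 1.0)
        ld = pd.DataFrame(r2, index=ids, columns=ids)
        a = prs.clump_and_threshold(eff, ld, p_max=1e-3)
        b = prs.clump_and_threshold(
            eff.sample(frac=1, random_state=0), ld, p_max=1e-3
        )
        assert a["id"].tolist() == b["id"].tolist()

    def test_missing_ld_treated_as_independent(self):
        eff = _effects(["a", "b"], [0.1, 0.1], ps=[1e-8, 1e-6], pos=[0, 1000])
        kept = prs.clump_and_threshold(eff, None, p_max=1e-5)
        assert sorted(kept["id"]) == ["a", "b"]


class TestRiskGroups:
    def test_quintiles_of_one_to_ten(self):
        groups = prs.assign_risk_groups(pd.Series(np.arange(1.0, 11.0)))
        assert (groups[:2] == "low").all()
        assert (groups[2:8] == "intermediate").all()
        assert (groups[8:] == "high").all()

    def test_monotone_transform_leaves_groups(self):
        scores = pd.Series(np.random.default_rng(1).normal(size=50))
        a = prs.assign_risk_groups(scores)
        b = prs.assign_risk_groups(np.exp(scores) * 3 + 7)
        assert (a.to_numpy() == b.to_numpy()).all()

    def test_five_distinct_scores(self):
        groups = prs.assign_risk_groups(pd.Series([1.0, 2.0, 3.0, 4.0, 5.0]))
        assert (groups == "low").sum() == 1
        assert (groups == "high").sum() == 1

    def test_constant_scores_rejected(self):
        with pytest.raises(DegenerateScoreError):
            prs.assign_risk_groups(pd.Series(np.ones(10)))


class TestDiscrimination:
    def test_perfect_separation_auc_one(self):
        scores = pd.Series([1, 2, 3, 10, 11, 12], dtype=float)
        event = pd.Series([0, 0, 0, 1, 1, 1])
        time = pd.Series([5.0] * 3 + [1.0, 2.0, 3.0])
        auc, _ = prs.evaluate_prs(scores, event, time)
        assert auc == 1.0

    def test_independent_scores_auc_near_half(self):
        rng = np.random.default_rng(4)
        n = 4000
        scores = pd.Series(rng.normal(size=n))
        event = pd.Series(rng.integers(0, 2, n))
        time = pd.Series(rng.uniform(1, 10, n))
        auc, _ = prs.evaluate_prs(scores, event, time)
        assert auc == pytest.approx(0.5, abs=0.03)

    def test_no_events_rejected(self):
        with pytest.raises(UndefinedMetricError):
            prs.evaluate_prs(
                pd.Series([1.0, 2.0]), pd.Series([0, 0]), pd.Series([1.0, 2.0])
            )

    @pytest.mark.parametrize("censored", [False, True])
    def test_cindex_matches_pairwise_oracle(self, censored):
        """Engine C-index equals an O(n^2) comparable-pair count."""
        rng = np.random.default_rng(8)
        n = 150
        scores = rng.normal(size=n)
        time = rng.exponential(5, n)
        if censored:
            event = rng.integers(0, 2, n)
        else:
            # effectively uncensored: only the last-followed subject lacks an
            # event, so every informative pair is comparable
            event = np.ones(n, dtype=int)
            event[np.argmax(time)] = 0
        _, cindex = prs.evaluate_prs(
            pd.Series(scores), pd.Series(event), pd.Series(time)
        )
        num = den = 0.0
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                # pair comparable if the earlier time is an event
                if event[i] == 1 and time[i] < time[j]:
                    den += 1
                    if scores[i] > scores[j]:
                        num += 1  # higher risk score died earlier: concordant
                    elif scores[i] == scores[j]:
                        num += 0.5
        assert cindex == pytest.approx(num / den, abs=1e-12)
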