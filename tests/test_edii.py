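"""E-DII scoring: worked arithmetic, the step-by-step oracle, invariances."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from ediirisk import edii
from ediirisk.errors import (
    DegenerateExposureError,
    InvalidRecordError,
    SchemaError,
)


def _records(rows, components):
    return pd.DataFrame(rows, columns=["participant_id", "energy_kcal"] + components)


class TestEnergyAdjust:
    def test_density_arithmetic(self):
        rec = _records([[1, 2000.0, 30.0]], ["fiber"])
        dens = edii.energy_adjust(rec, ["fiber"])
        assert dens.loc[1, "fiber"] == pytest.approx(15.0)

    def test_zero_intake_gives_zero_density(self):
        rec = _records([[1, 1800.0, 0.0]], ["fiber"])
        assert edii.energy_adjust(rec, ["fiber"]).loc[1, "fiber"] == 0.0

    def test_recalls_averaged_after_adjustment(self):
        rec = _records([[1, 1000.0, 10.0], [1, 1000.0, 20.0]], ["fiber"])
        assert edii.energy_adjust(rec, ["fiber"]).loc[1, "fiber"] == pytest.approx(15.0)

    def test_nonpositive_energy_rejected(self):
        rec = _records([[1, 0.0, 10.0]], ["fiber"])
        with pytest.raises(InvalidRecordError):
            edii.energy_adjust(rec, ["fiber"])

    def test_missing_component_column(self):
        rec = _records([[1, 2000.0, 30.0]], ["fiber"])
        with pytest.raises(SchemaError):
            edii.energy_adjust(rec, ["fiber", "magnesium"])


def _ref(components, means, sds, weights):
    return pd.DataFrame(
        {"component": components, "unit": "g", "mean": means, "sd": sds,
         "weight": weights}
    )


class TestScore:
    def test_all_densities_at_reference_means_score_zero(self, reference):
        dens = pd.DataFrame(
            [reference["mean"].to_numpy()], columns=reference["component"]
        )
        out = edii.edii_score(dens, reference)
        assert out["edii"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_one_sd_above_mean_contribution(self):
        ref = _ref(["fiber"], [10.0], [2.0], [-0.663])
        dens = pd.DataFrame({"fiber": [12.0]})
        out = edii.edii_score(dens, ref)
        expected = (2 * norm.cdf(1.0) - 1) * -0.663
        assert out["edii"].iloc[0] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.6827 * -0.663, abs=1e-4)

    def test_reflection_negates_contribution(self):
        ref = _ref(["x"], [10.0], [2.0], [0.5])
        up = edii.edii_score(pd.DataFrame({"x": [12.0]}), ref)["edii"].iloc[0]
        down = edii.edii_score(pd.DataFrame({"x": [8.0]}), ref)["edii"].iloc[0]
        assert up == pytest.approx(-down, rel=1e-12)

    def test_missing_component_named_in_error(self, reference):
        dens = pd.DataFrame({"fiber": [10.0]})
        with pytest.raises(SchemaError, match="magnesium"):
            edii.edii_score(dens, reference)

    def test_score_bounded_by_weight_mass(self, reference):
        rng = np.random.default_rng(7)
        comps = reference["component"].tolist()
        dens = pd.DataFrame(
            np.abs(rng.normal(0, 1000, (50, len(comps)))), columns=comps
        )
        out = edii.edii_score(dens, reference)
        assert (out["edii"].abs() <= reference["weight"].abs().sum() + 1e-12).all()

    def test_monotone_in_positive_weight_component(self, reference):
        comps = reference["component"].tolist()
        base = pd.DataFrame([reference["mean"].to_numpy()], columns=comps)
        bumped = base.copy()
        bumped.loc[0, "saturated_fat"] += 1.0  # positive weight
        s0 = edii.edii_score(base, reference)["edii"].iloc[0]
        s1 = edii.edii_score(bumped, reference)["edii"].iloc[0]
        assert s1 > s0

    def test_scale_invariance_of_full_pipeline(self, reference):
        comps = reference["component"].tolist()
        rng = np.random.default_rng(11)
        intakes = np.abs(rng.normal(20, 5, (3, len(comps))))
        rows = []
        for scale in (1.0, 3.7):
            rec = pd.DataFrame(intakes * scale, columns=comps)
            rec.insert(0, "participant_id", [1, 2, 3])
            rec["energy_kcal"] = 2000.0 * scale
            dens = edii.energy_adjust(rec, comps)
            rows.append(edii.edii_score(dens, reference)["edii"].to_numpy())
        np.testing.assert_allclose(rows[0], rows[1], rtol=1e-12)

    def test_matches_stepwise_oracle(self, reference):
        """100 random participants against an independently coded loop."""
        rng = np.random.default_rng(5)
        comps = reference["component"].tolist()
        dens = pd.DataFrame(
            np.abs(
                rng.normal(
                    reference["mean"], reference["sd"] * 2, (100, len(comps))
                )
            ),
            columns=comps,
        )
        out = edii.edii_score(dens, reference)["edii"].to_numpy()
        oracle = []
        for i in range(len(dens)):
            total = 0.0
            for _, row in reference.iterrows():
                z = (dens.iloc[i][row["component"]] - row["mean"]) / row["sd"]
                p = 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))
                total += (2.0 * p - 1.0) * row["weight"]
            oracle.append(total)
        np.testing.assert_allclose(out, np.asarray(oracle), rtol=1e-12, atol=1e-12)

    def test_empirical_percentile_variant_is_rank_based(self):
        ref = _ref(["x"], [10.0], [2.0], [1.0])
        dens = pd.DataFrame({"x": np.arange(1.0, 10.0)})
        out = edii.edii_score(dens, ref, percentile="empirical")
        # centered midrank percentiles of 9 ordered values
        expected = 2 * (np.arange(9) + 0.5) / 9 - 1
        np.testing.assert_allclose(out["edii"].to_numpy(), expected)


class TestScoreProperties:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        mu=st.floats(0.5, 100.0),
        sigma=st.floats(0.1, 20.0),
        w=st.floats(-1.0, 1.0),
        z=st.floats(-5.0, 5.0).filter(lambda v: abs(v) > 1e-3),
    )
    def test_single_component_score_bounded_and_sign_follows_weight(
        self, mu, sigma, w, z
    ):
        ref = _ref(["x"], [mu], [sigma], [w])
        dens = pd.DataFrame({"x": [mu + z * sigma]})
        score = edii.edii_score(dens, ref)["edii"].iloc[0]
        assert abs(score) <= abs(w) + 1e-12
        if w != 0:
            assert np.sign(score) == np.sign(w) * np.sign(z)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(scale=st.floats(0.05, 50.0), seed=st.integers(0, 10))
    def test_scale_invariance_property(self, scale, seed):
        ref = _ref(["a", "b"], [10.0, 5.0], [2.0, 1.0], [0.3, -0.6])
        rng = np.random.default_rng(seed)
        intakes = np.abs(rng.normal(20, 5, (2, 2)))
        scores = []
        for s in (1.0, scale):
            rec = pd.DataFrame(intakes * s, columns=["a", "b"])
            rec.insert(0, "participant_id", [1, 2])
            rec["energy_kcal"] = 2000.0 * s
            dens = edii.energy_adjust(rec, ["a", "b"])
            scores.append(edii.edii_score(dens, ref)["edii"].to_numpy())
        np.testing.assert_allclose(scores[0], scores[1], rtol=1e-9, atol=1e-12)


class TestExposureCoding:
    def test_tertiles_of_one_to_nine(self):
        scores = pd.Series(np.arange(1.0, 10.0))
        tert, _ = edii.code_exposure(scores)
        assert (tert[:3] == "T1").all()
        assert (tert[3:6] == "T2").all()
        assert (tert[6:] == "T3").all()

    def test_standardized_moments(self):
        scores = pd.Series(np.random.default_rng(3).normal(2, 4, 500))
        _, z = edii.code_exposure(scores)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0, rel=1e-12)

    def test_constant_scores_rejected(self):
        with pytest.raises(DegenerateExposureError):
            edii.code_exposure(pd.Series([1.0, 1.0, 1.0, 1.0]))

    def test_ties_go_to_lower_tertile(self):
        scores = pd.Series([1.0, 1.0, 1.0, 2.0, 2.0, 5.0])
        tert = edii.tertile_labels(scores)
        # the 1/3 quantile falls on a tied value; ties stay in T1
        assert (tert[scores == 1.0] == "T1").all()
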