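"""Homoeolog expression bias and atlas summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings, strategies as st

from panscan.core_io import ExpressionMatrix, ValidationError
from panscan.homoeolog_expression import (
    classify_heb,
    classify_heb_table,
    compare_pair_expression,
    display_log10,
    filter_expressed,
    normalize_pair,
    summarize_atlas,
)
from panscan.synthetic_data import generate_heb_dataset


def matrix_from_tissue_values(per_gene: dict[str, dict[str, float]],
                              species="Sp") -> ExpressionMatrix:
    tissues = sorted(next(iter(per_gene.values())))
    samples = [f"{species}_{t}" for t in tissues]
    values = pd.DataFrame(
        {f"{species}_{t}": {g: v[t] for g, v in per_gene.items()}
         for t in tissues}
    )
    values.index.name = "gene_id"
    meta = pd.DataFrame(
        {"species": species, "tissue": tissues, "replicate": 1}, index=samples
    )
    return ExpressionMatrix(values=values, sample_meta=meta)


class TestNormalize:
    @pytest.mark.parametrize("a,b,expected", [
        (10, 10, (0.5, 0.5)),
        (3, 1, (0.75, 0.25)),
        (0, 5, (0.0, 1.0)),
    ])
    def test_contributions(self, a, b, expected):
        assert normalize_pair(a, b) == pytest.approx(expected)

    def test_zero_total_rejected(self):
        with pytest.raises(ValidationError):
            normalize_pair(0.0, 0.0)


class TestClassifyHeb:
    def test_balanced_distance_zero(self):
        call = classify_heb("p", "root", 5.0, 5.0)
        assert call.category == "BALANCED"
        assert call.distances["BALANCED"] == pytest.approx(0.0)

    def test_full_dominance(self):
        assert classify_heb("p", "root", 8.0, 0.0).category == "DOM_A"
        assert classify_heb("p", "root", 0.0, 8.0).category == "DOM_B"

    def test_tie_at_three_quarters_goes_balanced(self):
        # (0.75, 0.25) is equidistant from (1,0) and (0.5,0.5).
        call = classify_heb("p", "root", 3.0, 1.0)
        assert call.category == "BALANCED"
        assert call.distances["DOM_A"] == pytest.approx(
            call.distances["BALANCED"]
        )
        assert call.distances["BALANCED"] == pytest.approx(
            math.sqrt(2 * 0.25**2)
        )

    def test_decision_boundary_at_p_075(self):
        # Category switches from BALANCED to dominant exactly above 0.75
        # (exact-fraction grid so the tie lands on the boundary precisely).
        for i in range(200, 401):
            p = i / 400
            call = classify_heb("p", "root", 100 * p, 100 * (1 - p))
            expected = "DOM_A" if p > 0.75 else "BALANCED"
            assert call.category == expected, p

    def test_neither_expressed(self):
        call = classify_heb("p", "root", 0.4, 0.5)
        assert call.category == "NOT_EXPRESSED" and call.p is None

    def test_one_expressed_still_classified(self):
        assert classify_heb("p", "root", 6.0, 0.2).category == "DOM_A"

    def test_require_both_switch(self):
        call = classify_heb("p", "root", 6.0, 0.2, require_both=True)
        assert call.category == "NOT_EXPRESSED"

    @settings(max_examples=50, deadline=None)
    @given(
        st.floats(min_value=0.6, max_value=500.0),
        st.floats(min_value=0.6, max_value=500.0),
        st.floats(min_value=0.01, max_value=100.0),
    )
    def test_scale_invariance(self, a, b, c):
        # Invariance holds whenever the expression filter still passes
        # after scaling.
        assume(max(a, b) * c > 0.5)
        assert (
            classify_heb("p", "root", a, b).category
            == classify_heb("p", "root", a * c, b * c).category
        )


class TestFilterExpressed:
    def test_strictly_greater_than_threshold(self):
        m = matrix_from_tissue_values({"g1": {"root": 0.5}, "g2": {"root": 0.6}})
        mask = filter_expressed(m)
        assert not mask.loc["g1", "root"]
        assert mask.loc["g2", "root"]

    def test_replicate_mean_rule(self):
        values = pd.DataFrame(
            {"r1": [0.2], "r2": [1.0]}, index=pd.Index(["g"], name="gene_id")
        )
        meta = pd.DataFrame(
            {"species": "S", "tissue": ["root", "root"], "replicate": [1, 2]},
            index=["r1", "r2"],
        )
        mask = filter_expressed(ExpressionMatrix(values, meta))
        assert mask.loc["g", "root"]


class TestPlantedRecovery:
    def test_recovery_with_noise(self):
        m, pairs, truth = generate_heb_dataset(
            300, p_dom=0.9, noise_sd=0.2, rng=11
        )
        calls = classify_heb_table(m, pairs)
        merged = truth.merge(calls, on=["pair_id", "tissue"])
        assert (merged["category_x"] == merged["category_y"]).mean() >= 0.95

    def test_perfect_recovery_noise_free(self):
        m, pairs, truth = generate_heb_dataset(
            100, p_dom=0.9, noise_sd=0.0, rng=11
        )
        calls = classify_heb_table(m, pairs)
        merged = truth.merge(calls, on=["pair_id", "tissue"])
        assert (merged["category_x"] == merged["category_y"]).all()

    def test_balanced_noise_free_exactly_equal(self):
        truth = pd.DataFrame(
            [{"pair_id": "P0", "tissue": t, "category": "BALANCED"}
             for t in ("root", "stem", "leaf", "panicle")]
        )
        m, pairs, _ = generate_heb_dataset(
            1, noise_sd=0.0, truth=truth, rng=5
        )
        a = m.values.loc[pairs["gene_a"].iloc[0]]
        b = m.values.loc[pairs["gene_b"].iloc[0]]
        assert (a.to_numpy() == b.to_numpy()).all()

    def test_not_expressed_below_threshold(self):
        truth = pd.DataFrame(
            [{"pair_id": "P0", "tissue": t, "category": "NOT_EXPRESSED"}
             for t in ("root", "stem", "leaf", "panicle")]
        )
        m, pairs, _ = generate_heb_dataset(1, truth=truth, rng=5)
        assert (m.values.to_numpy() <= 0.5).all()


class TestAtlas:
    def test_dominant_and_predominant(self):
        m = matrix_from_tissue_values(
            {"g1": {"root": 20.0, "stem": 2.0, "leaf": 1.0, "panicle": 0.5}}
        )
        (s,) = summarize_atlas(m)
        assert s.dominant_tissue == "root"
        assert s.predominant and s.expressed_anywhere

    def test_flat_profile_not_predominant(self):
        m = matrix_from_tissue_values(
            {"g1": {"root": 5.0, "stem": 5.0, "leaf": 5.0, "panicle": 5.0}}
        )
        (s,) = summarize_atlas(m)
        assert s.predominance_ratio == pytest.approx(1.0)
        assert not s.predominant

    def test_zero_fpkm_display_value(self):
        assert display_log10(0.0) == pytest.approx(-2.0)


class TestPairComparison:
    TISSUES = ("root", "stem", "leaf", "panicle")

    def _matrix(self, a_vals, b_vals):
        return matrix_from_tissue_values(
            {
                "A": dict(zip(self.TISSUES, a_vals)),
                "B": dict(zip(self.TISSUES, b_vals)),
            }
        )

    def test_one_silent(self):
        m = self._matrix((0.0, 0.0, 0.1, 0.0), (5.0, 8.0, 2.0, 9.0))
        assert compare_pair_expression("A", "B", m).call == "one_silent"

    def test_similar_profiles_redundant(self):
        m = self._matrix((5.0, 8.0, 2.0, 9.0), (5.5, 7.5, 2.2, 8.0))
        rep = compare_pair_expression("A", "B", m)
        assert rep.call == "redundant" and rep.concordance > 0.9

    def test_anticorrelated_profiles_diverged(self):
        m = self._matrix((1.0, 1.0, 1.0, 100.0), (100.0, 1.0, 1.0, 1.0))
        rep = compare_pair_expression("A", "B", m)
        assert rep.call == "diverged"
        assert rep.log2_ratio["panicle"] == pytest.approx(
            np.log2(101 / 2)
        )

    def test_constant_profile_concordance_undefined(self):
        m = self._matrix((5.0, 5.0, 5.0, 5.0), (5.0, 5.0, 5.0, 5.0))
        rep = compare_pair_expression("A", "B", m)
        assert rep.concordance is None and rep.call == "redundant"
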