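"""r_abs, relationship classification, rank-sum testing, keystone impact."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dropoutkeys.relationships import (
    classify_relationship,
    compute_r_abs,
    conserved_relationships,
    delta_ph,
    delta_ph_summary,
    keystone_impact,
    relationship_matrix,
    relationship_records,
    wilcoxon_rank_sum,
)
from dropoutkeys.scenarios import null_dataset, observation_table, planted_dataset
from dropoutkeys.types import PHRecord, ValidationError, default_community
from tests.conftest import build_table


def exact_ranksum_p(x, y):
    """Independent oracle: enumerate every assignment of the pooled ranks."""
    pooled = np.concatenate([x, y])
    n = len(x)
    ranks = np.argsort(np.argsort(pooled)) + 1  # no ties assumed
    obs = ranks[:n].sum()
    total = comb(len(pooled), n)
    idx = range(len(pooled))
    count_le = count_ge = 0
    for c in combinations(idx, n):
        s = ranks[list(c)].sum()
        count_le += s <= obs
        count_ge += s >= obs
    return min(1.0, 2 * min(count_le, count_ge) / total)


class TestRAbs:
    def test_identical_vectors_give_one(self):
        assert compute_r_abs([4.0, 5, 6], [4.0, 5, 6]) == 1.0

    def test_ratio_of_medians(self):
        assert compute_r_abs([4e7] * 3, [8e7] * 3) == 0.5

    def test_zero_full_median_is_undefined(self):
        assert np.isnan(compute_r_abs([1.0, 2, 3], [0.0, 0, 0]))

    def test_empty_vector_rejected(self):
        with pytest.raises(ValidationError):
            compute_r_abs([], [1.0])

    def test_mean_mode(self):
        assert compute_r_abs([1.0, 2, 9], [2.0, 2, 2], stat="mean") == 2.0


class TestClassification:
    D, F = True, False  # censored flags: D = below DTL

    @pytest.mark.parametrize(
        "drop_cens,full_cens,expected",
        [
            ([F, F, F], [D, D, D], "exclusion"),  # only detected without x
            ([D, D, D], [F, F, F], "positive_dependency"),  # needs x present
            ([D, D, D], [D, D, D], "below_DTL"),
            ([F, F, F], [F, F, F], None),  # falls through to r_abs sign
        ],
    )
    def test_detection_limit_categories(self, drop_cens, full_cens, expected):
        drop_vals = [0.0 if c else 100.0 for c in drop_cens]
        full_vals = [0.0 if c else 50.0 for c in full_cens]
        cat, r, _ = classify_relationship(drop_vals, drop_cens, full_vals, full_cens)
        if expected is None:
            assert cat == "negative" and r == 2.0
        else:
            assert cat == expected and np.isnan(r)

    def test_rabs_sign_decides(self):
        f = [False] * 3
        cat, r, _ = classify_relationship([10.0] * 3, f, [40.0] * 3, f)
        assert cat == "positive" and r == 0.25

    def test_tie_goes_to_positive_with_note(self):
        f = [False] * 3
        cat, r, note = classify_relationship([5.0] * 3, f, [5.0] * 3, f)
        assert cat == "positive" and r == 1.0 and "neutral" in note

    def test_majority_rule_for_detected(self):
        # 2 of 4 detected is NOT "strictly more than half"
        cat, _, _ = classify_relationship(
            [1.0, 1.0, 0, 0], [False, False, True, True], [0, 0, 0, 0], [True] * 4
        )
        assert cat != "exclusion"

    @given(scale=st.floats(1e-6, 1e6))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, scale):
        """Multiplying all abundances by a constant changes nothing."""
        rng = np.random.default_rng(7)
        a = rng.lognormal(10, 1, 6)
        b = rng.lognormal(9, 1, 6)
        f = [False] * 6
        cat1, r1, _ = classify_relationship(a, f, b, f)
        cat2, r2, _ = classify_relationship(a * scale, f, b * scale, f)
        assert cat1 == cat2
        assert r1 == pytest.approx(r2, rel=1e-9)
        assert wilcoxon_rank_sum(a, b) == wilcoxon_rank_sum(a * scale, b * scale)


class TestWilcoxon:
    def test_identical_constant_groups_give_p_one(self):
        assert wilcoxon_rank_sum([5.0] * 9, [5.0] * 9) == 1.0

    def test_extreme_separation_exact_p(self):
        x = np.arange(1.0, 10)
        y = np.arange(101.0, 110)
        p = wilcoxon_rank_sum(x, y)
        assert p == pytest.approx(2 / comb(18, 9), rel=1e-9)  # 4.1135e-5

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=6), rng.normal(size=6)
        assert wilcoxon_rank_sum(a, b) == wilcoxon_rank_sum(b, a)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, 4)
        b = rng.normal(0.8, 1, 5)
        assert wilcoxon_rank_sum(a, b) == pytest.approx(exact_ranksum_p(a, b), rel=1e-12)

    def test_minimum_replicates_enforced(self):
        with pytest.raises(ValidationError):
            wilcoxon_rank_sum([1.0, 2], [1.0, 2, 3])


class TestKeystoneImpact:
    def test_no_change_no_impact(self):
        vals = {("full", s): [100.0] * 9 for s in ("A", "B", "C")}
        vals.update({("minus_A", s): [100.0] * 9 for s in ("B", "C")})
        table = build_table(vals)
        imp = keystone_impact(table, "A", "E")
        assert imp.n_affected == 0 and imp.affected_set == ()

    def test_planted_effects_recovered_fixed_seed(self):
        """Ten-fold shifts on 3 strains at sigma=0.1 are all recovered."""
        table, planted = planted_dataset(seed=11, n_planted=3, fold=10.0, sigma=0.1)
        imp = keystone_impact(table, "E.fa", "E1")
        assert set(planted) <= set(imp.affected_set)
        assert imp.n_affected == 3

    def test_exclusion_counts_even_without_wilcoxon(self):
        """A strain crossing the DTL counts as affected regardless of p."""
        roster = default_community()
        base = np.full(12, 1e8)
        dropout = base.copy()
        i = roster.strain_ids.index("B.an")
        base[i] = 0.0  # absent in the full community
        dropout[i] = 1e8  # blooms without the focal strain
        rng = np.random.default_rng(5)
        table = observation_table(base, dropout, focal="E.fa", sigma=0.1, rng=rng)
        imp = keystone_impact(table, "E.fa", "E1")
        recs = {r.affected_y: r for r in relationship_records(table, "E.fa", "E1")}
        assert recs["B.an"].category == "exclusion"
        assert "B.an" in imp.affected_set


class TestRelationshipMatrix:
    def test_combinatorics_12_strains_2_environments(self):
        rng = np.random.default_rng(0)
        roster = default_community()
        base = np.full(12, 1e8)
        frames = []
        for env in ("AF", "APF"):
            for x in roster.strain_ids:
                t = observation_table(base, base, focal=x, environment=env, sigma=0.1, rng=rng)
                frames.append(t)
        data = pd.concat([t.data for t in frames]).drop_duplicates(
            subset=["sample_id", "strain_id"]
        )
        samples = pd.concat([t.samples for t in frames]).drop_duplicates(subset=["sample_id"])
        from dropoutkeys.types import AbundanceTable

        table = AbundanceTable(data, samples)
        m = relationship_matrix(table)
        assert len(m) == 12 * 11 * 2 == 264
        # exhaustive and mutually exclusive: every record has exactly one category
        assert m["category"].isin(
            ["negative", "positive", "exclusion", "positive_dependency", "below_DTL"]
        ).all()

    def test_missing_full_reference_raises(self):
        vals = {("minus_A", s): [1.0] * 3 for s in ("B", "C")}
        table = build_table(vals)
        with pytest.raises(ValidationError, match="E"):
            relationship_records(table, "A", "E", full_community="full")

    def test_conserved_pair_reported(self):
        rows = []
        for env in ("e1", "e2", "e3"):
            rows.append({"focal_x": "X", "affected_y": "Y", "environment": env, "category": "positive"})
            rows.append({"focal_x": "X", "affected_y": "Z", "environment": env,
                         "category": "positive" if env == "e1" else "negative"})
        out = conserved_relationships(pd.DataFrame(rows))
        assert out.to_dict("records") == [
            {"focal_x": "X", "affected_y": "Y", "category": "positive"}
        ]


class TestDeltaPH:
    @pytest.mark.parametrize("spent,fresh,expected", [(7.0, 7.0, 0.0), (5.5, 7.0, -1.5)])
    def test_definition(self, spent, fresh, expected):
        assert PHRecord("s", spent, fresh).delta_ph == pytest.approx(expected)

    def test_summary_median_per_community(self):
        ph = pd.DataFrame(
            {
                "sample_id": ["a", "b", "c"],
                "ph_spent": [6.0, 6.2, 5.0],
                "ph_fresh": [7.0, 7.0, 7.0],
            }
        )
        samples = pd.DataFrame(
            {
                "sample_id": ["a", "b", "c"],
                "community": ["full", "full", "minus_X"],
                "environment": ["E", "E", "E"],
            }
        )
        out = delta_ph_summary(ph, samples).set_index("community")["median_delta_ph"]
        assert out["full"] == pytest.approx(-0.9)
        assert out["minus_X"] == pytest.approx(-2.0)
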