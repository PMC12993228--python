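"""Cumulative-share classifier: examples, invariants and a brute-force oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pharmstock import (
    DegenerateInputError,
    EmptyInputError,
    ParetoConfig,
    cumulative_share_table,
    pareto_classify,
)


def oracle_labels(amounts, cum_cuts=(0.70, 0.90, 1.0), labels=("A", "B", "C")):
    """Independent O(n^2) reference: recompute the cumulative share from
    scratch at every rank and assign the first label whose cut the
    before-item share has not yet reached. Non-positive amounts take the
    lowest label."""
    pos = {i: a for i, a in amounts.items() if a > 0}
    total = sum(pos.values())
    order = sorted(pos, key=lambda i: (-pos[i], i))
    out = {}
    for r, pid in enumerate(order):
        cum_before = sum(pos[j] for j in order[:r]) / total
        out[pid] = labels[-1]
        for k, cut in enumerate(cum_cuts):
            if cum_before < cut - 1e-12:
                out[pid] = labels[k]
                break
    for pid, a in amounts.items():
        if a <= 0:
            out[pid] = labels[-1]
    return out


def random_amounts(rng, n):
    ids = [f"I{i:04d}" for i in range(n)]
    vals = np.exp(rng.normal(3.0, 1.6, size=n)).round(2)
    return dict(zip(ids, vals.tolist()))


class TestExamples:
    def test_single_item_takes_top_label(self):
        assert pareto_classify({"x": 100.0}).label_by_id == {"x": "A"}

    def test_exact_cutoff_alignment(self):
        res = pareto_classify({"a": 70.0, "b": 20.0, "c": 10.0})
        assert res.label_by_id == {"a": "A", "b": "B", "c": "C"}

    def test_tie_broken_by_ascending_id(self):
        tab = cumulative_share_table({"b": 50.0, "a": 50.0})
        assert tab["product_id"].tolist() == ["a", "b"]
        assert tab["cumulative_share"].tolist() == pytest.approx([0.5, 1.0])

    def test_cumulative_shares_of_aligned_input(self):
        tab = cumulative_share_table({"a": 70.0, "b": 20.0, "c": 10.0})
        assert tab["cumulative_share"].tolist() == pytest.approx([0.70, 0.90, 1.00])

    def test_empty_and_degenerate_inputs(self):
        with pytest.raises(EmptyInputError):
            pareto_classify({})
        with pytest.raises(DegenerateInputError):
            pareto_classify({"a": 0.0, "b": -1.0})

    def test_crossing_item_down_demotes_boundary_item(self):
        # first item reaches exactly 0.6 < 0.7; second crosses to 0.8:
        # up-rule keeps it in A, down-rule pushes it to B
        amounts = {"a": 60.0, "b": 20.0, "c": 20.0}
        up = pareto_classify(amounts, ParetoConfig(boundary_rule="crossing_item_up"))
        down = pareto_classify(amounts, ParetoConfig(boundary_rule="crossing_item_down"))
        assert up.label_by_id["b"] == "A"
        assert down.label_by_id["b"] == "B"

    def test_negative_forced_to_lowest_and_excluded_from_denominator(self):
        res = pareto_classify({"a": 70.0, "b": 20.0, "c": 10.0, "loss": -50.0})
        assert res.label_by_id == {"a": "A", "b": "B", "c": "C", "loss": "C"}
        ranked = res.ranked_table.set_index("product_id")
        assert ranked.loc["loss", "share"] == 0.0
        assert ranked.loc["a", "share"] == pytest.approx(0.70)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(20))
    def test_labels_match_bruteforce_scan(self, seed):
        rng = np.random.default_rng(seed)
        amounts = random_amounts(rng, int(rng.integers(3, 300)))
        assert pareto_classify(amounts).label_by_id == oracle_labels(amounts)

    def test_labels_match_with_negatives(self):
        rng = np.random.default_rng(99)
        amounts = random_amounts(rng, 150)
        for pid in list(amounts)[::7]:
            amounts[pid] = -amounts[pid]
        assert pareto_classify(amounts).label_by_id == oracle_labels(amounts)


class TestInvariants:
    @settings(derandomize=True, max_examples=40)
    @given(
        st.dictionaries(
            st.text(alphabet="abcdefgh", min_size=1, max_size=4),
            st.floats(0.01, 1e6),
            min_size=1,
            max_size=40,
        ),
        st.floats(0.001, 1e4),
    )
    def test_partition_and_scale_invariance(self, amounts, c):
        res = pareto_classify(amounts)
        assert set(res.label_by_id) == set(amounts)
        assert int(res.class_totals["item_count"].sum()) == len(amounts)
        scaled = pareto_classify({k: v * c for k, v in amounts.items()})
        assert scaled.label_by_id == res.label_by_id

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_monotone_in_amount(self, seed):
        rng = np.random.default_rng(seed)
        amounts = random_amounts(rng, 100)
        res = pareto_classify(amounts)
        order = {"A": 0, "B": 1, "C": 2}
        items = sorted(amounts.items(), key=lambda kv: -kv[1])
        ranks = [order[res.label_by_id[pid]] for pid, _ in items]
        assert ranks == sorted(ranks)

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_minimal_prefix_coverage(self, seed):
        """Class A is the minimal prefix reaching 70% of the total."""
        rng = np.random.default_rng(seed)
        amounts = random_amounts(rng, 200)
        res = pareto_classify(amounts)
        total = sum(amounts.values())
        a_items = sorted(
            (pid for pid, lab in res.label_by_id.items() if lab == "A"),
            key=lambda pid: -amounts[pid],
        )
        a_sum = sum(amounts[pid] for pid in a_items)
        assert a_sum / total >= 0.70
        assert (a_sum - amounts[a_items[-1]]) / total < 0.70

    def test_permutation_invariance(self):
        rng = np.random.default_rng(11)
        amounts = random_amounts(rng, 50)
        items = list(amounts.items())
        t1 = cumulative_share_table(dict(items))
        t2 = cumulative_share_table(dict(reversed(items)))
        assert t1.equals(t2)

    def test_cumulative_share_monotone_ends_at_one(self):
        rng = np.random.default_rng(21)
        tab = cumulative_share_table(random_amounts(rng, 80))
        cs = tab["cumulative_share"].to_numpy()
        assert (np.diff(cs) >= -1e-12).all()
        assert cs[-1] == pytest.approx(1.0, abs=1e-9)


class TestConfigValidation:
    def test_cutoffs_must_sum_to_one(self):
        with pytest.raises(ValueError):
            ParetoConfig(cutoffs=(0.7, 0.2, 0.2))

    def test_labels_must_be_distinct(self):
        with pytest.raises(ValueError):
            ParetoConfig(labels=("A", "A", "C"))
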