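"""Label-shuffling overlap test: exhaustive-enumeration oracle, symmetry,
determinism, calibration and monotonicity."""

import itertools

import numpy as np
import pytest

from tcrcompart import benchmarks
from tcrcompart.overlap import (
    derive_seed,
    observed_overlap,
    overlap_frame,
    permutation_overlap_test,
    run_overlap_suite,
)


def exhaustive_lower_tail(keys, n_a):
    """Brute-force lower-tail overlap probability over all C(n, n_a) label
    assignments — the independent oracle for the Monte-Carlo engine."""
    keys = list(keys)
    indices = set(range(len(keys)))
    observed = observed_overlap(keys[:n_a], keys[n_a:])
    at_most = total = 0
    for chosen in itertools.combinations(sorted(indices), n_a):
        group_a = [keys[i] for i in chosen]
        group_b = [keys[i] for i in indices - set(chosen)]
        total += 1
        at_most += observed_overlap(group_a, group_b) <= observed
    return at_most / total


class TestObservedOverlap:
    def test_set_intersection_semantics(self):
        assert observed_overlap(["c1", "c2", "c3"], ["c2", "c3", "c4"]) == 2
        assert observed_overlap(["c1"], ["c2"]) == 0
        assert observed_overlap(["c1", "c1", "c2"], ["c1", "c2", "c2"]) == 2


class TestPermutationTest:
    def test_four_cell_instance_matches_enumeration(self):
        """Two x-cells vs two y-cells: 2 of the 6 assignments give overlap 0,
        so the lower-tail probability is 1/3."""
        keys = ["x", "x", "y", "y"]
        assert exhaustive_lower_tail(keys, 2) == pytest.approx(1 / 3)
        result = permutation_overlap_test(keys[:2], keys[2:],
                                          n_permutations=20000, seed=1)
        se = np.sqrt((1 / 3) * (2 / 3) / 20000)
        assert result.observed_overlap == 0
        assert result.p_value == pytest.approx(1 / 3, abs=3 * se + 1e-4)

    @pytest.mark.parametrize("trial", range(5))
    def test_monte_carlo_agrees_with_enumeration_on_small_pools(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(5, 11))
        n_a = int(rng.integers(1, n))
        keys = [f"c{int(i)}" for i in rng.integers(0, 4, size=n)]
        exact = exhaustive_lower_tail(keys, n_a)
        result = permutation_overlap_test(
            keys[:n_a], keys[n_a:], n_permutations=20000, seed=200 + trial
        )
        se = np.sqrt(exact * (1 - exact) / 20000)
        assert result.p_value == pytest.approx(exact, abs=3 * se + 2e-4)

    def test_degenerate_shared_clonotype_gives_p_one(self):
        result = permutation_overlap_test(["z"] * 5, ["z"] * 3,
                                          n_permutations=500, seed=0)
        assert result.observed_overlap == 1
        assert result.null_histogram == {1: 500}
        assert result.p_value == 1.0

    def test_p_value_matches_plus_one_formula(self):
        rng = np.random.default_rng(3)
        keys = [f"c{int(i)}" for i in rng.integers(0, 20, size=60)]
        result = permutation_overlap_test(keys[:30], keys[30:],
                                          n_permutations=400, seed=5)
        null = np.repeat(
            list(result.null_histogram), list(result.null_histogram.values())
        )
        assert len(null) == 400
        expected = (1 + (null <= result.observed_overlap).sum()) / 401
        assert result.p_value == pytest.approx(expected)

    def test_swapping_groups_reproduces_the_null_exactly(self):
        rng = np.random.default_rng(4)
        a = [f"c{int(i)}" for i in rng.integers(0, 15, size=40)]
        b = [f"c{int(i)}" for i in rng.integers(5, 25, size=25)]
        r_ab = permutation_overlap_test(a, b, n_permutations=300, seed=11)
        r_ba = permutation_overlap_test(b, a, n_permutations=300, seed=11)
        assert r_ab.observed_overlap == r_ba.observed_overlap
        assert r_ab.null_histogram == r_ba.null_histogram
        assert r_ab.p_value == r_ba.p_value

    def test_min_cells_gate_skips_without_p(self):
        result = permutation_overlap_test(["a"] * 3, ["b"] * 50,
                                          min_cells=20, seed=0)
        assert result.skipped and result.p_value is None
        assert "min_cells" in result.skipped_reason

    def test_same_seed_reproduces_identical_result(self):
        rng = np.random.default_rng(6)
        keys = [f"c{int(i)}" for i in rng.integers(0, 30, size=80)]
        r1 = permutation_overlap_test(keys[:40], keys[40:], seed=7,
                                      n_permutations=200)
        r2 = permutation_overlap_test(keys[:40], keys[40:], seed=7,
                                      n_permutations=200)
        assert r1.p_value == r2.p_value
        assert r1.null_histogram == r2.null_histogram

    def test_tie_handling_variants_are_ordered(self):
        rng = np.random.default_rng(8)
        keys = [f"c{int(i)}" for i in rng.integers(0, 10, size=50)]
        kwargs = dict(n_permutations=300, seed=9)
        p_incl = permutation_overlap_test(keys[:25], keys[25:], **kwargs).p_value
        p_mid = permutation_overlap_test(keys[:25], keys[25:], ties="mid",
                                         **kwargs).p_value
        assert p_mid <= p_incl


class TestSuite:
    def test_result_bookkeeping_over_donors_pairs_and_scopes(self, small_dataset,
                                                             small_config):
        cells = small_dataset.truth.cells
        results = run_overlap_suite(cells, n_permutations=50, seed=1)
        n_donors = small_config.n_donors
        n_lineages = len(small_config.lineages)
        n_clusters = len(small_config.clusters)
        assert len(results) == n_donors * n_lineages * 3 * (1 + n_clusters)
        frame = overlap_frame(results)
        assert (frame.loc[frame["skipped_reason"] == "", "p_value"].notna()).all()

    def test_same_master_seed_gives_identical_p_values(self, small_dataset):
        cells = small_dataset.truth.cells
        p1 = overlap_frame(run_overlap_suite(cells, n_permutations=60, seed=5))
        p2 = overlap_frame(run_overlap_suite(cells, n_permutations=60, seed=5))
        assert p1.equals(p2)

    def test_per_test_seeds_are_stable_under_stratum_removal(self, small_dataset):
        """Dropping one donor leaves every other stratum's p-value unchanged."""
        cells = small_dataset.truth.cells
        full = overlap_frame(run_overlap_suite(cells, n_permutations=60, seed=5))
        subset = overlap_frame(
            run_overlap_suite(cells[cells["donor"] != "donor2"],
                              n_permutations=60, seed=5)
        )
        keys = ["donor", "lineage", "scope", "compartment_a", "compartment_b"]
        merged = full.merge(subset, on=keys, suffixes=("_full", "_sub"))
        assert len(merged) == len(subset)
        # NaN-safe equality: skipped strata carry no p-value on either side
        assert merged["p_value_full"].equals(merged["p_value_sub"])

    def test_derive_seed_is_stable_and_bounded(self):
        s = derive_seed(123, "donor1|CD4|global|Blood|BM_CD69neg")
        assert s == derive_seed(123, "donor1|CD4|global|Blood|BM_CD69neg")
        assert 0 <= s < 2**31
        assert s != derive_seed(124, "donor1|CD4|global|Blood|BM_CD69neg")


class TestOperatingCharacteristics:
    def test_super_uniform_under_full_sharing(self, calibration_pvalues_500):
        """With identical pools the reported p is conservative: the empirical
        rejection rate stays below alpha plus a DKW(0.01) band."""
        pvalues = calibration_pvalues_500
        dkw = np.sqrt(np.log(2 / 0.01) / (2 * len(pvalues)))
        for alpha in (0.01, 0.05, 0.10):
            assert (pvalues <= alpha).mean() <= alpha + dkw

    def test_expected_p_decreases_with_less_sharing(self):
        """Averaged over replicates, the p-value falls monotonically as the
        fraction of the pool shared between compartments drops."""
        mean_p = []
        for sharing in (1.0, 0.9, 0.8):
            pvals = []
            for i in range(30):
                config = benchmarks.two_compartment_config(
                    n_cells_per_group=60, sharing=sharing,
                    seed=derive_seed(31, f"mono-{sharing}-{i}"),
                )
                keys_a, keys_b = benchmarks._group_keys(config)
                pvals.append(
                    permutation_overlap_test(
                        keys_a, keys_b, n_permutations=100,
                        seed=derive_seed(37, f"mono-{sharing}-{i}"),
                    ).p_value
                )
            mean_p.append(np.mean(pvals))
        assert mean_p[0] > mean_p[1] > mean_p[2]
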