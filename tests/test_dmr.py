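"""DMR caller: blocks, CUSUM segmentation, testing, FDR, directionality."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methepi.config import SyntheticConfig
from methepi.context import merge_cg_strands
from methepi.dmr import (
    DmrParams,
    build_candidate_blocks,
    build_site_matrix,
    call_dmrs,
    segment_block,
)
from methepi.dmr import test_and_correct as run_candidate_tests
from methepi.synthetic import generate_reference, simulate_methylome_set


def make_matrix(positions, a_values, b_values, chrom="chr1"):
    """Assemble the per-site ratio matrix the caller operates on.

    ``a_values``/``b_values``: array (n_sites, n_replicates) of ratios.
    """
    a_values = np.atleast_2d(np.asarray(a_values, dtype=float).T).T
    b_values = np.atleast_2d(np.asarray(b_values, dtype=float).T).T
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.asarray(positions, dtype=np.int64),
            "end": np.asarray(positions, dtype=np.int64) + 2,
        }
    )
    for i in range(a_values.shape[1]):
        df[f"a{i}"] = a_values[:, i]
    for i in range(b_values.shape[1]):
        df[f"b{i}"] = b_values[:, i]
    return df


class TestCandidateBlocks:
    def test_evenly_spaced_sites_form_one_block(self):
        m = make_matrix(np.arange(12) * 100, np.full(12, 0.5), np.full(12, 0.1))
        blocks = build_candidate_blocks(m, DmrParams())
        assert len(blocks) == 1
        assert len(blocks[0]) == 12

    def test_too_few_sites_yield_no_block(self):
        m = make_matrix(np.arange(9) * 100, np.full(9, 0.5), np.full(9, 0.1))
        assert build_candidate_blocks(m, DmrParams()) == []

    def test_matches_bruteforce_gap_partition(self, rng):
        positions = np.sort(rng.choice(20_000, size=200, replace=False))
        m = make_matrix(positions, rng.uniform(0, 1, 200), rng.uniform(0, 1, 200))
        params = DmrParams(min_cpgs=3)
        blocks = build_candidate_blocks(m, params)
        # independent scalar partition by gap rule
        expected, run = [], [0]
        for i in range(1, len(positions)):
            if positions[i] - positions[i - 1] <= params.max_dist:
                run.append(i)
            else:
                expected.append(run)
                run = [i]
        expected.append(run)
        expected = [r for r in expected if len(r) >= params.min_cpgs]
        assert len(blocks) == len(expected)
        for block, idx in zip(blocks, expected):
            np.testing.assert_array_equal(block["start"], positions[idx])


def naive_segment(diffs, min_cpgs, min_meth_diff):
    """Independent scalar re-specification of the top-down CUSUM segmentation."""
    n = len(diffs)
    if n < min_cpgs:
        return []
    mean = sum(diffs) / n
    if abs(mean) >= min_meth_diff:
        return [(0, n)]
    if n < 2:
        return []
    best_k, best_val = 0, -1.0
    running = 0.0
    for k in range(n - 1):
        running += diffs[k] - mean
        if abs(running) > best_val:
            best_val, best_k = abs(running), k
    split = best_k + 1
    left = naive_segment(diffs[:split], min_cpgs, min_meth_diff)
    right = naive_segment(diffs[split:], min_cpgs, min_meth_diff)
    return left + [(s + split, e + split) for s, e in right]


class TestSegmentation:
    def test_homogeneous_block_emitted_whole(self):
        m = make_matrix(np.arange(15) * 50, np.full(15, 0.6), np.full(15, 0.1))
        out = segment_block(m, DmrParams())
        assert len(out) == 1 and len(out[0]) == 15

    def test_no_difference_emits_nothing(self):
        m = make_matrix(np.arange(15) * 50, np.full(15, 0.4), np.full(15, 0.4))
        assert segment_block(m, DmrParams()) == []

    def test_changepoint_block_emits_differential_half(self):
        """First 15 sites differ by 0.5, last 15 by 0; only the first half
        reaches a 0.5 threshold, and brute-force enumeration of contiguous
        qualifying windows agrees that 15 is the maximal qualifying length."""
        diffs = np.r_[np.full(15, 0.5), np.zeros(15)]
        m = make_matrix(np.arange(30) * 50, 0.4 + diffs, np.full(30, 0.4))
        params = DmrParams(min_meth_diff=0.5)
        out = segment_block(m, params)
        assert len(out) == 1
        np.testing.assert_array_equal(out[0]["start"], np.arange(15) * 50)
        qualifying = [
            (i, j)
            for i in range(30)
            for j in range(i + params.min_cpgs, 31)
            if abs(diffs[i:j].mean()) >= params.min_meth_diff
        ]
        assert max(j - i for i, j in qualifying) == 15
        assert (0, 15) in qualifying

    @pytest.mark.parametrize("trial", range(20))
    def test_equivalence_with_naive_recursion(self, trial):
        """Vectorized segmentation equals an independent scalar recursion
        on random instances of up to 100 sites."""
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(10, 101))
        a = rng.uniform(0, 1, size=(n, 2))
        b = np.clip(a - rng.choice([0.0, 0.3], size=(n, 1)), 0, 1)
        m = make_matrix(np.arange(n) * 40, a, b)
        params = DmrParams(min_cpgs=5, min_meth_diff=0.15)
        got = [
            (int(seg["start"].iloc[0]) // 40, int(seg["start"].iloc[-1]) // 40 + 1)
            for seg in segment_block(m, params)
        ]
        diffs = list(a.mean(axis=1) - b.mean(axis=1))
        assert got == naive_segment(diffs, params.min_cpgs, params.min_meth_diff)


class TestTestAndCorrect:
    def test_identical_groups_give_no_dmrs(self, rng):
        vals = rng.uniform(0, 1, size=(20, 3))
        m = make_matrix(np.arange(20) * 50, vals, vals.copy())
        assert call_dmrs_from_matrix(m) == []

    def test_fully_separated_candidate_retained_with_closed_form_p(self):
        m = make_matrix(np.arange(10) * 50, np.ones((10, 3)), np.zeros((10, 3)))
        out = run_candidate_tests([m], DmrParams())
        assert len(out) == 1
        dmr = out[0]
        assert dmr.q_value == dmr.p_value  # single candidate: BH is identity
        # closed-form normal-approximation U-test p for complete separation
        # of two fully tied groups of 30 values each
        n1 = n2 = 30
        n = n1 + n2
        u = n1 * n2
        tie_term = 2 * (30**3 - 30)
        sigma = np.sqrt(n1 * n2 / 12 * ((n + 1) - tie_term / (n * (n - 1))))
        z = (u - n1 * n2 / 2 - 0.5) / sigma
        expected_p = 2 * stats.norm.sf(z)
        assert dmr.p_value == pytest.approx(expected_p, rel=1e-9)

    def test_bh_against_independent_implementation(self, rng):
        """50 null candidates plus one separated one: only it survives FDR 0.1,
        and q-values match a hand-rolled Benjamini-Hochberg."""
        candidates = []
        for i in range(50):
            vals = rng.uniform(0.3, 0.7, size=(12, 3))
            jitter = vals + rng.normal(0, 0.02, size=(12, 3))
            candidates.append(
                make_matrix(np.arange(12) * 50 + 10_000 * i, vals, jitter)
            )
        candidates.append(
            make_matrix(np.arange(12) * 50 + 10_000 * 60, np.ones((12, 3)), np.zeros((12, 3)))
        )
        out = run_candidate_tests(candidates, DmrParams())
        assert len(out) == 1
        assert out[0].start == 10_000 * 60
        # independent BH: q_i = min_{j>=i} p_(j) * m / j
        pvals = []
        for cand in candidates:
            a = cand[["a0", "a1", "a2"]].to_numpy().ravel()
            b = cand[["b0", "b1", "b2"]].to_numpy().ravel()
            pvals.append(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        order = np.argsort(pvals)
        m_tests = len(pvals)
        ranked = np.array(pvals)[order] * m_tests / np.arange(1, m_tests + 1)
        qvals = np.minimum.accumulate(ranked[::-1])[::-1]
        assert out[0].q_value == pytest.approx(qvals[0])

    def test_small_candidate_dropped_with_warning(self):
        m = make_matrix([0], [[1.0]], [[0.0]])
        with pytest.warns(UserWarning, match="fewer than two"):
            assert run_candidate_tests([m], DmrParams()) == []


def call_dmrs_from_matrix(matrix, params=None):
    params = params or DmrParams()
    candidates = []
    for block in build_candidate_blocks(matrix, params):
        candidates.extend(segment_block(block, params))
    return run_candidate_tests(candidates, params)


def _cg_groups(methylomes, genotypes):
    return {
        g: [merge_cg_strands(r[r["context"] == "CG"]) for r in methylomes[g]]
        for g in genotypes
    }


@pytest.fixture(scope="module")
def synthetic_cg():
    config = SyntheticConfig(seed=31, genome_length=15_000)
    ref = generate_reference(config)
    methylomes, _ = simulate_methylome_set(config, ref)
    return _cg_groups(methylomes, ("wt", "dnmt1"))


class TestEndToEnd:
    def test_emitted_dmrs_satisfy_all_constraints(self, synthetic_cg):
        params = DmrParams()
        dmrs = call_dmrs(synthetic_cg["dnmt1"], synthetic_cg["wt"], params)
        assert len(dmrs) > 0
        assert (dmrs["n_cpgs"] >= params.min_cpgs).all()
        assert (dmrs["mean_diff"].abs() >= params.min_meth_diff).all()
        assert (dmrs["q_value"] <= params.fdr).all()
        assert (dmrs["start"] < dmrs["end"]).all()
        # non-overlap within chromosome
        for _, sub in dmrs.groupby("chrom"):
            sub = sub.sort_values("start")
            assert (sub["start"].to_numpy()[1:] >= sub["end"].to_numpy()[:-1]).all()

    def test_group_swap_negates_mean_diff(self, synthetic_cg):
        fwd = call_dmrs(synthetic_cg["dnmt1"], synthetic_cg["wt"])
        rev = call_dmrs(synthetic_cg["wt"], synthetic_cg["dnmt1"])
        pd.testing.assert_frame_equal(
            fwd.drop(columns="mean_diff"), rev.drop(columns="mean_diff")
        )
        np.testing.assert_allclose(fwd["mean_diff"], -rev["mean_diff"])

    def test_hypomethylated_mutant_dmrs_are_negative(self, synthetic_cg):
        dmrs = call_dmrs(synthetic_cg["dnmt1"], synthetic_cg["wt"])
        assert (dmrs["mean_diff"] < 0).mean() >= 0.9

    def test_site_matrix_enforces_min_coverage_in_every_sample(self, synthetic_cg):
        params = DmrParams(min_coverage=12)
        matrix = build_site_matrix(synthetic_cg["dnmt1"], synthetic_cg["wt"], params)
        recs = {**{}, "a": synthetic_cg["dnmt1"], "b": synthetic_cg["wt"]}
        for label, group in recs.items():
            for i, rec in enumerate(group):
                depth = (
                    rec.set_index(["chrom", "start"])["n_meth"]
                    + rec.set_index(["chrom", "start"])["n_unmeth"]
                )
                idx = pd.MultiIndex.from_frame(matrix[["chrom", "start"]])
                assert (depth.loc[idx] >= params.min_coverage).all()
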