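"""NMF metagenes: update properties, consensus rank selection, gene sets."""

import numpy as np
import pandas as pd
import pytest

from lgatlas.metagenes import (
    consensus_select_rank,
    metagene_genes,
    metagene_score,
    nmf_brunet,
)
from lgatlas.simulate import simulate_block_counts


def _frame(arr, prefix_g="g", prefix_s="s"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"{prefix_g}{i}" for i in range(arr.shape[0])],
        columns=[f"{prefix_s}{j}" for j in range(arr.shape[1])],
    )


class TestBrunetNMF:
    def test_exact_factorization_reaches_tiny_kl(self):
        rng = np.random.default_rng(0)
        V = _frame(rng.uniform(0, 5, (30, 3)) @ rng.uniform(0, 5, (3, 12)))
        m = nmf_brunet(V, 3, max_iter=5000, seed=1, stall_checks=None)
        assert m.kl < 1e-6

    def test_kl_trace_monotone_nonincreasing(self):
        rng = np.random.default_rng(1)
        for rep in range(10):
            V = _frame(rng.uniform(0.1, 50, (20, 10)))
            m = nmf_brunet(V, 3, max_iter=100, seed=rep, stall_checks=None)
            d = np.diff(m.kl_trace)
            assert (d <= 1e-9 * (1 + np.abs(m.kl_trace[:-1]))).all()

    def test_same_seed_bit_identical(self):
        V = _frame(np.random.default_rng(2).uniform(0.1, 10, (15, 8)))
        a = nmf_brunet(V, 2, max_iter=50, seed=9)
        b = nmf_brunet(V, 2, max_iter=50, seed=9)
        assert a.basis.equals(b.basis) and a.coef.equals(b.coef)

    def test_factors_nonnegative(self):
        V = _frame(np.random.default_rng(3).uniform(0, 10, (15, 8)))
        m = nmf_brunet(V, 3, max_iter=80, seed=0)
        assert (m.basis.to_numpy() >= 0).all() and (m.coef.to_numpy() >= 0).all()

    def test_rank_too_large_rejected(self):
        V = _frame(np.ones((5, 4)))
        with pytest.raises(ValueError, match="rank"):
            nmf_brunet(V, 4, seed=0)

    def test_zero_row_named_in_error(self):
        V = _frame(np.ones((5, 4)))
        V.loc["g2"] = 0.0
        with pytest.raises(ValueError, match="g2"):
            nmf_brunet(V, 2, seed=0)


class TestConsensus:
    def test_planted_three_blocks_selects_rank_three(self):
        counts, _, _ = simulate_block_counts(seed=11)
        sel = consensus_select_rank(
            counts, ranks=range(2, 6), runs=20, seed=11, max_iter=500
        )
        assert sel.chosen_rank == 3
        assert sel.cophenetic[3] > 0.95

    def test_noiseless_blocks_give_binary_consensus(self):
        counts, _, sample_truth = simulate_block_counts(background_noise=0, seed=1)
        sel = consensus_select_rank(counts, ranks=[3], runs=5, seed=1, max_iter=300)
        C = sel.consensus[3].to_numpy()
        assert set(np.unique(C)) <= {0.0, 1.0}
        assert sel.cophenetic[3] == pytest.approx(1.0)
        # consensus blocks match planted sample blocks exactly
        blocks = sample_truth.set_index("sample")["block"]
        expected = (
            blocks.to_numpy()[:, None] == blocks.to_numpy()[None, :]
        ).astype(float)
        assert np.array_equal(C, expected)

    def test_single_rank_list(self):
        counts, _, _ = simulate_block_counts(seed=5)
        sel = consensus_select_rank(counts, ranks=[3], runs=4, seed=5, max_iter=200)
        assert sel.chosen_rank == 3

    def test_degenerate_single_block_flagged_unstable(self):
        counts, _, _ = simulate_block_counts(
            n_blocks=1, samples_per_block=8, seed=7
        )
        sel = consensus_select_rank(
            counts, ranks=range(2, 5), runs=10, seed=7, max_iter=300
        )
        assert not sel.stable

    def test_consensus_permutation_equivariant(self):
        counts, _, _ = simulate_block_counts(seed=13)
        perm = list(counts.columns[::-1])
        a = consensus_select_rank(counts, ranks=[3], runs=6, seed=13, max_iter=300)
        b = consensus_select_rank(
            counts[perm], ranks=[3], runs=6, seed=13, max_iter=300
        )
        assert np.allclose(
            a.consensus[3].loc[perm, perm].to_numpy(), b.consensus[3].to_numpy()
        )

    def test_too_few_runs_rejected(self):
        counts, _, _ = simulate_block_counts(seed=1)
        with pytest.raises(ValueError, match="runs"):
            consensus_select_rank(counts, ranks=[3], runs=1)


class TestMetageneGenes:
    def test_threshold_rule(self):
        counts, _, _ = simulate_block_counts(seed=2)
        model = nmf_brunet(counts, 3, seed=2)
        model.basis.iloc[0] = [9.0, 1.0, 0.0]
        model.basis.iloc[1] = [3.0, 2.0, 0.0]
        sets = metagene_genes(model, threshold=0.8)
        g0, g1 = model.basis.index[0], model.basis.index[1]
        assert g0 in sets[0]
        assert all(g1 not in s for s in sets.values())

    def test_sets_disjoint(self):
        counts, _, _ = simulate_block_counts(seed=4)
        sets = metagene_genes(nmf_brunet(counts, 3, seed=4), threshold=0.8)
        all_genes = [g for s in sets.values() for g in s]
        assert len(all_genes) == len(set(all_genes))

    def test_planted_blocks_recovered(self):
        counts, gene_truth, _ = simulate_block_counts(seed=6)
        sets = metagene_genes(nmf_brunet(counts, 3, seed=6), threshold=0.8)
        truth = dict(zip(gene_truth.gene, gene_truth.block))
        assigned = {g for s in sets.values() for g in s}
        # precision: within each metagene, members share one planted block
        correct = sum(
            max(
                sum(truth[g] == b for g in genes)
                for b in set(truth.values())
            )
            for genes in sets.values() if genes
        )
        assert correct / len(assigned) >= 0.95
        assert len(assigned) / len(truth) >= 0.95  # recall

    def test_low_threshold_rejected(self):
        counts, _, _ = simulate_block_counts(seed=2)
        with pytest.raises(ValueError, match="0.5"):
            metagene_genes(nmf_brunet(counts, 3, seed=2), threshold=0.4)


@pytest.fixture(scope="module")
def sets_truth():
    counts, gene_truth, _ = simulate_block_counts(seed=8)
    model = nmf_brunet(counts, 3, seed=8)
    return metagene_genes(model), gene_truth


class TestMetageneScore:
    def test_block_elevated_sample_ranks_first(self, sets_truth):
        sets, gene_truth = sets_truth
        block0 = set(gene_truth[gene_truth.block == 0].gene)
        expr = pd.DataFrame(
            {"hep": [80.0 if g in block0 else 20.0 for g in gene_truth.gene]},
            index=gene_truth.gene,
        )
        scores = metagene_score(sets, expr)
        k0 = max(sets, key=lambda k: len(block0 & set(sets[k])))
        assert scores["hep"].idxmax() == k0

    def test_uniform_expression_scores_zero(self, sets_truth):
        sets, gene_truth = sets_truth
        expr = pd.DataFrame({"s": np.ones(len(gene_truth))}, index=gene_truth.gene)
        assert np.allclose(metagene_score(sets, expr)["s"], 0.0)

    def test_missing_set_gets_nan(self, sets_truth):
        sets, gene_truth = sets_truth
        sets = dict(sets)
        sets[99] = ["not_a_gene"]
        expr = pd.DataFrame(
            {"s": np.arange(len(gene_truth), dtype=float)}, index=gene_truth.gene
        )
        scores = metagene_score(sets, expr)
        assert np.isnan(scores.loc[99, "s"])
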