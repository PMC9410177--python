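"""Gene ranking, collinear-block chaining and duplication classification."""

import numpy as np
import pytest

from lignanscreen.errors import ValidationError
from lignanscreen.synteny import (
    AnchorPair,
    GeneModel,
    assign_ranks,
    chain_collinear_blocks,
    classify_duplicates,
    interspecies_synteny_fraction,
)


def genes_on(chrom, starts, prefix="g"):
    return [GeneModel(f"{prefix}{i}", chrom, s, s + 10) for i, s in enumerate(starts)]


class TestAssignRanks:
    def test_ranks_follow_start_order(self):
        ranked = assign_ranks(genes_on("c1", [100, 50, 200]))
        assert [g.rank for g in ranked] == [2, 1, 3]

    def test_chromosomes_rank_independently(self):
        genes = genes_on("c1", [100, 50]) + genes_on("c2", [10], prefix="h")
        ranked = assign_ranks(genes)
        assert [g.rank for g in ranked] == [2, 1, 1]

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        genes = genes_on("c1", list(rng.choice(10_000, size=40, replace=False)))
        ranked = {g.gene_id: g.rank for g in assign_ranks(genes)}
        shuffled = [genes[i] for i in rng.permutation(len(genes))]
        assert {g.gene_id: g.rank for g in assign_ranks(shuffled)} == ranked

    def test_duplicate_gene_id_errors(self):
        genes = [GeneModel("a", "c1", 1, 5), GeneModel("a", "c1", 10, 20)]
        with pytest.raises(ValidationError, match="duplicate"):
            assign_ranks(genes)


def make_instance(pairs, na=12, nb=12):
    """Build ranked gene sets and anchors from (rank_a, rank_b) pairs."""
    genes_a = assign_ranks(genes_on("A", [i * 100 for i in range(1, na + 1)],
                                    prefix="a"))
    genes_b = assign_ranks(genes_on("B", [i * 100 for i in range(1, nb + 1)],
                                    prefix="b"))
    by_rank_a = {g.rank: g.gene_id for g in genes_a}
    by_rank_b = {g.rank: g.gene_id for g in genes_b}
    anchors = [AnchorPair(by_rank_a[ra], by_rank_b[rb]) for ra, rb in pairs]
    return anchors, genes_a, genes_b


class TestChaining:
    def test_five_collinear_anchors_form_one_same_block(self):
        anchors, ga, gb = make_instance([(i, i) for i in range(1, 6)])
        blocks = chain_collinear_blocks(anchors, ga, gb, min_anchors=5)
        assert len(blocks) == 1
        assert blocks[0].orientation == "same"
        assert len(blocks[0].anchors) == 5

    def test_four_anchors_below_minimum_form_no_block(self):
        anchors, ga, gb = make_instance([(i, i) for i in range(1, 5)])
        assert chain_collinear_blocks(anchors, ga, gb, min_anchors=5) == []

    def test_inverted_block_detected(self):
        anchors, ga, gb = make_instance([(i, 7 - i) for i in range(1, 6)])
        blocks = chain_collinear_blocks(anchors, ga, gb, min_anchors=5)
        assert len(blocks) == 1
        assert blocks[0].orientation == "inverted"

    def test_gap_constraint_splits_chains(self):
        pairs = [(1, 1), (2, 2), (3, 3), (4, 4), (5, 5)]
        anchors, ga, gb = make_instance(pairs, na=40, nb=40)
        wide = [(p[0] * 6, p[1] * 6) for p in pairs]  # consecutive gaps of 6
        anchors_w, ga_w, gb_w = make_instance(wide, na=40, nb=40)
        assert chain_collinear_blocks(anchors_w, ga_w, gb_w,
                                      max_gap=5, min_anchors=5) == []
        assert len(chain_collinear_blocks(anchors_w, ga_w, gb_w,
                                          max_gap=6, min_anchors=5)) == 1


# --- exhaustive oracle ------------------------------------------------------


def _step_ok(p, q, direction, max_gap):
    da, db = q[0] - p[0], (q[1] - p[1]) * direction
    return 0 < da <= max_gap and 0 < db <= max_gap


def _best_chain_oracle(points, direction, max_gap):
    """All-chains enumeration; returns the max-length, lexicographically
    smallest chain as a list of (ra, rb)."""
    best = None
    n = len(points)

    def dfs(chain):
        nonlocal best
        key = (-len(chain), [points[i] for i in chain])
        if best is None or key < best:
            best = key
        for j in range(chain[-1] + 1, n):
            if _step_ok(points[chain[-1]], points[j], direction, max_gap):
                dfs(chain + [j])

    for i in range(n):
        dfs([i])
    return [] if best is None else best[1]


def oracle_blocks(pairs, max_gap, min_anchors):
    pool = sorted(pairs)
    out = []
    while pool:
        same = _best_chain_oracle(pool, 1, max_gap)
        inv = _best_chain_oracle(pool, -1, max_gap)
        chain, orient = (same, "same") if len(same) >= len(inv) else (inv, "inverted")
        if len(chain) < min_anchors:
            break
        out.append((orient, chain))
        used = set(chain)
        pool = [p for p in pool if p not in used]
    return out


class TestChainingOracle:
    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(123)
        for trial in range(200):
            n = int(rng.integers(2, 11))
            grid = [(int(a), int(b)) for a in range(1, 13) for b in range(1, 13)]
            idx = rng.choice(len(grid), size=n, replace=False)
            pairs = sorted(grid[i] for i in idx)
            max_gap = int(rng.integers(2, 8))
            min_anchors = int(rng.integers(2, 5))
            anchors, ga, gb = make_instance(pairs)
            blocks = chain_collinear_blocks(anchors, ga, gb,
                                            max_gap=max_gap,
                                            min_anchors=min_anchors)
            rank_a = {g.gene_id: g.rank for g in ga}
            rank_b = {g.gene_id: g.rank for g in gb}
            got = [(b.orientation,
                    [(rank_a[a.gene_a], rank_b[a.gene_b]) for a in b.anchors])
                   for b in blocks]
            # blocks are reported position-sorted, not in extraction order
            expected = sorted(oracle_blocks(pairs, max_gap, min_anchors),
                              key=lambda b: b[1][0][0])
            assert got == expected, f"trial {trial}: {pairs}"


class TestChainingProperties:
    def random_instance(self, rng, n=25):
        grid = [(int(a), int(b)) for a in range(1, 21) for b in range(1, 21)]
        idx = rng.choice(len(grid), size=n, replace=False)
        return make_instance(sorted(grid[i] for i in idx), na=22, nb=22)

    def test_each_anchor_in_at_most_one_block_and_monotone_ranks(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            anchors, ga, gb = self.random_instance(rng)
            blocks = chain_collinear_blocks(anchors, ga, gb, max_gap=6,
                                            min_anchors=3)
            seen = set()
            rank_a = {g.gene_id: g.rank for g in ga}
            rank_b = {g.gene_id: g.rank for g in gb}
            for b in blocks:
                ras = [rank_a[a.gene_a] for a in b.anchors]
                rbs = [rank_b[a.gene_b] for a in b.anchors]
                assert ras == sorted(ras) and len(set(ras)) == len(ras)
                if b.orientation == "same":
                    assert rbs == sorted(rbs)
                else:
                    assert rbs == sorted(rbs, reverse=True)
                for a in b.anchors:
                    assert (a.gene_a, a.gene_b) not in seen
                    seen.add((a.gene_a, a.gene_b))

    def test_lowering_min_anchors_never_reduces_block_count(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            anchors, ga, gb = self.random_instance(rng)
            strict = chain_collinear_blocks(anchors, ga, gb, max_gap=6,
                                            min_anchors=5)
            loose = chain_collinear_blocks(anchors, ga, gb, max_gap=6,
                                           min_anchors=3)
            assert len(loose) >= len(strict)


class TestClassifyDuplicates:
    def test_adjacent_paralogs_are_tandem(self):
        ranked = assign_ranks(genes_on("c1", [100, 200, 300]))
        calls = classify_duplicates([("g0", "g1")], [], ranked)
        assert calls[0].cls == "tandem"

    def test_block_anchor_pair_is_segmental(self):
        pairs = [(i, i) for i in range(1, 6)]
        anchors, ga, gb = make_instance(pairs)
        # place both gene sets in one genome: rename chrom B genes
        all_genes = ga + gb
        blocks = chain_collinear_blocks(anchors, all_genes, all_genes,
                                        min_anchors=5)
        calls = classify_duplicates([("a0", "b0"), ("a0", "b5")], blocks, all_genes)
        assert [c.cls for c in calls] == ["segmental", "dispersed"]

    def test_generator_planted_calls_recovered(self, dataset):
        ref = dataset.cfg.reference_variety
        ranked = assign_ranks(dataset.gene_models[ref])
        blocks = chain_collinear_blocks(dataset.anchors_intra, ranked, ranked)
        pairs = sorted(dataset.truth.duplication_calls)
        calls = classify_duplicates(pairs, blocks, ranked)
        got = {c.pair: c.cls for c in calls}
        assert got == dataset.truth.duplication_calls
        pod_calls = [c for p, c in got.items()
                     if dataset.truth.family_of[p[0]] == "POD"]
        assert pod_calls.count("segmental") == 18
        assert pod_calls.count("tandem") == 1


class TestSyntenyFraction:
    def block_covering(self, gene_ids):
        from lignanscreen.synteny import CollinearBlock
        anchors = [AnchorPair(g, f"other_{g}") for g in gene_ids]
        return CollinearBlock(anchors, "c1", "x1", "same")

    @pytest.mark.parametrize("n_syntenic,n_family,percent",
                             [(31, 83, 37), (26, 48, 54), (0, 60, 0)])
    def test_reported_percentages(self, n_syntenic, n_family, percent):
        family = {f"g{i}" for i in range(n_family)}
        blocks = ([self.block_covering([f"g{i}" for i in range(n_syntenic)])]
                  if n_syntenic else [])
        count, pct = interspecies_synteny_fraction(family, blocks)
        assert (count, pct) == (n_syntenic, percent)

    def test_empty_family_errors(self):
        with pytest.raises(ValidationError):
            interspecies_synteny_fraction(set(), [])

    def test_generator_syntenic_genes_recovered(self, dataset):
        ref = dataset.cfg.reference_variety
        ranked_ref = assign_ranks(dataset.gene_models[ref])
        ranked_at = assign_ranks(dataset.at_genes)
        blocks = chain_collinear_blocks(dataset.anchors_cross, ranked_ref,
                                        ranked_at)
        side_a = {a.gene_a for b in blocks for a in b.anchors}
        assert side_a == dataset.truth.syntenic_genes
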