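"""Collinear-block chaining and duplication-mode classification."""

import itertools

import numpy as np
import pytest

from panscan.core_io import ConfigError, ProteinRecord, ValidationError
from panscan.duplication_synteny import (
    CollinearBlock,
    HomologPair,
    build_cnv_matrix,
    classify_duplications,
    compute_similarity_pairs,
    find_collinear_blocks,
    read_homolog_pairs,
)
from panscan.duplication_synteny import _chain_dp


def brute_force_best_chain(points, max_gap):
    """Exhaustive longest valid chain over (rank_a, rank_b) points."""
    best = 0
    n = len(points)
    for orientation in ("same", "inverted"):
        for size in range(n, best, -1):
            found = False
            for combo in itertools.combinations(range(n), size):
                pts = sorted(points[i] for i in combo)
                ok = True
                for (a1, b1), (a2, b2) in zip(pts, pts[1:]):
                    if not 0 < a2 - a1 <= max_gap:
                        ok = False
                        break
                    step = b2 - b1 if orientation == "same" else b1 - b2
                    if not 0 < step <= max_gap:
                        ok = False
                        break
                if ok:
                    best = max(best, size)
                    found = True
                    break
            if found:
                break
    return best


class TestChainDP:
    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 13))
            pts = [
                (int(rng.integers(0, 30)), int(rng.integers(0, 30)))
                for _ in range(n)
            ]
            pts = list(dict.fromkeys(pts))
            indexed = [(a, b, i) for i, (a, b) in enumerate(pts)]
            dp_best = max(
                len(_chain_dp(indexed, o, 25)) for o in ("same", "inverted")
            )
            assert dp_best == brute_force_best_chain(pts, 25)

    def test_inverted_orientation_found(self):
        pairs = [HomologPair.make(f"a{i}", f"b{i}") for i in range(6)]
        ranks = {}
        for i, p in enumerate(pairs):
            ranks[p.gene_a] = ("cA", i)
            ranks[p.gene_b] = ("cB", 10 - i)
        (block,) = find_collinear_blocks(pairs, ranks, min_anchors=5)
        assert block.orientation == "inverted"
        assert len(block.anchors) == 6


class TestFindBlocks:
    def _planted(self, n_anchors, offset=0):
        pairs = [
            HomologPair.make(f"a{i}", f"b{i}") for i in range(n_anchors)
        ]
        ranks = {}
        for i, p in enumerate(pairs):
            ranks[p.gene_a] = ("cA", i + offset)
            ranks[p.gene_b] = ("cB", i + offset)
        return pairs, ranks

    def test_planted_chain_recovered(self):
        pairs, ranks = self._planted(8)
        (block,) = find_collinear_blocks(pairs, ranks)
        assert len(block.anchors) == 8

    def test_below_min_anchors_discarded(self):
        pairs, ranks = self._planted(4)
        assert find_collinear_blocks(pairs, ranks, min_anchors=5) == []

    def test_lowering_min_anchors_monotone(self, rng):
        pairs = []
        ranks = {}
        k = 0
        for i in range(40):
            a, b = f"a{k}", f"b{k}"
            k += 1
            ranks[a] = ("cA", int(rng.integers(0, 60)))
            ranks[b] = ("cB", int(rng.integers(0, 60)))
            pairs.append(HomologPair.make(a, b))
        prev: set[frozenset] = set()
        for min_anchors in (8, 6, 5, 4, 3):
            blocks = find_collinear_blocks(pairs, ranks, min_anchors=min_anchors)
            found = {frozenset(b.anchor_set) for b in blocks}
            assert all(any(p <= f for f in found) for p in prev)
            prev = found

    def test_gene_without_rank_rejected(self):
        with pytest.raises(ValidationError):
            find_collinear_blocks([HomologPair.make("a", "b")], {"a": ("c", 0)})

    def test_each_pair_in_at_most_one_block(self):
        pairs, ranks = self._planted(12)
        blocks = find_collinear_blocks(pairs, ranks)
        seen = [p for b in blocks for p in b.anchor_set]
        assert len(seen) == len(set(seen))


def _linear_ranks(genes, chrom="c1"):
    return {g: (chrom, i) for i, g in enumerate(genes)}


class TestClassifyDuplications:
    def test_tandem_adjacent(self):
        genes = [f"g{i}" for i in range(10)]
        ranks = _linear_ranks(genes)
        calls = classify_duplications(
            [HomologPair.make("g3", "g4")], [], ranks, [], ["g3", "g4"]
        )
        assert {c.mode for c in calls} == {"TD"}

    def test_proximal_window(self):
        genes = [f"g{i}" for i in range(20)]
        ranks = _linear_ranks(genes)
        calls = classify_duplications(
            [HomologPair.make("g2", "g9")], [], ranks, [], ["g2", "g9"],
            proximal_window=10,
        )
        assert {c.mode for c in calls} == {"PD"}

    def test_beyond_window_not_proximal(self):
        genes = [f"g{i:02d}" for i in range(30)]
        ranks = _linear_ranks(genes)
        calls = classify_duplications(
            [HomologPair.make("g02", "g20")], [], ranks, [], ["g02", "g20"],
        )
        assert all(c.mode == "DSD" for c in calls)

    def test_block_anchor_is_wgd(self):
        pairs = [HomologPair.make(f"a{i}", f"b{i}") for i in range(6)]
        ranks = {}
        for i, p in enumerate(pairs):
            ranks[p.gene_a] = ("cA", i)
            ranks[p.gene_b] = ("cB", i)
        blocks = find_collinear_blocks(pairs, ranks)
        calls = classify_duplications(
            [pairs[2]], blocks, ranks, [], [pairs[2].gene_a, pairs[2].gene_b]
        )
        assert {c.mode for c in calls} == {"WGD"}

    def test_transposed_one_ancestral(self):
        # g1 keeps outgroup collinearity (anchor in an outgroup block);
        # its duplicate gX sits on another chromosome with no collinearity.
        genome_genes = [f"g{i}" for i in range(8)]
        outgroup_genes = [f"o{i}" for i in range(8)]
        ranks = _linear_ranks(genome_genes, "cA")
        ranks.update(_linear_ranks(outgroup_genes, "cO"))
        ranks["gX"] = ("cB", 0)
        out_pairs = [
            HomologPair.make(g, o) for g, o in zip(genome_genes, outgroup_genes)
        ]
        out_blocks = find_collinear_blocks(out_pairs, ranks)
        assert out_blocks
        calls = classify_duplications(
            [HomologPair.make("g1", "gX")], [], ranks, out_blocks, ["g1", "gX"]
        )
        assert {c.mode for c in calls} == {"TRD"}

    def test_singleton_without_pair(self):
        ranks = _linear_ranks(["g0", "g1"])
        calls = classify_duplications([], [], ranks, [], ["g0"])
        assert calls[0].mode == "SINGLETON" and calls[0].partner == ""

    def test_partition_every_gene_one_call(self, pipeline_result):
        calls = pipeline_result.duplication_calls
        assert not calls.duplicated(subset=["genome", "gene_id"]).any()
        genes = pipeline_result.dataset.genome_set.genes
        for genome in calls["genome"].unique():
            fam = set(
                genes[(genes["genome"] == genome) & (genes["family"] != "none")][
                    "gene_id"
                ]
            )
            assert set(calls[calls["genome"] == genome]["gene_id"]) == fam


class TestSimilarityPairs:
    def test_identical_sequences_kept(self):
        seq = "MGNACSKDKEDKE" * 10
        prots = [ProteinRecord("a", sequence=seq), ProteinRecord("b", sequence=seq)]
        (pair,) = compute_similarity_pairs(prots, floor=100.0)
        assert pair.gene_a == "a" and pair.score > 500

    def test_unrelated_random_dropped(self, rng):
        AA20 = "ACDEFGHIKLMNPQRSTVWY"
        kept = 0
        for i in range(20):
            prots = [
                ProteinRecord(
                    f"p{j}",
                    sequence="".join(AA20[k] for k in rng.integers(0, 20, 100)),
                )
                for j in range(2)
            ]
            kept += len(compute_similarity_pairs(prots, floor=100.0))
        assert kept == 0

    def test_single_protein_empty(self):
        assert compute_similarity_pairs(
            [ProteinRecord("a", sequence="MGNACSK")], floor=50.0
        ) == []

    def test_nonpositive_floor_rejected(self):
        with pytest.raises(ConfigError):
            compute_similarity_pairs([], floor=0.0)


class TestHomologPairIO:
    def test_headered_table(self, tmp_path):
        p = tmp_path / "pairs.tsv"
        p.write_text("gene_a\tgene_b\tscore\nb\ta\t12.5\n")
        (pair,) = read_homolog_pairs(p)
        assert (pair.gene_a, pair.gene_b, pair.score) == ("a", "b", 12.5)

    def test_blast_outfmt6(self, tmp_path):
        p = tmp_path / "pairs.tsv"
        row = ["gA", "gB", "98.1", "500", "5", "0", "1", "500", "1", "500",
               "1e-100", "345"]
        p.write_text("\t".join(row) + "\n")
        (pair,) = read_homolog_pairs(p)
        assert pair.score == 345.0


class TestCnvMatrix:
    def test_counts_and_absences(self, default_dataset):
        cnv = build_cnv_matrix(default_dataset.genome_set.genes)
        genes = default_dataset.genome_set.genes
        first = default_dataset.config.genomes[0].genome.label
        fam = genes[genes["family"] != "none"]
        per_family = (
            fam[fam["genome"] == first].groupby("family").size().to_dict()
        )
        assert per_family == {"CCaMK": 1, "CPK": 29, "CRK": 5, "PEPRK": 2,
                              "PPCK": 3}
        assert int(cnv[first].sum()) == 40

    def test_duplicated_group_counts_two(self, default_dataset):
        cnv = build_cnv_matrix(default_dataset.genome_set.genes)
        truth = default_dataset.genome_set.duplication_truth
        for r in truth.itertuples():
            assert cnv.loc[r.ortholog_group, r.genome] == 2
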