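"""Supermatrix construction, p-distance, NJ preview."""

import random

import numpy as np
import pandas as pd
import pytest

from mitocharacter.phylo import (
    PCG_ORDER,
    concatenate_pcgs,
    neighbor_joining,
    p_distance_matrix,
)
from mitocharacter.simulate import SyntheticSpec, generate_genome


def _genomes(seeds):
    out = []
    for s in seeds:
        seq, ann, _ = generate_genome(SyntheticSpec(seed=s))
        ann.genome_id = f"t{s}"
        out.append((ann, seq))
    return out


class TestConcatenate:
    def test_single_genome_length_is_sum_of_pcgs(self):
        from mitocharacter.annotation import feature_length

        (ann, seq), = _genomes([1])
        sm = concatenate_pcgs([(ann, seq)])
        assert sm.length == sum(feature_length(f, ann.length) for f in ann.pcgs)
        assert [g for g, _, _ in sm.partitions] == list(PCG_ORDER)
        starts = [a for _, a, _ in sm.partitions]
        ends = [b for _, _, b in sm.partitions]
        assert starts[0] == 1 and ends[-1] == sm.length
        assert all(a2 == b1 + 1 for b1, a2 in zip(ends, starts[1:]))  # tiling

    def test_identical_genomes_give_identical_rows(self):
        (ann, seq), = _genomes([2])
        import copy

        ann2 = copy.deepcopy(ann)
        ann2.genome_id = "copy"
        sm = concatenate_pcgs([(ann, seq), (ann2, seq)])
        assert sm.sequences[0] == sm.sequences[1]

    def test_l_strand_gene_is_reverse_complemented_and_last(self):
        from mitocharacter.annotation import extract_feature_sequence

        (ann, seq), = _genomes([3])
        sm = concatenate_pcgs([(ann, seq)])
        gene, a, b = sm.partitions[-1]
        assert gene == "nad6" and ann.get("nad6").strand == "L"
        block = sm.sequences[0][a - 1: b]
        assert block.rstrip("-") == extract_feature_sequence(seq, ann.get("nad6"))
        assert block.startswith("ATG")

    def test_missing_gene_names_taxon_and_gene(self, toy):
        F, make = toy
        ann = make([F("nad1", 1, 9)], 20, genome_id="incomplete_taxon")
        with pytest.raises(ValueError, match="incomplete_taxon.*nad2"):
            concatenate_pcgs([(ann, "ATGAAATAAACGTACGTACG")])


class TestPDistance:
    def test_identical_rows_zero_and_simple_case(self):
        from mitocharacter.phylo import Supermatrix

        sm = Supermatrix(["a", "b"], ["AAAA", "AAAT"], [("g", 1, 4)])
        dm = p_distance_matrix(sm)
        assert dm.loc["a", "a"] == 0 and dm.loc["a", "b"] == 0.25

    def test_gapped_sites_excluded(self):
        from mitocharacter.phylo import Supermatrix

        sm = Supermatrix(["a", "b"], ["AA-T", "AAC-"], [("g", 1, 4)])
        dm = p_distance_matrix(sm)
        assert dm.loc["a", "b"] == 0  # only the first two sites are comparable

    def test_matches_brute_force_site_loop(self):
        rng = random.Random(7)
        rows = ["".join(rng.choice("ACGT-") for _ in range(300)) for _ in range(3)]
        from mitocharacter.phylo import Supermatrix

        sm = Supermatrix(["a", "b", "c"], rows, [("g", 1, 300)])
        dm = p_distance_matrix(sm)
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            diff = comparable = 0
            for x, y in zip(rows[i], rows[j]):
                if x != "-" and y != "-":
                    comparable += 1
                    diff += x != y
            assert dm.iloc[i, j] == pytest.approx(diff / comparable)

    def test_symmetry_and_zero_diagonal(self):
        sm_rows = _genomes([1, 2, 3])
        from mitocharacter.phylo import concatenate_pcgs

        dm = p_distance_matrix(concatenate_pcgs(sm_rows))
        assert np.allclose(dm.to_numpy(), dm.to_numpy().T)
        assert np.allclose(np.diag(dm.to_numpy()), 0)


def _tree_distances(n, rng):
    """Simulate an additive tree bottom-up, tracking exact leaf distances."""
    clusters = [[f"L{i}"] for i in range(n)]
    depth = {f"L{i}": 0.0 for i in range(n)}
    dist = {}
    splits = []
    while len(clusters) > 1:
        i, j = sorted(rng.sample(range(len(clusters)), 2))
        ci, cj = clusters[i], clusters[j]
        bi, bj = rng.uniform(0.05, 1.0), rng.uniform(0.05, 1.0)
        for t in ci:
            depth[t] += bi
        for t in cj:
            depth[t] += bj
        for a in ci:
            for b in cj:
                dist[frozenset((a, b))] = depth[a] + depth[b]
        merged = ci + cj
        if 2 <= len(merged) <= n - 2:
            splits.append(frozenset(merged))
        clusters = [clusters[k] for k in range(len(clusters)) if k not in (i, j)]
        clusters.append(merged)
    labels = sorted(depth)
    mat = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            d = dist[frozenset((labels[a], labels[b]))]
            mat[a, b] = mat[b, a] = d
    return labels, mat, splits


def _newick_splits(newick, labels):
    """Non-trivial splits of an unrooted newick tree via skbio."""
    from io import StringIO

    from skbio import TreeNode

    tree = TreeNode.read(StringIO(newick))
    n = len(labels)
    out = set()
    for node in tree.non_tips():
        tips = frozenset(t.name for t in node.tips())
        if 2 <= len(tips) <= n - 2:
            out.add(tips)
            out.add(frozenset(set(labels) - tips))
    return out


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        # d(ab)=3, d(ac)=5, d(bc)=6 -> branch lengths 1, 2, 4
        dm = pd.DataFrame([[0, 3, 5], [3, 0, 6], [5, 6, 0]],
                          index=list("abc"), columns=list("abc"))
        newick = neighbor_joining(dm)
        from io import StringIO

        from skbio import TreeNode

        tree = TreeNode.read(StringIO(newick))
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 4.0})

    def test_additive_four_taxon_topology(self):
        # ((a,b),(c,d)) with internal branch 3
        dm = pd.DataFrame(
            [[0, 2, 7, 7], [2, 0, 7, 7], [7, 7, 0, 2], [7, 7, 2, 0]],
            index=list("abcd"), columns=list("abcd"), dtype=float)
        splits = _newick_splits(neighbor_joining(dm), list("abcd"))
        assert frozenset({"a", "b"}) in splits

    @pytest.mark.parametrize("n,seed", [(5, 0), (6, 1), (7, 2), (8, 3)])
    def test_recovers_random_additive_trees(self, n, seed):
        labels, mat, true_splits = _tree_distances(n, random.Random(seed))
        dm = pd.DataFrame(mat, index=labels, columns=labels)
        splits = _newick_splits(neighbor_joining(dm), labels)
        for split in true_splits:
            comp = frozenset(set(labels) - split)
            assert split in splits or comp in splits

    def test_non_symmetric_matrix_rejected(self):
        dm = np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            neighbor_joining(dm, ["a", "b", "c"])

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError, match="3 taxa"):
            neighbor_joining(np.zeros((2, 2)), ["a", "b"])
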