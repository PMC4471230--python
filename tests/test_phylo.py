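"""K2P distances, neighbor joining (exact on additive matrices), bootstrap."""

import itertools
import math

import numpy as np
import pytest

from conftest import random_genome

from paleomito.phylo import (
    DistanceMatrix,
    bootstrap_support,
    clade_support,
    distance_matrix,
    k2p_distance,
    nj_tree,
)


class TestK2P:
    def test_identical_sequences(self):
        assert k2p_distance("ACGT" * 25, "ACGT" * 25) == 0.0

    def test_closed_form_ten_transitions(self):
        """100 sites, 10 transitions, 0 transversions -> 0.5*ln(1/0.8)."""
        a = "A" * 100
        b = "G" * 10 + "A" * 90
        assert k2p_distance(a, b) == pytest.approx(0.5 * math.log(1 / 0.8))
        assert k2p_distance(a, b) == pytest.approx(0.1116, abs=1e-4)

    def test_transversions_enter_second_term(self):
        a = "A" * 100
        b = "C" * 8 + "A" * 92  # Q = 0.08, P = 0
        expect = -0.5 * math.log(1 - 0.08) - 0.25 * math.log(1 - 0.16)
        assert k2p_distance(a, b) == pytest.approx(expect)

    def test_symmetry(self):
        x = random_genome(300, seed=100).seq
        y = random_genome(300, seed=101).seq[:300]
        assert k2p_distance(x, y) == pytest.approx(k2p_distance(y, x))

    def test_gap_and_n_sites_excluded_pairwise(self):
        a = "ACGTA" + "A" * 20
        b = "-CGTN" + "A" * 20
        assert k2p_distance(a, b) == 0.0

    def test_saturation_is_nan(self):
        a = "A" * 10
        b = "G" * 10  # P = 1: 1 - 2P - Q < 0
        assert math.isnan(k2p_distance(a, b))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            k2p_distance("ACGT", "ACG")


def _tree_distances(n_taxa, rng):
    """Random binary tree -> (additive distance matrix, set of splits)."""
    # build by random sequential attachment; track leaf-to-leaf path lengths
    import collections

    adj = collections.defaultdict(dict)
    nodes = ["L0", "L1", "L2"]
    centre = "I0"
    for leaf in nodes:
        adj[centre][leaf] = adj[leaf][centre] = round(float(rng.uniform(0.05, 1.0)), 3)
    n_internal = 1
    for i in range(3, n_taxa):
        # split a random edge, hang the new leaf off the midpoint
        a = list(adj)[int(rng.integers(len(adj)))]
        b = list(adj[a])[int(rng.integers(len(adj[a])))]
        w = adj[a][b]
        mid = f"I{n_internal}"
        n_internal += 1
        del adj[a][b], adj[b][a]
        adj[a][mid] = adj[mid][a] = round(w / 2, 6)
        adj[b][mid] = adj[mid][b] = round(w - w / 2, 6)
        leaf = f"L{i}"
        adj[mid][leaf] = adj[leaf][mid] = round(float(rng.uniform(0.05, 1.0)), 3)
    leaves = sorted(n for n in adj if n.startswith("L"))

    def path(u, v):
        # BFS with accumulated lengths
        import heapq

        seen = {u: 0.0}
        todo = [(0.0, u)]
        while todo:
            d, x = heapq.heappop(todo)
            if x == v:
                return d
            for y, w in adj[x].items():
                if y not in seen or seen[y] > d + w:
                    seen[y] = d + w
                    heapq.heappush(todo, (d + w, y))
        raise RuntimeError

    m = np.zeros((len(leaves), len(leaves)))
    for i, u in enumerate(leaves):
        for j in range(i + 1, len(leaves)):
            m[i, j] = m[j, i] = path(u, leaves[j])

    splits = set()
    anchor = leaves[0]
    for x in adj:
        for y in adj[x]:
            if x < y:
                # leaves on y's side when edge x-y removed
                stack, seen = [y], {x, y}
                side = set()
                while stack:
                    z = stack.pop()
                    if z.startswith("L"):
                        side.add(z)
                    for w in adj[z]:
                        if w not in seen:
                            seen.add(w)
                            stack.append(w)
                if 1 < len(side) < len(leaves) - 1:
                    splits.add(
                        frozenset(side) if anchor not in side
                        else frozenset(leaves) - side
                    )
    return DistanceMatrix(leaves, m), splits


class TestNeighborJoining:
    def test_three_taxa_three_point_formula(self):
        m = DistanceMatrix(["a", "b", "c"], np.array(
            [[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]]
        ))
        tree = nj_tree(m)
        lengths = {c.name: bl for c, bl in tree.root.children}
        assert lengths["a"] == pytest.approx(0.5 * (0.3 + 0.5 - 0.6))
        assert lengths["b"] == pytest.approx(0.5 * (0.3 + 0.6 - 0.5))
        assert lengths["c"] == pytest.approx(0.5 * (0.5 + 0.6 - 0.3))

    @pytest.mark.parametrize("n_taxa", [4, 5, 6])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exact_on_additive_matrices(self, n_taxa, seed):
        """NJ recovers the generating topology from additive distances."""
        m, true_splits = _tree_distances(n_taxa, np.random.default_rng(seed))
        assert nj_tree(m).splits() == true_splits

    def test_agrees_with_skbio_on_additive_input(self):
        skbio = pytest.importorskip("skbio")
        m, true_splits = _tree_distances(6, np.random.default_rng(7))
        sk_tree = skbio.tree.nj(skbio.DistanceMatrix(m.values, m.taxa))
        anchor = m.taxa[0]
        sk_splits = set()
        all_leaves = frozenset(m.taxa)
        for node in sk_tree.non_tips():
            side = frozenset(t.name for t in node.tips())
            if 1 < len(side) < len(all_leaves) - 1:
                sk_splits.add(side if anchor not in side else all_leaves - side)
        assert sk_splits == true_splits == nj_tree(m).splits()

    def test_taxon_permutation_invariance(self):
        m, _ = _tree_distances(6, np.random.default_rng(3))
        perm = [3, 1, 5, 0, 4, 2]
        m2 = DistanceMatrix(
            [m.taxa[i] for i in perm], m.values[np.ix_(perm, perm)]
        )
        assert nj_tree(m).splits() == nj_tree(m2).splits()

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], np.zeros((2, 2))))


def _clade_alignment(rng, n_sites=2000):
    """Two clearly separated clades plus tip noise."""
    anc = "".join("ACGT"[i] for i in rng.integers(0, 4, n_sites))

    def mutate(seq, k):
        out = list(seq)
        for p in rng.choice(n_sites, size=k, replace=False):
            out[p] = {"A": "G", "G": "A", "C": "T", "T": "C"}[out[p]]
        return "".join(out)

    left = mutate(anc, 120)
    right = mutate(anc, 120)
    return {
        "l1": mutate(left, 8), "l2": mutate(left, 8), "l3": mutate(left, 8),
        "r1": mutate(right, 8), "r2": mutate(right, 8),
    }


class TestBootstrap:
    def test_clear_clades_reach_full_support(self):
        aln = _clade_alignment(np.random.default_rng(11))
        tree = bootstrap_support(aln, 200, seed=1)
        assert clade_support(tree, ["l1", "l2", "l3"]) >= 95.0

    def test_zero_replicates_gives_no_supports(self):
        aln = _clade_alignment(np.random.default_rng(12))
        tree = bootstrap_support(aln, 0, seed=1)
        assert all(
            node.support is None for node in tree.split_nodes().values()
        )

    def test_seeded_determinism(self):
        aln = _clade_alignment(np.random.default_rng(13))
        t1 = bootstrap_support(aln, 100, seed=5)
        t2 = bootstrap_support(aln, 100, seed=5)
        assert t1.newick() == t2.newick()

    def test_basal_taxon_attaches_outside_modern_clade(self):
        """An 'ancient' sequence with private variants, a modern clade with
        shared derived variants, and an outgroup retaining the ancestral
        state at those sites: the ancient leaf falls outside the modern
        clade with high support."""
        rng = np.random.default_rng(14)
        n = 4000
        ref = "".join("ACGT"[i] for i in rng.integers(0, 4, n))
        ts = {"A": "G", "G": "A", "C": "T", "T": "C"}

        def mutate(seq, positions):
            out = list(seq)
            for p in positions:
                out[p] = ts[out[p]]
            return "".join(out)

        sites = rng.choice(n, size=400, replace=False)
        ancient_private = sites[:15]
        modern_derived = sites[15:30]  # ancient keeps the ancestral state here
        stem = sites[30:100]
        og_sites = sites[100:250]
        ancient = mutate(ref, list(ancient_private) + list(modern_derived))
        # NB: 'ref' plays the modern reference; ancestral = ref + modern_derived
        anc_state = mutate(ref, modern_derived)
        aln = {"ancient": ancient, "modern_ref": ref}
        for i in range(4):
            priv = rng.choice(n, size=3, replace=False)
            aln[f"modern_{i}"] = mutate(ref, priv)
        outgroup_base = mutate(mutate(anc_state, stem), og_sites)
        aln["outgroup"] = outgroup_base
        tree = bootstrap_support(aln, 200, seed=2)
        moderns = ["modern_ref"] + [f"modern_{i}" for i in range(4)]
        support = clade_support(tree, moderns)
        assert support is not None and support >= 95.0
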