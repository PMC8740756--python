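"""Pileup, majority consensus, distances, neighbor joining, lineage calls."""

from __future__ import annotations

import numpy as np
import pytest

from sedadna import simulate as sim
from sedadna.consensus import (
    DiagnosticPanel,
    DiagnosticSite,
    assign_lineage,
    bipartitions,
    bootstrap_support,
    build_pileup,
    call_consensus,
    distance_matrix,
    internal_consistency,
    neighbor_joining,
    pairwise_differences,
)
from sedadna.damage import filter_deaminated
from tests.conftest import (
    aligned_from_truth,
    make_fragment,
    simulate_deaminated_library,
)

GENOME = "".join(np.random.default_rng(123).choice(list("ACGT"), 2000))


def pileup_from_reads(reads_at_zero: list[str], L: int = 50):
    """Pileup of plus-strand reads all starting at position 0."""
    frags = [
        make_fragment(GENOME[:len(r)], r, fragment_id=f"r{i}", start=0)
        for i, r in enumerate(reads_at_zero)
    ]
    return build_pileup(frags, "ref", L, dedupe=False)


class TestPileup:
    def test_duplicates_collapsed(self):
        a = make_fragment(GENOME[:30], GENOME[:30], "a", start=0)
        b = make_fragment(GENOME[:30], GENOME[:30], "b", start=0)
        pile = build_pileup([a, b], "ref", 100)
        assert pile.coverage[:30].max() == 1
        assert len(pile.fragment_ids) == 1

    def test_disjoint_fragments_disjoint_coverage(self):
        a = make_fragment(GENOME[:20], GENOME[:20], "a", start=0)
        b = make_fragment(GENOME[40:60], GENOME[40:60], "b", start=40)
        pile = build_pileup([a, b], "ref", 100)
        assert pile.coverage[:20].all() and pile.coverage[40:60].all()
        assert not pile.coverage[20:40].any()

    def test_empty_input_zero_coverage(self):
        pile = build_pileup([], "ref", 100)
        assert pile.coverage.sum() == 0

    def test_out_of_bounds_without_wrap_rejected(self):
        bad = make_fragment(GENOME[:30], GENOME[:30], "a", start=90)
        with pytest.raises(ValueError, match="wrap"):
            build_pileup([bad], "ref", 100)

    def test_wrapping_fragment_folds_back(self):
        frag = aligned_from_truth(GENOME[:100], 90, 20, "+",
                                  GENOME[90:100] + GENOME[:10], "w")
        pile = build_pileup([frag], "ref", 100)
        assert pile.coverage[90:].all() and pile.coverage[:10].all()

    def test_minus_strand_counted_on_forward_reference(self):
        read = sim.revcomp(GENOME[10:40])
        frag = aligned_from_truth(GENOME, 10, 30, "-", read, "m")
        pile = build_pileup([frag], "ref", 2000)
        g = np.array(list(GENOME[10:40]))
        idx = np.array([{"A": 0, "C": 1, "G": 2, "T": 3}[b] for b in g])
        assert (pile.counts[np.arange(10, 40), idx] == 1).all()


class TestCallConsensus:
    def test_two_of_three_called(self):
        """{A:2, T:1}: support 0.667 ≥ 0.66 → A."""
        pile = pileup_from_reads(["A", "A", "T"])
        cons = call_consensus(pile)
        assert cons.calls[0] == "A"

    def test_single_coverage_uncalled(self):
        pile = pileup_from_reads(["A"])
        assert call_consensus(pile).calls[0] == "N"

    def test_even_split_uncalled(self):
        pile = pileup_from_reads(["A", "T"])
        assert call_consensus(pile).calls[0] == "N"

    def test_covered_fraction(self):
        pile = pileup_from_reads(["AAA", "AAA"], L=10)
        assert call_consensus(pile).covered_fraction == pytest.approx(0.3)


class TestInternalConsistency:
    def test_seventy_percent_support_flagged(self):
        pile = pileup_from_reads(["A"] * 7 + ["T"] * 3)
        flagged = internal_consistency(pile)
        assert [f.position for f in flagged] == [0]
        assert flagged[0].support == pytest.approx(0.7)

    def test_strong_support_not_flagged(self):
        pile = pileup_from_reads(["A"] * 11 + ["T"])
        assert internal_consistency(pile) == []

    def test_below_min_coverage_not_evaluated(self):
        pile = pileup_from_reads(["A"] * 5 + ["T"] * 4)
        assert internal_consistency(pile) == []

    def test_minor_allele_end_proximity_reported(self):
        # minor T observed at read position 1 => within 3 bases of the end
        pile = pileup_from_reads(["A" * 10] * 7 + ["T" + "A" * 9] * 3, L=20)
        (f,) = internal_consistency(pile)
        assert f.minor_end_proximal_fraction == pytest.approx(1.0)


class TestPairwiseDifferences:
    def test_identical_and_counted_differences(self):
        assert pairwise_differences("ACGT", "ACGT") == (0, 4)
        assert pairwise_differences("AAAA", "TTTA") == (3, 4)

    def test_n_positions_excluded(self):
        assert pairwise_differences("ANGT", "ACGA") == (1, 3)

    def test_no_co_called_positions_undefined(self):
        with pytest.raises(ValueError, match="co-called"):
            pairwise_differences("NNAA", "TTNN")

    def test_symmetry_and_self_zero(self):
        a, b = "ACGTNACGT", "ACTTNACGA"
        assert pairwise_differences(a, b) == pairwise_differences(b, a)
        assert pairwise_differences(a, a)[0] == 0


def random_additive_tree(n_taxa: int, rng: np.random.Generator):
    """Random unrooted binary tree; returns (labels, D, bipartitions).

    Oracle for NJ: the distance matrix is additive by construction (path
    lengths on the tree), so NJ must recover the topology exactly.
    """
    labels = [f"t{i:02d}" for i in range(n_taxa)]
    adj: dict[int, dict[int, float]] = {}
    node_of = {}

    def add_edge(u, v, w):
        adj.setdefault(u, {})[v] = w
        adj.setdefault(v, {})[u] = w

    nxt = n_taxa
    # star over first three leaves
    centre = nxt
    nxt += 1
    for leaf in range(3):
        add_edge(leaf, centre, float(rng.uniform(0.1, 1.0)))
    for leaf in range(3, n_taxa):
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        u, v = edges[int(rng.integers(len(edges)))]
        w = adj[u].pop(v)
        adj[v].pop(u)
        mid = nxt
        nxt += 1
        split = float(rng.uniform(0.2, 0.8))
        add_edge(u, mid, w * split)
        add_edge(mid, v, w * (1 - split))
        add_edge(leaf, mid, float(rng.uniform(0.1, 1.0)))

    def dists_from(src):
        out = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u].items():
                if v not in out:
                    out[v] = out[u] + w
                    stack.append(v)
        return out

    D = np.zeros((n_taxa, n_taxa))
    for i in range(n_taxa):
        d = dists_from(i)
        for j in range(n_taxa):
            D[i, j] = d[j]

    # true bipartitions: cut each internal edge
    ref = labels[0]
    parts = set()
    internal = [(u, v) for u in adj for v in adj[u]
                if u < v and u >= n_taxa and v >= n_taxa]
    for u, v in internal:
        seen = {u}
        stack = [u]
        while stack:
            x = stack.pop()
            for y in adj[x]:
                if y != v and (x, y) != (u, v) and y not in seen:
                    if not (x == u and y == v):
                        seen.add(y)
                        stack.append(y)
        side = frozenset(labels[i] for i in seen if i < n_taxa)
        if 1 < len(side) < n_taxa - 1:
            if ref in side:
                side = frozenset(labels) - side
            parts.add(side)
    return labels, D, parts


class TestNeighborJoining:
    def test_two_taxa_single_edge(self):
        tree = neighbor_joining(np.array([[0.0, 3.0], [3.0, 0.0]]),
                                labels=["A", "B"])
        lengths = sorted(bl for _, bl in tree.children)
        assert lengths == pytest.approx([0.0, 3.0])

    def test_three_taxa_closed_form(self):
        """d(AB)=5, d(AC)=7, d(BC)=8 → branches 2, 3, 5 (exact)."""
        D = np.array([[0, 5, 7], [5, 0, 8], [7, 8, 0]], dtype=float)
        tree = neighbor_joining(D, labels=["A", "B", "C"])
        by_label = {c.label: bl for c, bl in tree.children}
        assert by_label == {"A": pytest.approx(2.0), "B": pytest.approx(3.0),
                            "C": pytest.approx(5.0)}

    def test_four_taxa_recovers_generating_topology(self):
        """Additive distances from ((A,B),(C,D)) with internal edge 2."""
        # external branches: A=1, B=2, C=3, D=4; internal edge 2
        D = np.array([
            [0, 3, 6, 7],
            [3, 0, 7, 8],
            [6, 7, 0, 7],
            [7, 8, 7, 0],
        ], dtype=float)
        tree = neighbor_joining(D, labels=["A", "B", "C", "D"])
        assert bipartitions(tree) == {frozenset({"C", "D"})}

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            neighbor_joining(np.array([[0, 1], [2, 0]]), labels=["A", "B"])

    @pytest.mark.parametrize("n_taxa", [5, 6, 7, 8])
    def test_additive_recovery_property(self, n_taxa):
        """NJ is consistent: additive matrices reproduce their tree."""
        for seed in range(15):
            rng = np.random.default_rng(1000 * n_taxa + seed)
            labels, D, truth = random_additive_tree(n_taxa, rng)
            tree = neighbor_joining(D, labels=labels)
            assert bipartitions(tree) == truth

    def test_agrees_with_independent_implementation(self):
        """Cross-check topology against scikit-bio's NJ on a random matrix."""
        skbio = pytest.importorskip("skbio")
        import dendropy
        from dendropy.calculate import treecompare

        rng = np.random.default_rng(17)
        labels, D, _ = random_additive_tree(7, rng)
        # perturb slightly so the matrix is non-trivially non-additive
        noise = rng.uniform(0, 0.02, D.shape)
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0.0)
        Dn = D + noise
        Dn = (Dn + Dn.T) / 2.0          # exact float symmetry
        mine = neighbor_joining(Dn, labels=labels).newick()
        theirs = str(
            skbio.tree.nj(skbio.DistanceMatrix(Dn, ids=labels))
        )
        tns = dendropy.TaxonNamespace()
        t1 = dendropy.Tree.get(data=mine, schema="newick",
                               taxon_namespace=tns)
        t2 = dendropy.Tree.get(data=theirs, schema="newick",
                               taxon_namespace=tns)
        t1.encode_bipartitions()
        t2.encode_bipartitions()
        assert treecompare.symmetric_difference(t1, t2) == 0


class TestBootstrap:
    @staticmethod
    def _two_clade_alignment():
        rng = np.random.default_rng(5)
        core = "".join(rng.choice(list("ACGT"), 60))
        flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
        other = "".join(flip[b] for b in core[:25]) + core[25:]
        aln = {}
        for i, name in enumerate(["a1", "a2", "a3"]):
            s = list(core)
            s[40 + i] = flip[s[40 + i]]        # private mutation
            aln[name] = "".join(s)
        for i, name in enumerate(["b1", "b2", "b3"]):
            s = list(other)
            s[50 + i] = flip[s[50 + i]]
            aln[name] = "".join(s)
        return aln

    def test_clean_clades_get_full_support(self):
        aln = self._two_clade_alignment()
        supports = bootstrap_support(aln, n_reps=100, seed=0)
        clade_b = frozenset({"b1", "b2", "b3"})
        assert supports[clade_b] == pytest.approx(100.0)
        assert all(0.0 <= v <= 100.0 for v in supports.values())

    def test_same_seed_reproducible(self):
        aln = self._two_clade_alignment()
        assert bootstrap_support(aln, 50, seed=3) == \
            bootstrap_support(aln, 50, seed=3)

    def test_invariant_alignment_rejected(self):
        aln = {k: "AAAA" for k in ["a", "b", "c", "d"]}
        with pytest.raises(ValueError, match="variable"):
            bootstrap_support(aln)


class TestRecoveryFromSimulatedFragments:
    def test_single_individual_consensus_accuracy(self):
        """≥10× deaminated coverage: ≤0.5% called-base error, and coverage
        grows monotonically with fragment count."""
        genome = GENOME
        g_arr = np.array(list(genome))
        covered_prev = 0.0
        for n_frags in (400, 900, 1600):
            lib = simulate_deaminated_library(genome, n_frags, seed=n_frags)
            deam = filter_deaminated(lib)
            pile = build_pileup(deam, "ref", len(genome))
            cons = call_consensus(pile)
            called = cons.calls != "N"
            if called.any():
                err = float(np.mean(cons.calls[called] != g_arr[called]))
                assert err <= 0.005
            assert cons.covered_fraction >= covered_prev
            covered_prev = cons.covered_fraction
        assert covered_prev > 0.5

    def test_two_individual_mixture_flags_divergent_site(self):
        """50:50 mixture of genomes differing at one site is flagged there."""
        pos = 1000
        g1 = GENOME
        g2 = GENOME[:pos] + ("A" if GENOME[pos] != "A" else "G") + GENOME[pos + 1:]
        lib = (
            simulate_deaminated_library(g1, 900, seed=1, error=0.0)
            + simulate_deaminated_library(g2, 900, seed=2, error=0.0)
        )
        deam = filter_deaminated(lib)
        pile = build_pileup(deam, "ref", len(g1))
        assert pile.coverage[pos] >= 10
        flagged = {f.position for f in internal_consistency(pile)}
        assert pos in flagged


class TestLineageAssignment:
    PANEL = DiagnosticPanel(sites=[
        DiagnosticSite(10, (("modern", "A"), ("neanderthal", "C"))),
        DiagnosticSite(30, (("modern", "T"), ("neanderthal", "C"))),  # C/T: confounded
        DiagnosticSite(50, (("modern", "G"), ("neanderthal", "T"))),
    ])

    @staticmethod
    def _frag_with_base(position: int, base: str, fid: str):
        ref = "A" * 21
        read = "A" * 10 + base + "A" * 10
        return make_fragment(ref, read, fid, start=position - 10)

    def test_unanimous_votes_call_lineage(self):
        frags = [self._frag_with_base(10, "C", f"f{i}") for i in range(10)]
        call = assign_lineage(frags, self.PANEL, 2000)
        assert call.call == "neanderthal"
        assert call.votes["neanderthal"] == 10

    def test_even_split_is_mixed(self):
        frags = [self._frag_with_base(10, "C", f"n{i}") for i in range(5)]
        frags += [self._frag_with_base(10, "A", f"m{i}") for i in range(5)]
        call = assign_lineage(frags, self.PANEL, 2000)
        assert call.call == "mixed"
        assert call.votes == {"modern": 5, "neanderthal": 5}

    def test_damage_confounded_site_excluded(self):
        frags = [self._frag_with_base(30, "T", f"f{i}") for i in range(8)]
        call = assign_lineage(frags, self.PANEL, 2000)
        assert call.call == "undetermined"
        assert call.n_sites_excluded == 1
        incl = assign_lineage(frags, self.PANEL, 2000,
                              exclude_damage_confounded=False)
        assert incl.call == "modern"

    def test_fragment_missing_all_sites_votes_nothing(self):
        frags = [self._frag_with_base(500, "G", "f0")]
        call = assign_lineage(frags, self.PANEL, 2000)
        assert call.call == "undetermined"
        assert call.n_informative == 0
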