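import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import hypergeom

from penguin import clustering as cl
from penguin.intervals import GenomicInterval


class FakeEpin:
    def __init__(self, gene_id, pairs):
        self.gene_id = gene_id
        self.edges = {tuple(sorted(p)): frozenset({"direct"}) for p in pairs}


def _dist_oracle(epins, universe_size, metric):
    n = len(epins)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            A, B = set(epins[i].edges), set(epins[j].edges)
            if metric == "shared_over_universe":
                D[i, j] = 1 - len(A & B) / universe_size
            else:
                D[i, j] = 1 - (len(A & B) / len(A | B) if A | B else 1.0)
    return D


class TestUniverseAndDistance:
    def test_union_semantics(self):
        epins = [FakeEpin("a", [("A", "B")]), FakeEpin("b", [("A", "B"), ("B", "C")])]
        assert len(cl.build_universe(epins)) == 2
        disjoint = [
            FakeEpin("a", [("A", "B"), ("C", "D"), ("E", "F")]),
            FakeEpin("b", [("G", "H"), ("I", "J"), ("K", "L"), ("M", "N")]),
        ]
        assert len(cl.build_universe(disjoint)) == 7

    def test_identical_and_disjoint_pairs(self):
        pairs5 = [(f"A{i}", f"B{i}") for i in range(5)]
        other5 = [(f"C{i}", f"D{i}") for i in range(5)]
        epins = [FakeEpin("a", pairs5), FakeEpin("b", pairs5), FakeEpin("c", other5)]
        u = cl.build_universe(epins)
        assert len(u) == 10
        D = cl.epin_distance_matrix(epins, u)
        assert D[0, 1] == pytest.approx(0.5)  # identical: 1 - 5/10
        assert D[0, 2] == pytest.approx(1.0)  # disjoint
        assert D[0, 0] == 0.0
        J = cl.epin_distance_matrix(epins, u, metric="jaccard")
        assert J[0, 1] == 0.0 and J[0, 2] == 1.0

    def test_matches_brute_force_sets(self):
        rng = np.random.default_rng(0)
        prots = [f"P{i}" for i in range(12)]
        epins = []
        for k in range(6):
            n = int(rng.integers(2, 8))
            pairs = set()
            while len(pairs) < n:
                i, j = rng.choice(12, 2, replace=False)
                pairs.add(tuple(sorted((prots[i], prots[j]))))
            epins.append(FakeEpin(f"g{k}", pairs))
        u = cl.build_universe(epins)
        for metric in ("shared_over_universe", "jaccard"):
            D = cl.epin_distance_matrix(epins, u, metric=metric)
            assert np.allclose(D, _dist_oracle(epins, len(u), metric))

    @given(st.integers(0, 2 ** 18 - 1), st.integers(0, 2 ** 18 - 1), st.integers(0, 2 ** 18 - 1))
    def test_jaccard_triangle_inequality(self, x, y, z):
        def to_pairs(mask):
            return [(f"A{i}", f"B{i}") for i in range(18) if mask >> i & 1]

        epins = [FakeEpin("x", to_pairs(x | 1)), FakeEpin("y", to_pairs(y | 1)),
                 FakeEpin("z", to_pairs(z | 1))]
        u = cl.build_universe(epins)
        D = cl.epin_distance_matrix(epins, u, metric="jaccard")
        assert D[0, 1] <= D[0, 2] + D[2, 1] + 1e-12
        assert np.allclose(D, D.T)


class TestWardCut:
    def _epins_two_groups(self):
        core1 = [(f"A{i}", f"B{i}") for i in range(6)]
        core2 = [(f"C{i}", f"D{i}") for i in range(6)]
        epins = []
        for k in range(4):
            extra = [(f"A{k}x", f"B{k}y")]
            epins.append(FakeEpin(f"g1_{k}", core1 + extra))
        for k in range(4):
            extra = [(f"C{k}x", f"D{k}y")]
            epins.append(FakeEpin(f"g2_{k}", core2 + extra))
        return epins

    def test_identical_epins_merge_first(self):
        pairs = [("A", "B"), ("C", "D")]
        epins = [FakeEpin("dup1", pairs), FakeEpin("dup2", pairs),
                 FakeEpin("other", [("E", "F"), ("G", "H"), ("I", "J")])]
        u = cl.build_universe(epins)
        D = cl.epin_distance_matrix(epins, u, metric="jaccard")
        tree = cl.ward_tree(D, [e.gene_id for e in epins])
        first = tree.merge_list[0]
        merged = {tree.leaves[int(first[0])], tree.leaves[int(first[1])]}
        assert merged == {"dup1", "dup2"}
        assert first[2] == pytest.approx(0.0, abs=1e-12)

    def test_two_tight_pairs_recovered_at_k2(self):
        epins = self._epins_two_groups()
        u = cl.build_universe(epins)
        D = cl.epin_distance_matrix(epins, u)
        tree = cl.ward_tree(D, [e.gene_id for e in epins])
        got = cl.cut_tree(tree, 2)
        groups = {}
        for g, c in got.items():
            groups.setdefault(c, set()).add(g)
        assert sorted(map(len, groups.values())) == [4, 4]
        assert any(all(g.startswith("g1") for g in grp) for grp in groups.values())

    def test_cut_is_hierarchically_consistent(self):
        epins = self._epins_two_groups()
        u = cl.build_universe(epins)
        tree = cl.ward_tree(cl.epin_distance_matrix(epins, u), [e.gene_id for e in epins])
        for k in range(3, 8):
            fine = cl.cut_tree(tree, k)
            coarse = cl.cut_tree(tree, k - 1)
            # every fine cluster maps into exactly one coarse cluster
            mapping = {}
            for g in fine:
                mapping.setdefault(fine[g], set()).add(coarse[g])
            assert all(len(v) == 1 for v in mapping.values())

    def test_k_out_of_range_rejected(self):
        epins = self._epins_two_groups()
        u = cl.build_universe(epins)
        tree = cl.ward_tree(cl.epin_distance_matrix(epins, u), [e.gene_id for e in epins])
        with pytest.raises(ValueError):
            cl.cut_tree(tree, 1)
        with pytest.raises(ValueError):
            cl.cut_tree(tree, 9)


class TestFisher:
    @pytest.mark.parametrize(
        "table,odds_2dp",
        [
            ((11, 262, 26, 4015), 6.48),
            ((5, 5, 5, 5), 1.0),
            ((1, 640, 36, 3637), 0.16),
        ],
    )
    def test_sample_odds_ratio(self, table, odds_2dp):
        odds, _ = cl.fisher_2x2(*table)
        assert round(odds, 2) == odds_2dp

    def test_reference_p_values(self):
        _, p_low = cl.fisher_2x2(11, 262, 26, 4015)
        assert p_low == pytest.approx(1.04e-5, rel=0.05)
        _, p_bal = cl.fisher_2x2(5, 5, 5, 5)
        assert p_bal == 1.0
        _, p_dep = cl.fisher_2x2(1, 640, 36, 3637)
        assert p_dep == pytest.approx(0.03, abs=0.01)

    def test_degenerate_odds_conventions(self):
        assert cl.fisher_2x2(3, 0, 0, 7)[0] == math.inf
        assert cl.fisher_2x2(0, 3, 7, 0)[0] == 0.0
        with pytest.raises(ValueError):
            cl.fisher_2x2(-1, 0, 0, 1)

    @given(
        a=st.integers(0, 12), b=st.integers(0, 12),
        c=st.integers(0, 12), d=st.integers(0, 12),
    )
    def test_matches_hypergeometric_enumeration(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        _, p = cl.fisher_2x2(a, b, c, d)
        N, K, n = a + b + c + d, a + b, a + c
        kmin, kmax = max(0, n - (N - K)), min(K, n)
        pmf_obs = hypergeom.pmf(a, N, n, K)
        total = sum(
            hypergeom.pmf(k, N, n, K)
            for k in range(kmin, kmax + 1)
            if hypergeom.pmf(k, N, n, K) <= pmf_obs * (1 + 1e-9)
        )
        assert p == pytest.approx(min(total, 1.0), rel=1e-7, abs=1e-12)


class TestBranchEnrichment:
    @staticmethod
    def _tree(n=8, seed=0):
        rng = np.random.default_rng(seed)
        D = rng.random((n, n))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        return cl.ward_tree(D, [f"g{i}" for i in range(n)])

    def test_perfectly_separating_branch(self):
        epins = [FakeEpin(f"p{k}", [(f"A{k}", f"B{k}"), ("A", "B")]) for k in range(3)]
        epins += [FakeEpin(f"n{k}", [(f"C{k}", f"D{k}"), ("C", "D")]) for k in range(3)]
        u = cl.build_universe(epins)
        tree = cl.ward_tree(cl.epin_distance_matrix(epins, u), [e.gene_id for e in epins])
        labels = {e.gene_id: e.gene_id.startswith("p") for e in epins}
        recs = cl.branch_enrichment(tree, labels)
        perfect = [r for r in recs if r.table == (3, 0, 0, 3)]
        assert perfect and all(r.odds_ratio == math.inf for r in perfect)

    def test_hand_built_tables(self):
        tree = self._tree()
        labels = {f"g{i}": i < 4 for i in range(8)}
        recs = cl.branch_enrichment(tree, labels)
        assert len(recs) == 7
        sets = []
        n = 8
        nodes = [frozenset([l]) for l in tree.leaves]
        for left, right, _h, _s in tree.merge_list:
            nodes.append(nodes[int(left)] | nodes[int(right)])
        for rec, under in zip(recs, nodes[n:]):
            a = sum(labels[l] for l in under)
            assert rec.table == (a, len(under) - a, 4 - a, 8 - len(under) - (4 - a))
            odds, p = cl.fisher_2x2(*rec.table)
            assert rec.p_value == p

    def test_null_calibration_at_root_children(self):
        rng = np.random.default_rng(1)
        tree = self._tree(n=40, seed=3)
        base = [True] * 10 + [False] * 30
        hits = 0
        n_perm = 400
        for _ in range(n_perm):
            perm = rng.permutation(base)
            labels = dict(zip(tree.leaves, perm.tolist()))
            recs = cl.branch_enrichment(tree, labels)
            if recs[-1 - 1].p_value < 0.05:  # a large fixed branch near the root
                hits += 1
        # Fisher's exact test is conservative: never anti-conservative
        assert hits / n_perm <= 0.05 + 2 * math.sqrt(0.05 * 0.95 / n_perm)

    def test_missing_labels_rejected(self):
        tree = self._tree()
        with pytest.raises(ValueError):
            cl.branch_enrichment(tree, {"g0": True})


class TestAnnotations:
    @staticmethod
    def _contacts():
        from penguin.contacts import EPContact

        out = []
        for gid, tss, center in [("G1", 100_000, 200_000), ("G2", 500_000, 700_000)]:
            bins = [GenomicInterval("chr1", center - 7000 + i * 1000, center - 6000 + i * 1000)
                    for i in range(15)]
            c = EPContact(
                gene_id=gid,
                promoter_region=GenomicInterval("chr1", tss, tss + 1000),
                promoter_loci=[GenomicInterval("chr1", tss - 1000 + k * 1000, tss + k * 1000)
                               for k in range(3)],
                enhancer_region=GenomicInterval("chr1", center - 7000, center + 8000),
                enhancer_bins=bins,
            )
            c.prioritized = bins[6:9]
            out.append(c)
        return out

    def test_ctcf_requires_both_sides(self):
        contacts = self._contacts()
        near_prom_and_enh = [
            GenomicInterval("chr1", 91_500, 91_800),   # 9 kb upstream of G1 promoter
            GenomicInterval("chr1", 198_000, 198_300),  # inside G1 enhancer region
        ]
        labels = cl.annotate_ctcf(contacts, near_prom_and_enh)
        assert labels == {"G1": True, "G2": False}
        only_prom = [GenomicInterval("chr1", 99_000, 99_300)]
        assert cl.annotate_ctcf(contacts, only_prom)["G1"] is False

    def test_snp_scope_semantics(self):
        from penguin.io import SNPRecord

        contacts = self._contacts()
        in_pri_bin = SNPRecord("rs1", GenomicInterval("chr1", 199_500, 199_501), 1e-9)
        in_promoter = SNPRecord("rs2", GenomicInterval("chr1", 500_100, 500_101), 1e-9)
        labels_e = cl.annotate_snps(contacts, [in_pri_bin, in_promoter], scope="enhancers_only")
        assert labels_e == {"G1": True, "G2": False}
        labels_any = cl.annotate_snps(contacts, [in_pri_bin, in_promoter], scope="either")
        assert labels_any == {"G1": True, "G2": True}
        labels_both = cl.annotate_snps(contacts, [in_pri_bin, in_promoter], scope="both")
        assert labels_both == {"G1": False, "G2": False}

    def test_annotations_match_brute_force_window_oracle(self):
        rng = np.random.default_rng(4)
        contacts = self._contacts()
        snps = [
            __import__("penguin.io", fromlist=["SNPRecord"]).SNPRecord(
                f"rs{i}", GenomicInterval("chr1", int(p), int(p) + 1), 1e-4)
            for i, p in enumerate(rng.integers(80_000, 800_000, size=25))
        ]
        for scope in ("enhancers_only", "promoters_only", "either", "both"):
            got = cl.annotate_snps(contacts, snps, gap=10_000, scope=scope)
            for c in contacts:
                e_hit = any(
                    s.position.overlaps(b.expand(10_000))
                    for s in snps for b in c.prioritized
                )
                p_hit = any(
                    s.position.overlaps(c.promoter_region.expand(10_000)) for s in snps
                )
                want = {"enhancers_only": e_hit, "promoters_only": p_hit,
                        "either": e_hit or p_hit, "both": e_hit and p_hit}[scope]
                assert got[c.gene_id] == want

    def test_gene_list_strict_matching(self):
        labels = cl.annotate_gene_list(["MYC", "Myc", "FOXA1"], ["MYC", "GATA2"])
        assert labels == {"MYC": True, "Myc": False, "FOXA1": False}


class TestHotspotsAndNMI:
    def test_gap_merge_semantics(self):
        ivs = [
            GenomicInterval("chr1", 0, 1000),
            GenomicInterval("chr1", 6000, 7000),    # 5 kb gap: merged
            GenomicInterval("chr1", 37_000, 38_000),  # 30 kb gap: new hotspot
        ]
        hs = cl.merge_hotspots(ivs, gap=15_000)
        assert len(hs) == 2
        assert hs[0].span == GenomicInterval("chr1", 0, 7000)
        exact = [GenomicInterval("chr1", 0, 1000), GenomicInterval("chr1", 16_000, 17_000)]
        assert len(cl.merge_hotspots(exact, gap=15_000)) == 2  # strict <

    def test_matches_sorted_sweep_oracle(self):
        rng = np.random.default_rng(6)
        ivs = sorted(
            GenomicInterval("chr1", int(s), int(s) + 500)
            for s in rng.integers(0, 300_000, size=40)
        )
        hs = cl.merge_hotspots(ivs, gap=15_000)
        # oracle: sweep
        groups, cur = [], [ivs[0]]
        end = ivs[0].end
        for iv in ivs[1:]:
            if iv.start - end < 15_000:
                cur.append(iv)
                end = max(end, iv.end)
            else:
                groups.append(cur)
                cur, end = [iv], iv.end
        groups.append(cur)
        assert [len(h.member_intervals) for h in hs] == [len(g) for g in groups]
        assert sum(len(h.member_intervals) for h in hs) == 40

    def test_nmi_identity_and_permutation_invariance(self):
        a = {i: i % 3 for i in range(12)}
        relabeled = {i: (v + 1) % 3 for i, v in a.items()}
        assert cl.nmi(a, a) == pytest.approx(1.0)
        assert cl.nmi(a, relabeled) == pytest.approx(1.0)

    def test_nmi_matches_entropy_formula(self):
        a = {i: v for i, v in enumerate([0, 0, 0, 1, 1, 1, 1, 2, 2, 2, 2, 2])}
        b = {i: v for i, v in enumerate([0, 0, 1, 1, 1, 0, 2, 2, 2, 2, 1, 2])}
        n = 12
        from collections import Counter

        def H(labels):
            return -sum(c / n * math.log(c / n) for c in Counter(labels.values()).values())

        joint = Counter((a[i], b[i]) for i in range(12))
        ca, cb = Counter(a.values()), Counter(b.values())
        I = sum(
            c / n * math.log((c / n) / ((ca[x] / n) * (cb[y] / n)))
            for (x, y), c in joint.items()
        )
        expected = I / ((H(a) + H(b)) / 2)
        assert cl.nmi(a, b) == pytest.approx(expected, abs=1e-12)

    def test_randomization_p_value(self):
        a = {i: i % 2 for i in range(20)}
        obs, p = cl.nmi_randomization(a, a, n_rand=200, seed=0)
        assert obs == pytest.approx(1.0)
        assert p < 0.05
        single = {i: 0 for i in range(20)}
        assert cl.nmi(single, a) == 0.0
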