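"""EPIN clustering by edge content, annotation labelling and enrichment.

EPINs are vectorized over the union of all edges (the edge universe),
pairwise distances are 1 - |shared edges| / |universe| (a Jaccard variant is
provided), and the dendrogram is built with Ward's linkage. Enrichment of
binary annotations (CTCF proximity, disease SNPs, oncogene membership) is
tested with two-sided Fisher's exact tests on every dendrogram branch and
on flat cluster cuts. Hotspot merging of enhancer intervals and the
normalized-mutual-information randomization test also live here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import fisher_exact
from sklearn.metrics import normalized_mutual_info_score

from .intervals import GenomicInterval

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EdgeUniverse:
    edges: tuple
    index: dict

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class ClusterTree:
    """Ward dendrogram: a scipy-format (n-1) x 4 merge table over leaves in
    canonical order."""

    merge_list: np.ndarray
    leaves: tuple

    def n_leaves(self) -> int:
        return len(self.leaves)


@dataclass(frozen=True)
class EnrichmentRecord:
    unit: str
    annotation: str
    table: tuple                 # (a, b, c, d)
    odds_ratio: float
    p_value: float
    direction: str               # enriched | depleted | neutral
    p_bonferroni: float = 1.0


@dataclass(frozen=True)
class Hotspot:
    member_intervals: tuple
    span: GenomicInterval
    gap_used: int


# ---------------------------------------------------------------------------
# vectorization and clustering
# ---------------------------------------------------------------------------

def build_universe(epins) -> EdgeUniverse:
    if len(epins) < 2:
        raise ValueError("need at least two EPINs")
    edges = sorted({pair for e in epins for pair in e.edges})
    return EdgeUniverse(edges=tuple(edges), index={p: i for i, p in enumerate(edges)})


def epin_distance_matrix(epins, universe: EdgeUniverse, metric: str = "shared_over_universe") -> np.ndarray:
    """Pairwise EPIN distance over the edge universe.

    Default: d(A,B) = 1 - |E_A & E_B| / |U| with the diagonal forced to 0
    (the raw formula would give 1 - |E_A|/|U| on the diagonal).
    ``metric='jaccard'`` gives the true pseudo-metric 1 - |&|/|or|.
    """
    if len(universe) == 0:
        raise ValueError("empty edge universe")
    n = len(epins)
    M = np.zeros((n, len(universe)), dtype=bool)
    for i, e in enumerate(epins):
        for pair in e.edges:
            M[i, universe.index[pair]] = True
    inter = (M.astype(np.int32) @ M.astype(np.int32).T).astype(float)
    if metric == "shared_over_universe":
        D = 1.0 - inter / len(universe)
    elif metric == "jaccard":
        sizes = M.sum(axis=1).astype(float)
        union = sizes[:, None] + sizes[None, :] - inter
        with np.errstate(invalid="ignore", divide="ignore"):
            D = 1.0 - np.where(union > 0, inter / np.maximum(union, 1e-300), 1.0)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    np.fill_diagonal(D, 0.0)
    return D


def ward_tree(distances: np.ndarray, leaves) -> ClusterTree:
    leaves = tuple(leaves)
    if distances.shape != (len(leaves), len(leaves)):
        raise ValueError("distance matrix / leaf mismatch")
    Z = hierarchy.linkage(squareform(distances, checks=False), method="ward")
    return ClusterTree(merge_list=Z, leaves=leaves)


def cut_tree(tree: ClusterTree, k: int) -> dict:
    """Cut into exactly k groups; cluster ids (1..k) are assigned by
    decreasing size, ties broken by lexicographically smallest leaf."""
    n = tree.n_leaves()
    if not (2 <= k <= n):
        raise ValueError(f"k must lie in [2, {n}]")
    raw = hierarchy.fcluster(tree.merge_list, t=k, criterion="maxclust")
    groups: dict = {}
    for leaf, lab in zip(tree.leaves, raw):
        groups.setdefault(lab, []).append(leaf)
    order = sorted(groups.values(), key=lambda g: (-len(g), min(g)))
    out = {}
    for cid, members in enumerate(order, start=1):
        for leaf in members:
            out[leaf] = cid
    return out


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def _near(iv: GenomicInterval, peaks, gap: int) -> bool:
    e = iv.expand(gap)
    return any(e.overlaps(p) for p in peaks)


def annotate_ctcf(contacts, peaks, gap: int = 10_000) -> dict:
    """Label each promoter true when a peak lies within ``gap`` of its
    promoter region AND within ``gap`` of at least one of its enhancer
    regions."""
    by_chrom: dict = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    by_gene: dict = {}
    for c in contacts:
        by_gene.setdefault(c.gene_id, []).append(c)
    labels = {}
    for gid, cs in by_gene.items():
        chrom_peaks = by_chrom.get(cs[0].promoter_region.chrom, [])
        prom_ok = _near(cs[0].promoter_region, chrom_peaks, gap)
        enh_ok = any(_near(c.enhancer_region, chrom_peaks, gap) for c in cs)
        labels[gid] = bool(prom_ok and enh_ok)
    return labels


def annotate_snps(contacts, snps, gap: int = 10_000, scope: str = "enhancers_only") -> dict:
    """Label promoters by SNP proximity.

    Scope semantics: a SNP within ``gap`` of a *prioritized* enhancer bin
    (enhancers_only), of the promoter region (promoters_only), of either,
    or of both."""
    if scope not in ("enhancers_only", "promoters_only", "either", "both"):
        raise ValueError(f"unknown scope {scope!r}")
    by_chrom: dict = {}
    for s in snps:
        by_chrom.setdefault(s.position.chrom, []).append(s.position)
    by_gene: dict = {}
    for c in contacts:
        by_gene.setdefault(c.gene_id, []).append(c)
    labels = {}
    for gid, cs in by_gene.items():
        pos = by_chrom.get(cs[0].promoter_region.chrom, [])
        enh_hit = any(
            _near(b, pos, gap) for c in cs for b in c.prioritized
        )
        prom_hit = _near(cs[0].promoter_region, pos, gap)
        labels[gid] = {
            "enhancers_only": enh_hit,
            "promoters_only": prom_hit,
            "either": enh_hit or prom_hit,
            "both": enh_hit and prom_hit,
        }[scope]
    return labels


def annotate_gene_list(gene_ids, gene_list) -> dict:
    members = set(gene_list)
    lowered = {g.lower() for g in members}
    labels = {}
    for gid in gene_ids:
        labels[gid] = gid in members
        if not labels[gid] and gid.lower() in lowered:
            log.warning("gene %s matches the list only case-insensitively; not counted", gid)
    return labels


# ---------------------------------------------------------------------------
# Fisher tests
# ---------------------------------------------------------------------------

def fisher_2x2(a: int, b: int, c: int, d: int) -> tuple:
    """Two-sided Fisher's exact test with the unconditional sample odds
    ratio ad/bc (0 when ad = 0 with bc > 0; +inf when bc = 0 with ad > 0;
    1 for the empty 0/0 case)."""
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("table entries must be non-negative integers")
    if a + b + c + d < 1:
        raise ValueError("empty table")
    ad, bc = a * d, b * c
    if bc == 0:
        odds = math.inf if ad > 0 else 1.0
    else:
        odds = ad / bc
    _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return odds, float(p)


def _leaf_sets(tree: ClusterTree):
    """Leaf set under each internal merge node, in merge order."""
    n = tree.n_leaves()
    sets = [frozenset([leaf]) for leaf in tree.leaves]
    internal = []
    for left, right, _h, _s in tree.merge_list:
        s = sets[int(left)] | sets[int(right)]
        sets.append(s)
        internal.append(s)
    return internal


def branch_enrichment(tree: ClusterTree, labels: dict, annotation: str = "label", alpha: float = 0.001):
    """Fisher test per internal branch: positives under the branch against
    positives in the rest of the tree."""
    missing = [l for l in tree.leaves if l not in labels]
    if missing:
        raise ValueError(f"labels missing for {len(missing)} leaves")
    total_pos = sum(bool(labels[l]) for l in tree.leaves)
    total = tree.n_leaves()
    records = []
    branches = _leaf_sets(tree)
    for i, under in enumerate(branches):
        a = sum(bool(labels[l]) for l in under)
        b = len(under) - a
        c = total_pos - a
        d = total - len(under) - c
        odds, p = fisher_2x2(a, b, c, d)
        if p < alpha and odds > 1:
            direction = "enriched"
        elif p < alpha and odds < 1:
            direction = "depleted"
        else:
            direction = "neutral"
        records.append(
            EnrichmentRecord(
                unit=f"branch_{i}", annotation=annotation, table=(a, b, c, d),
                odds_ratio=odds, p_value=p, direction=direction,
                p_bonferroni=min(1.0, p * len(branches)),
            )
        )
    return records


def cluster_enrichment(assignment: dict, labels: dict, annotation: str = "label", alpha: float = 0.001):
    """Fisher test per flat cluster: positives inside vs outside."""
    genes = sorted(assignment)
    total_pos = sum(bool(labels[g]) for g in genes)
    clusters = sorted(set(assignment.values()))
    records = []
    for cid in clusters:
        inside = [g for g in genes if assignment[g] == cid]
        a = sum(bool(labels[g]) for g in inside)
        b = len(inside) - a
        c = total_pos - a
        d = len(genes) - len(inside) - c
        odds, p = fisher_2x2(a, b, c, d)
        direction = (
            "enriched" if (p < alpha and odds > 1)
            else "depleted" if (p < alpha and odds < 1)
            else "neutral"
        )
        records.append(
            EnrichmentRecord(
                unit=f"cluster_{cid}", annotation=annotation, table=(a, b, c, d),
                odds_ratio=odds, p_value=p, direction=direction,
                p_bonferroni=min(1.0, p * len(clusters)),
            )
        )
    return records


# ---------------------------------------------------------------------------
# hotspots and NMI
# ---------------------------------------------------------------------------

def merge_hotspots(intervals, gap: int = 15_000):
    """Single-linkage chain merge per chromosome: consecutive intervals are
    merged while separated by strictly less than ``gap`` bp."""
    by_chrom: dict = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    hotspots = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda i: (i.start, i.end))
        chain = [ivs[0]]
        end = ivs[0].end
        for iv in ivs[1:]:
            if iv.start - end < gap:
                chain.append(iv)
                end = max(end, iv.end)
            else:
                hotspots.append(_close_hotspot(chain, gap))
                chain, end = [iv], iv.end
        hotspots.append(_close_hotspot(chain, gap))
    return hotspots


def _close_hotspot(chain, gap) -> Hotspot:
    return Hotspot(
        member_intervals=tuple(chain),
        span=GenomicInterval(chain[0].chrom, chain[0].start, max(iv.end for iv in chain)),
        gap_used=gap,
    )


def promoters_per_hotspot(hotspots, contacts, cluster_genes=None) -> float:
    """Mean number of distinct promoters contacted per hotspot, optionally
    restricted to the promoters of one cluster. Contacts are attributed via
    their prioritized bins (full enhancer region when none)."""
    counts = []
    for h in hotspots:
        genes = set()
        for c in contacts:
            if cluster_genes is not None and c.gene_id not in cluster_genes:
                continue
            regions = c.prioritized or [c.enhancer_region]
            if any(h.span.overlaps(r) for r in regions):
                genes.add(c.gene_id)
        counts.append(len(genes))
    return float(np.mean(counts)) if counts else float("nan")


def nmi(partition_a, partition_b) -> float:
    """Normalized mutual information (arithmetic normalization) between two
    partitions over the same element set; a single-class partition gives 0."""
    keys = sorted(partition_a)
    if sorted(partition_b) != keys:
        raise ValueError("partitions must cover the same elements")
    la = [partition_a[k] for k in keys]
    lb = [partition_b[k] for k in keys]
    if len(set(la)) < 2 or len(set(lb)) < 2:
        log.warning("single-class partition; NMI defined as 0")
        return 0.0
    return float(normalized_mutual_info_score(la, lb, average_method="arithmetic"))


def nmi_randomization(partition_a, partition_b, n_rand: int = 10_000, seed: int = 0) -> tuple:
    """Observed NMI plus an empirical p-value from shuffling partition_a's
    labels: p = (1 + #{NMI_rand >= NMI_obs}) / (n_rand + 1)."""
    observed = nmi(partition_a, partition_b)
    keys = sorted(partition_a)
    la = np.array([partition_a[k] for k in keys])
    lb = [partition_b[k] for k in keys]
    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(n_rand):
        perm = rng.permutation(la)
        if len(set(perm.tolist())) < 2:
            val = 0.0
        else:
            val = normalized_mutual_info_score(perm, lb, average_method="arithmetic")
        if val >= observed:
            ge += 1
    return observed, (1 + ge) / (n_rand + 1)
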