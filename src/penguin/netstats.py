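"""Node centralities, cluster-specificity ratios and permutation tests.

For a protein P and a cluster C of EPINs, the specificity S(P, C) is the
ratio of P's mean centrality over the EPINs in C to its mean centrality
over the EPINs outside C, with absence counted as centrality 0 in both
means. Significance is assessed by drawing same-size random EPIN subsets
(without replacement within each draw) and counting how often the random
specificity reaches the observed one; the empirical p-value carries the
standard +1 correction and is therefore never exactly zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import networkx as nx
import numpy as np

from .clustering import fisher_2x2

MEASURES = ("degree", "betweenness")


@dataclass
class CentralityTable:
    """Dense (protein x EPIN) centrality matrices plus the cluster index."""

    proteins: tuple
    gene_ids: tuple
    degree: np.ndarray        # ints, absent pairs are 0
    betweenness: np.ndarray
    presence: np.ndarray      # bool: protein is a node of the EPIN
    epin_index: dict          # gene_id -> cluster id

    def matrix(self, measure: str) -> np.ndarray:
        if measure not in MEASURES:
            raise ValueError(f"measure must be one of {MEASURES}")
        return self.degree if measure == "degree" else self.betweenness


@dataclass
class SpecificityResult:
    protein: str
    cluster: int
    s_degree: float
    s_betweenness: float
    p_degree: float
    p_betweenness: float
    presence_or: float
    presence_p: float
    n_in: int
    m_out: int


def centralities(epin) -> dict:
    """Per-node (betweenness, degree) for one EPIN, treated as an
    undirected, unweighted simple graph. Betweenness is the unnormalized
    shortest-path count with even splitting over equally short paths."""
    g = nx.Graph()
    g.add_edges_from(epin.edges)
    deg = dict(g.degree())
    btw = nx.betweenness_centrality(g, normalized=False)
    return {v: (float(btw[v]), int(deg[v])) for v in sorted(g.nodes())}


def build_centrality_table(epins, assignment: dict) -> CentralityTable:
    per_epin = {e.gene_id: centralities(e) for e in epins}
    proteins = tuple(sorted({p for c in per_epin.values() for p in c}))
    gene_ids = tuple(sorted(per_epin))
    pidx = {p: i for i, p in enumerate(proteins)}
    D = np.zeros((len(proteins), len(gene_ids)))
    B = np.zeros_like(D)
    P = np.zeros(D.shape, dtype=bool)
    for j, gid in enumerate(gene_ids):
        for prot, (b, d) in per_epin[gid].items():
            i = pidx[prot]
            D[i, j] = d
            B[i, j] = b
            P[i, j] = True
    return CentralityTable(
        proteins=proteins, gene_ids=gene_ids,
        degree=D, betweenness=B, presence=P,
        epin_index=dict(assignment),
    )


def _cluster_mask(table: CentralityTable, cluster) -> np.ndarray:
    mask = np.array([table.epin_index.get(g) == cluster for g in table.gene_ids])
    if not mask.any():
        raise ValueError(f"cluster {cluster!r} is empty")
    if mask.all():
        raise ValueError("cluster covers the whole collection")
    return mask


def _ratio(num: float, den: float) -> float:
    if den > 0:
        return num / den
    return math.inf if num > 0 else math.nan


def specificity(protein: str, cluster, table: CentralityTable, measure: str) -> float:
    """S = mean centrality inside the cluster / mean outside (absence = 0).

    0/0 yields NaN (undefined sentinel, excluded from testing)."""
    mask = _cluster_mask(table, cluster)
    v = table.matrix(measure)[table.proteins.index(protein)]
    return _ratio(v[mask].mean(), v[~mask].mean())


def specificity_permutation(
    protein: str,
    cluster,
    table: CentralityTable,
    measure: str,
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Empirical p for the observed specificity against same-size random
    EPIN subsets: (1 + #{S_rand >= S_obs}) / (n_perm + 1). An observed +inf
    is matched only by random +inf."""
    mask = _cluster_mask(table, cluster)
    n = int(mask.sum())
    v = table.matrix(measure)[table.proteins.index(protein)]
    s_obs = _ratio(v[mask].mean(), v[~mask].mean())
    if math.isnan(s_obs):
        return math.nan
    rng = np.random.default_rng(seed)
    total = v.sum()
    N = v.size
    ge = 0
    for _ in range(n_perm):
        idx = rng.choice(N, size=n, replace=False)
        inside = v[idx].sum()
        s_rand = _ratio(inside / n, (total - inside) / (N - n))
        if not math.isnan(s_rand) and s_rand >= s_obs:
            ge += 1
    return (1 + ge) / (n_perm + 1)


@lru_cache(maxsize=200_000)
def _fisher_cached(a, b, c, d):
    return fisher_2x2(a, b, c, d)


def cluster_presence_enrichment(features: dict, assignment: dict, alpha: float = 0.01):
    """Two-sided Fisher per (item, cluster) on presence/absence of the item
    (an edge or a node) in the cluster's EPINs versus all others."""
    from .clustering import EnrichmentRecord

    genes = sorted(assignment)
    missing = [g for g in genes if g not in features]
    if missing:
        raise ValueError(f"features missing for {len(missing)} EPIN(s)")
    clusters = sorted(set(assignment.values()))
    items = sorted({i for g in genes for i in features[g]})
    has = {
        item: np.array([item in features[g] for g in genes]) for item in items
    }
    records = []
    for cid in clusters:
        inside = np.array([assignment[g] == cid for g in genes])
        n_in = int(inside.sum())
        n_out = len(genes) - n_in
        for item in items:
            a = int((has[item] & inside).sum())
            b = n_in - a
            c = int(has[item].sum()) - a
            d = n_out - c
            odds, p = _fisher_cached(a, b, c, d)
            direction = (
                "enriched" if (p < alpha and odds > 1)
                else "depleted" if (p < alpha and odds < 1)
                else "neutral"
            )
            records.append(
                EnrichmentRecord(
                    unit=f"cluster_{cid}", annotation=str(item), table=(a, b, c, d),
                    odds_ratio=odds, p_value=p, direction=direction,
                )
            )
    return records


def specificity_analysis(
    table: CentralityTable,
    cluster,
    proteins=None,
    n_perm: int = 1000,
    seed: int = 0,
):
    """Specificity ratios, permutation p-values and presence enrichment for
    every requested protein in one cluster."""
    mask = _cluster_mask(table, cluster)
    n_in, m_out = int(mask.sum()), int((~mask).sum())
    proteins = list(proteins) if proteins is not None else list(table.proteins)
    results = []
    for offset, prot in enumerate(proteins):
        i = table.proteins.index(prot)
        pres = table.presence[i]
        a = int(pres[mask].sum())
        b = n_in - a
        c = int(pres[~mask].sum())
        d = m_out - c
        p_or, p_p = _fisher_cached(a, b, c, d)
        row = {}
        for m_i, measure in enumerate(MEASURES):
            v = table.matrix(measure)[i]
            s = _ratio(v[mask].mean(), v[~mask].mean())
            p = (
                specificity_permutation(
                    prot, cluster, table, measure,
                    n_perm=n_perm, seed=seed + 7919 * offset + m_i,
                )
                if not math.isnan(s)
                else math.nan
            )
            row[measure] = (s, p)
        results.append(
            SpecificityResult(
                protein=prot, cluster=cluster,
                s_degree=row["degree"][0], s_betweenness=row["betweenness"][0],
                p_degree=row["degree"][1], p_betweenness=row["betweenness"][1],
                presence_or=p_or, presence_p=p_p,
                n_in=n_in, m_out=m_out,
            )
        )
    return results


def significant_specific_proteins(cluster, results, alpha: float = 0.01) -> set:
    """Proteins significantly specific for BOTH centrality measures and
    over-represented in the cluster (three-way conjunction)."""
    out = set()
    for r in results:
        if r.cluster != cluster:
            continue
        if alpha >= 1.0:  # degenerate threshold: no filtering
            out.add(r.protein)
        elif (
            r.p_degree < alpha
            and r.p_betweenness < alpha
            and r.presence_p < alpha
            and r.presence_or > 1
        ):
            out.add(r.protein)
    return out
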