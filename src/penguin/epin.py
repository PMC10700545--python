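"""Assembly of per-promoter enhancer-promoter protein interaction networks.

An EPIN connects the DNA-binding proteins with motif occurrences in a
promoter region (promoter-bound nodes) to those with occurrences in the
promoter's prioritized enhancer bins (enhancer-bound nodes), either by a
direct physical interaction or through exactly one intermediate protein
that interacts with at least one bound protein on each side. Intermediates
connecting only one side are discarded; same-side bound-bound interactions
are not part of the network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

from .intervals import GenomicInterval
from .io import ExpressionRecord, MotifHit, PPIEdge

log = logging.getLogger(__name__)

# edge role tags
DIRECT = "direct"                 # promoter-bound -- enhancer-bound
P_INTERMEDIATE = "promoter-intermediate"
INTERMEDIATE_E = "intermediate-enhancer"


@dataclass
class EPIN:
    gene_id: str
    promoter_bound: frozenset
    enhancer_bound: dict                      # enhancer-bin -> frozenset of proteins
    intermediates: frozenset
    edges: dict                               # canonical pair -> frozenset of role tags
    enhancer_count: int
    flags: set = field(default_factory=set)

    @property
    def enhancer_bound_all(self) -> frozenset:
        out: set = set()
        for prots in self.enhancer_bound.values():
            out |= prots
        return frozenset(out)

    @property
    def nodes(self) -> frozenset:
        out: set = set()
        for a, b in self.edges:
            out.add(a)
            out.add(b)
        return frozenset(out)

    def validate(self) -> None:
        bound = self.promoter_bound | self.enhancer_bound_all
        if self.intermediates & bound:
            raise AssertionError("intermediate overlaps a bound set")
        adj: dict = {}
        for a, b in self.edges:
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
        for v in self.intermediates:
            nb = adj.get(v, set())
            if not (nb & self.promoter_bound) or not (nb & self.enhancer_bound_all):
                raise AssertionError(f"intermediate {v} does not bridge both sides")


def map_bound_proteins(regions, hits, mode: str = "overlap") -> dict:
    """Assign DNA-binding proteins to regions via motif occurrences.

    A protein is assigned to a region when one of its motif hits overlaps
    the region by >= 1 bp (``mode='overlap'``, default) or is fully
    contained in it (``mode='containment'``); duplicate motifs of the same
    protein count once.
    """
    if mode not in ("overlap", "containment"):
        raise ValueError(f"unknown assignment mode {mode!r}")
    by_chrom: dict = {}
    for h in hits:
        by_chrom.setdefault(h.interval.chrom, []).append(h)
    out: dict = {}
    for region in regions:
        prots = set()
        for h in by_chrom.get(region.chrom, []):
            ok = (
                h.interval.overlaps(region)
                if mode == "overlap"
                else region.contains(h.interval)
            )
            if ok:
                prots.add(h.protein_id)
        out[region] = frozenset(prots)
    return out


def filter_ppi_context(
    edges,
    expression,
    min_fpkm: float = 0.003,
    gene_map: dict | None = None,
) -> nx.Graph:
    """Keep PPI edges whose proteins' genes are expressed above ``min_fpkm``
    (strict >) in every replicate.

    ``gene_map`` maps protein name -> gene symbol (identity by default).
    Proteins with no expression record are excluded and counted in
    ``graph.graph['excluded_no_expression']``.
    """
    fpkm = {r.gene_id: r.fpkm for r in expression}
    gene_map = gene_map or {}

    def expressed(protein: str) -> bool | None:
        gene = gene_map.get(protein, protein)
        vals = fpkm.get(gene)
        if vals is None:
            return None
        return all(v > min_fpkm for v in vals)

    g = nx.Graph()
    missing = set()
    for e in edges:
        status = [expressed(e.protein_a), expressed(e.protein_b)]
        missing |= {p for p, s in zip(e.pair, status) if s is None}
        if all(status):
            g.add_edge(e.protein_a, e.protein_b)
    g.graph["excluded_no_expression"] = len(missing)
    if missing:
        log.warning("%d protein(s) without expression record excluded", len(missing))
    return g


def build_epin(gene_id, promoter_bound, enhancer_bound, ppi: nx.Graph) -> EPIN:
    """Build one EPIN.

    Edges are (i) PPI edges between a promoter-bound and an enhancer-bound
    protein (direct), and (ii) for every non-bound protein v adjacent to at
    least one bound protein on *each* side, all of v's edges to promoter-
    and enhancer-bound proteins (v becomes an intermediate). Nothing else:
    no same-side bound-bound edges, no intermediate-intermediate edges. An
    EPIN with zero edges is returned flagged.
    """
    P = frozenset(promoter_bound)
    enhancer_bound = {b: frozenset(s) for b, s in enhancer_bound.items()}
    Eall: set = set()
    for s in enhancer_bound.values():
        Eall |= s
    Eall = frozenset(Eall)
    bound = P | Eall

    edges: dict = {}

    def add_edge(u, v, role):
        pair = (u, v) if u < v else (v, u)
        edges.setdefault(pair, set()).add(role)

    for u, v in ppi.edges():
        if (u in P and v in Eall) or (v in P and u in Eall):
            add_edge(u, v, DIRECT)

    intermediates = set()
    for v in ppi.nodes():
        if v in bound:
            continue
        nbrs = set(ppi.neighbors(v))
        p_nbrs = nbrs & P
        e_nbrs = nbrs & Eall
        if p_nbrs and e_nbrs:
            intermediates.add(v)
            for p in p_nbrs:
                add_edge(v, p, P_INTERMEDIATE)
            for e in e_nbrs:
                add_edge(v, e, INTERMEDIATE_E)

    epin = EPIN(
        gene_id=gene_id,
        promoter_bound=P,
        enhancer_bound=enhancer_bound,
        intermediates=frozenset(intermediates),
        edges={pair: frozenset(r) for pair, r in sorted(edges.items())},
        enhancer_count=len(enhancer_bound),
        flags=set() if edges else {"empty"},
    )
    return epin


def epin_summary(epin: EPIN) -> dict:
    """Node/edge counts by role for one EPIN."""
    nodes = epin.nodes
    roles = {
        "promoter_bound": len(nodes & epin.promoter_bound),
        "enhancer_bound": len(nodes & epin.enhancer_bound_all),
        "both_bound": len(nodes & epin.promoter_bound & epin.enhancer_bound_all),
        "intermediate": len(nodes & epin.intermediates),
    }
    edge_roles: dict = {DIRECT: 0, P_INTERMEDIATE: 0, INTERMEDIATE_E: 0}
    for tags in epin.edges.values():
        for t in tags:
            edge_roles[t] += 1
    return {
        "gene_id": epin.gene_id,
        "n_nodes": len(nodes),
        "n_edges": len(epin.edges),
        "enhancer_count": epin.enhancer_count,
        **{f"n_{k}": v for k, v in roles.items()},
        **{f"n_edges_{k.replace('-', '_')}": v for k, v in edge_roles.items()},
    }


def write_epin_tables(epins, nodes_path, edges_path):
    """Emit the collection as a node table (protein, role flags, enhancer-bin
    provenance) and an edge table (pair, role tags)."""
    import pandas as pd
    from pathlib import Path

    node_rows, edge_rows = [], []
    for e in sorted(epins, key=lambda e: e.gene_id):
        bins_of: dict = {}
        for b, prots in e.enhancer_bound.items():
            for p in prots:
                bins_of.setdefault(p, []).append(f"{b.chrom}:{b.start}-{b.end}")
        listed = e.nodes | e.promoter_bound | e.enhancer_bound_all | e.intermediates
        for v in sorted(listed):
            node_rows.append(
                {
                    "gene_id": e.gene_id,
                    "protein": v,
                    "promoter_bound": int(v in e.promoter_bound),
                    "enhancer_bound": int(v in e.enhancer_bound_all),
                    "intermediate": int(v in e.intermediates),
                    "in_network": int(v in e.nodes),
                    "enhancer_bins": ";".join(sorted(bins_of.get(v, []))),
                }
            )
        for (a, b), roles in e.edges.items():
            edge_rows.append(
                {"gene_id": e.gene_id, "protein_a": a, "protein_b": b,
                 "roles": ";".join(sorted(roles))}
            )
        if not e.edges:
            edge_rows.append(
                {"gene_id": e.gene_id, "protein_a": "", "protein_b": "", "roles": ""}
            )
    for path, rows, cols in (
        (nodes_path, node_rows,
         ["gene_id", "protein", "promoter_bound", "enhancer_bound", "intermediate",
          "in_network", "enhancer_bins"]),
        (edges_path, edge_rows, ["gene_id", "protein_a", "protein_b", "roles"]),
    ):
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
    return nodes_path, edges_path


def read_epin_tables(nodes_path, edges_path):
    import pandas as pd

    nodes = pd.read_csv(nodes_path, sep="\t", keep_default_na=False)
    edges = pd.read_csv(edges_path, sep="\t", keep_default_na=False)
    epins = []
    for gid, grp in nodes.groupby("gene_id", sort=True):
        P = frozenset(grp.loc[grp["promoter_bound"] == 1, "protein"])
        inter = frozenset(grp.loc[grp["intermediate"] == 1, "protein"])
        ebound: dict = {}
        for _, row in grp.iterrows():
            for token in str(row["enhancer_bins"]).split(";"):
                if not token:
                    continue
                chrom, span = token.split(":")
                s, t = span.split("-")
                iv = GenomicInterval(chrom, int(s), int(t))
                ebound.setdefault(iv, set()).add(row["protein"])
        edict = {}
        eg = edges[edges["gene_id"] == gid]
        for _, row in eg.iterrows():
            if not row["protein_a"]:
                continue
            pair = tuple(sorted((row["protein_a"], row["protein_b"])))
            edict[pair] = frozenset(str(row["roles"]).split(";"))
        epins.append(
            EPIN(
                gene_id=str(gid),
                promoter_bound=P,
                enhancer_bound={b: frozenset(s) for b, s in ebound.items()},
                intermediates=inter,
                edges=dict(sorted(edict.items())),
                enhancer_count=len(ebound),
                flags=set() if edict else {"empty"},
            )
        )
    return epins


def epins_from_contacts(contacts, motif_hits, ppi, promoter_halfwidth: int = 500):
    """Assemble the full EPIN collection from prioritized contacts.

    Motif scanning uses the 1-kb promoter window TSS +/- 500 bp and the
    prioritized enhancer bins of each contact. Bound proteins are restricted
    to nodes of the expression-filtered PPI graph.
    """
    by_gene: dict = {}
    for c in contacts:
        by_gene.setdefault(c.gene_id, []).append(c)
    regions = set()
    prom_region = {}
    for gid, cs in by_gene.items():
        tss = cs[0].promoter_region.start
        pr = GenomicInterval(
            cs[0].promoter_region.chrom, max(0, tss - promoter_halfwidth), tss + promoter_halfwidth
        )
        prom_region[gid] = pr
        regions.add(pr)
        for c in cs:
            regions.update(c.prioritized)
    bound = map_bound_proteins(sorted(regions), motif_hits)
    known = set(ppi.nodes())
    epins = []
    for gid in sorted(by_gene):
        pbound = frozenset(bound[prom_region[gid]] & known)
        ebound = {}
        for c in by_gene[gid]:
            for b in c.prioritized:
                prots = bound[b] & known
                if prots:
                    ebound[b] = frozenset(prots)
        epins.append(build_epin(gid, pbound, ebound, ppi))
    return epins
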