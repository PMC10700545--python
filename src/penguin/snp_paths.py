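"""SNP path tracing through EPINs.

Two scenarios tie a disease-associated SNP to a protein path between an
enhancer and its promoter: (1) the SNP lies inside a DNA-binding motif
occurrence within a prioritized enhancer bin, implicating the bound
protein's paths to the promoter; (2) the SNP lies inside the gene body
encoding an EPIN node, implicating every enhancer->promoter path through
that node. Paths have length 2 (direct) or 3 (one intermediate) and are
oriented enhancer-bound -> promoter-bound.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

log = logging.getLogger(__name__)


@dataclass
class SNPPathRecord:
    gene_id: str
    snp: object
    scenario: int                 # 1 = SNP in enhancer motif, 2 = SNP in node gene body
    affected: str
    provenance: str               # motif id (scenario 1) or encoding gene (scenario 2)
    paths: list = field(default_factory=list)

    def path_strings(self) -> list:
        return [">".join(p) for p in self.paths]


@dataclass
class DEEnrichment:
    gene_id: str
    fraction1: float | None       # DE / covered among path intermediates
    fraction2: float | None       # DE / covered among all EPIN intermediates
    enrichment: float | None


def find_motif_snps(contacts, motif_hits, snps, p_cutoff: float | None = None):
    """Scenario-1 hits: (SNP, motif hit, promoter) triples where the SNP
    position lies inside a motif occurrence overlapping a prioritized
    enhancer bin. Containment is exact: no proximity window here."""
    if p_cutoff is not None:
        snps = [s for s in snps if s.assoc_p < p_cutoff]
    by_chrom_hits: dict = {}
    for h in motif_hits:
        by_chrom_hits.setdefault(h.interval.chrom, []).append(h)
    out = []
    for c in contacts:
        if not c.prioritized:
            continue
        chrom = c.enhancer_region.chrom
        local = [
            h for h in by_chrom_hits.get(chrom, [])
            if any(h.interval.overlaps(b) for b in c.prioritized)
        ]
        for h in local:
            for s in snps:
                if h.interval.contains(s.position):
                    out.append((c.gene_id, s, h))
    return out


def find_node_gene_snps(gene_models, snps, epin):
    """Scenario-2 hits: (SNP, node, role) where the SNP falls inside the
    gene body encoding an EPIN node. Nodes without a gene model are skipped
    and counted."""
    models = {g.gene_id: g for g in gene_models}
    roles = {}
    for v in epin.nodes:
        if v in epin.intermediates:
            roles[v] = "intermediate"
        elif v in epin.promoter_bound and v in epin.enhancer_bound_all:
            roles[v] = "both_bound"
        elif v in epin.promoter_bound:
            roles[v] = "promoter_bound"
        else:
            roles[v] = "enhancer_bound"
    out, skipped = [], 0
    for v in sorted(epin.nodes):
        gm = models.get(v)
        if gm is None:
            skipped += 1
            continue
        for s in snps:
            if gm.body.contains(s.position):
                out.append((s, v, roles[v]))
    if skipped:
        log.debug("%s: %d node(s) without gene model skipped", epin.gene_id, skipped)
    return out


def _adjacency(epin):
    adj: dict = {}
    for a, b in epin.edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    return adj


def enumerate_snp_paths(epin, affected: str, scenario: int):
    """All enhancer-bound -> promoter-bound paths of length <= 3 through
    ``affected``, ordered deterministically.

    Scenario 1: ``affected`` is the enhancer-bound protein the paths start
    from. Scenario 2: ``affected`` is any node; for an intermediate this is
    every realized E-bound -> affected -> P-bound triple, for a bound node
    every path containing it."""
    if affected not in epin.nodes:
        raise ValueError(f"{affected} is not a node of the {epin.gene_id} EPIN")
    adj = _adjacency(epin)
    P = epin.promoter_bound
    Eall = epin.enhancer_bound_all
    inter = epin.intermediates

    paths = []
    # all E->P paths of length <= 3 (middle node must be an intermediate)
    for e in sorted(Eall & set(adj)):
        for nxt in sorted(adj[e]):
            if nxt in P:
                paths.append((e, nxt))
            if nxt in inter:
                for p in sorted(adj[nxt] & P):
                    paths.append((e, nxt, p))
    if scenario == 1:
        keep = [p for p in paths if p[0] == affected]
    elif scenario == 2:
        keep = [p for p in paths if affected in p]
    else:
        raise ValueError("scenario must be 1 or 2")
    return sorted(set(keep))


def de_enrichment(epin, de_labels: dict, snp_path_nodes) -> DEEnrichment:
    """Ratio of the DE fraction among covered intermediates on SNP paths
    (Fraction1) to the DE fraction among all covered EPIN intermediates
    (Fraction2). ``de_labels`` maps gene -> 'DE' | 'not-DE'; genes absent
    from the mapping are uncovered and excluded from both fractions."""
    def frac(nodes):
        covered = [v for v in nodes if de_labels.get(v) in ("DE", "not-DE")]
        if not covered:
            return None
        de = sum(de_labels[v] == "DE" for v in covered)
        return de / len(covered)

    path_inter = set(snp_path_nodes) & epin.intermediates
    f1 = frac(path_inter)
    f2 = frac(epin.intermediates)
    enr = None
    if f1 is not None and f2 is not None and f2 > 0:
        enr = f1 / f2
    return DEEnrichment(gene_id=epin.gene_id, fraction1=f1, fraction2=f2, enrichment=enr)
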