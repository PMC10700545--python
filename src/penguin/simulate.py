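"""Synthetic input bundles with known ground truth.

The generator forward-simulates every input the pipeline consumes: a gene
and enhancer layout on a small genome, 5-kb loop calls with q-values, 1-kb
locus-pair contact counts drawn Poisson(beta_x * beta_y * E(d)) with planted
lognormal per-locus biases and a power-law distance decay, motif occurrences
realizing per-cluster protein wiring programs, an annotated PPI table, an
expression table, CTCF peaks, disease SNPs planted inside enhancer motifs
and node gene bodies, an oncogene list, DE labels and a small trans-eQTL
table. Truth tables (biases, cluster programs, planted annotation labels)
are produced alongside so every pipeline stage can be scored.

Determinism: one generator seeded once per bundle; draws happen in a fixed
staged order (gene layout, enhancer layout, decoy loops, biases, counts,
PPI wiring, expression, motifs, CTCF, SNPs, oncogenes, DE labels, eQTLs),
so a given seed yields a byte-identical bundle and partial regeneration is
impossible by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import GenomicInterval
from .io import GeneModel

BIN = 1000
ANCHOR = 5000
PAD = 5000


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic bundle.

    Scale defaults (200 promoters, 800 proteins, ~5000 PPI edges) are sized
    for a full-pipeline run in a few minutes on one CPU while keeping the
    statistical structure (distance decay, multiplicative biases, cluster
    wiring programs, annotation enrichments) testable.
    """

    seed: int = 0
    # genome shape
    n_chrom: int = 2
    chrom_size: int = 14_000_000
    # regulatory layout
    n_genes: int = 200
    mean_enhancers: float = 3.0          # enhancers per promoter, >= 1
    min_sep: int = 20_000                # bp, enhancer center to TSS
    max_sep: int = 600_000
    n_decoy_loops: int = 40
    # contact counts
    decay_exponent: float = -1.0         # b in E(d) ~ d^b
    # mean 1-kb pair count at min_sep; sized so a called loop carries a
    # di-tag total in the hundreds, as FDR < 0.01 calls do
    read_depth: float = 300.0
    bias_sigma: float = 0.3              # lognormal spread of planted beta
    noise: str = "poisson"               # "poisson" | "none"
    # proteins and wiring
    n_proteins: int = 800
    n_dbps: int = 160
    ppi_background_edges: int = 5000
    n_clusters: int = 2
    program_dbps_per_side: int = 8
    program_intermediates: int = 12
    program_motif_prob: float = 0.9
    sprinkle_motif_prob: float = 0.02
    unexpressed_fraction: float = 0.05
    failing_ppi_fraction: float = 0.10
    # annotations
    prioritize_fraction: float = 0.8     # used to predict prioritized bins
    ctcf_clusters: tuple = (1,)
    ctcf_prob_enriched: float = 0.9
    ctcf_prob_base: float = 0.2
    snp_clusters: tuple = (1,)
    snp_prob_enriched: float = 0.5
    snp_prob_base: float = 0.03
    node_snp_prob: float = 0.3
    n_background_snps: int = 60
    onco_prob_enriched: float = 0.12
    onco_prob_base: float = 0.02
    de_covered_prob: float = 0.85
    de_prob: float = 0.3

    def __post_init__(self) -> None:
        if self.decay_exponent > 0:
            raise ValueError("decay_exponent must be <= 0")
        if self.bias_sigma < 0:
            raise ValueError("bias_sigma must be >= 0")
        if self.noise not in ("poisson", "none"):
            raise ValueError("noise must be 'poisson' or 'none'")
        if self.mean_enhancers < 1:
            raise ValueError("mean_enhancers must be >= 1")


@dataclass
class SimulatedBundle:
    """In-memory view of one synthetic bundle plus its ground truth."""

    config: SimulationConfig
    gene_models: list
    enhancer_layout: list            # (gene_id, chrom, center, distance)
    loops: pd.DataFrame
    pair_counts: pd.DataFrame
    enhancer_peaks: list
    ctcf_peaks: list
    motif_hits: pd.DataFrame         # FIMO dialect
    ppi: pd.DataFrame
    expression: pd.DataFrame
    snps: pd.DataFrame
    oncogenes: list
    de_labels: pd.DataFrame
    eqtl: pd.DataFrame
    truth: dict = field(default_factory=dict)


def _expected(d, cfg: SimulationConfig) -> float:
    return cfg.read_depth * (d / cfg.min_sep) ** cfg.decay_exponent


def _predicted_prioritized(center: int, tss: int, cfg: SimulationConfig) -> list:
    """Bin indices the pipeline is expected to prioritize under noiseless
    counts: bins whose summed expectation over the promoter loci reaches
    ``prioritize_fraction`` of the best bin."""
    prom_mids = [tss - 500 + k * BIN for k in range(3)]
    scores = []
    for i in range(15):
        mid = center - 7000 + i * BIN + 500
        scores.append(sum(_expected(abs(mid - pm), cfg) for pm in prom_mids))
    top = max(scores)
    return [i for i, s in enumerate(scores) if s >= cfg.prioritize_fraction * top]


def simulate_bundle(config: SimulationConfig) -> SimulatedBundle:
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    # ---- stage 1: promoter gene layout -----------------------------------
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chrom)]
    per_chrom = int(np.ceil(cfg.n_genes / cfg.n_chrom))
    slot = max(60_000, (cfg.chrom_size - 2_000_000) // max(per_chrom, 1))
    genes = []
    gi = 0
    for chrom in chroms:
        for s in range(per_chrom):
            if gi >= cfg.n_genes:
                break
            tss = 1_000_000 + s * slot + int(rng.integers(0, 20)) * BIN
            strand = "+" if rng.random() < 0.5 else "-"
            L = int(rng.integers(5, 30)) * BIN
            if strand == "+":
                body = GenomicInterval(chrom, tss, tss + L, strand)
            else:
                body = GenomicInterval(chrom, tss - L + 1, tss + 1, strand)
            genes.append(
                GeneModel(
                    gene_id=f"G{gi:04d}",
                    tss=GenomicInterval(chrom, tss, tss + 1, strand),
                    body=body,
                )
            )
            gi += 1
    tss_by_chrom: dict = {}
    for g in genes:
        tss_by_chrom.setdefault(g.tss.chrom, []).append(g.tss.start)

    clusters = {g.gene_id: int(i % cfg.n_clusters) + 1 for i, g in enumerate(genes)}

    # ---- stage 2: enhancers and loops ------------------------------------
    def clashes(chrom, lo, hi):
        return any(lo - 9_000 < t < hi + 9_000 for t in tss_by_chrom[chrom])

    enhancer_layout = []
    loop_rows = []
    peak_rows = []
    for g in genes:
        chrom, tss = g.tss.chrom, g.tss.start
        n_e = 1 + rng.poisson(cfg.mean_enhancers - 1)
        placed = 0
        attempts = 0
        own_centers = []
        while placed < n_e and attempts < 50 * n_e:
            attempts += 1
            d = int(rng.integers(cfg.min_sep // BIN, cfg.max_sep // BIN + 1)) * BIN
            side = 1 if rng.random() < 0.5 else -1
            center = tss + side * d
            lo, hi = center - PAD - 2000, center + PAD + 3000
            if lo < 0 or hi > cfg.chrom_size or clashes(chrom, lo, hi):
                continue
            # 15-kb regions of the same promoter must not share 1-kb loci
            if any(abs(center - c0) < 16_000 for c0 in own_centers):
                continue
            own_centers.append(center)
            enhancer_layout.append((g.gene_id, chrom, center, d))
            peak_rows.append((chrom, center - 1000, center + 1000))
            loop_rows.append(
                (chrom, tss - 2000, tss + 3000, chrom, center - 2000, center + 3000,
                 0.0, float(rng.uniform(1e-6, 5e-3)))
            )
            placed += 1

    # decoy loops: promoter-promoter pairs and insignificant calls
    for _ in range(cfg.n_decoy_loops):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        tsses = tss_by_chrom[chrom]
        i, j = rng.choice(len(tsses), size=2, replace=False)
        t1, t2 = sorted((tsses[int(i)], tsses[int(j)]))
        q = float(rng.uniform(1e-4, 5e-3)) if rng.random() < 0.5 else float(rng.uniform(0.02, 0.5))
        loop_rows.append((chrom, t1 - 2000, t1 + 3000, chrom, t2 - 2000, t2 + 3000, 1.0, q))

    # ---- stage 3: planted biases -----------------------------------------
    loci = set()
    for gid, chrom, center, _d in enhancer_layout:
        for i in range(15):
            loci.add((chrom, center - 7000 + i * BIN))
        tss = next(g.tss.start for g in genes if g.gene_id == gid)
        for k in range(3):
            loci.add((chrom, tss - BIN + k * BIN))
    loci = sorted(loci)
    betas = {
        locus: float(np.exp(rng.normal(0.0, cfg.bias_sigma))) if cfg.bias_sigma > 0 else 1.0
        for locus in loci
    }

    # ---- stage 4: pair counts --------------------------------------------
    tss_of = {g.gene_id: g.tss.start for g in genes}
    pair_rows = []
    loop_totals: dict = {}
    for gid, chrom, center, _d in enhancer_layout:
        tss = tss_of[gid]
        total = 0.0
        for i in range(15):
            x = center - 7000 + i * BIN
            for k in range(3):
                y = tss - BIN + k * BIN
                dxy = abs((x + 500) - (y + 500))
                mu = betas[(chrom, x)] * betas[(chrom, y)] * _expected(max(dxy, 1), cfg)
                c = float(rng.poisson(mu)) if cfg.noise == "poisson" else float(mu)
                total += c
                pair_rows.append((chrom, x, x + BIN, chrom, y, y + BIN, c))
        loop_totals[(chrom, center)] = total
    # write loop counts as the summed pair counts of the region
    loops_df = pd.DataFrame(
        loop_rows,
        columns=["chr1", "start1", "end1", "chr2", "start2", "end2", "count", "qvalue"],
    )
    for idx, row in loops_df.iterrows():
        key = (row["chr1"], int(row["start2"]) + 2000)
        if key in loop_totals:
            loops_df.at[idx, "count"] = loop_totals[key]

    pair_df = pd.DataFrame(
        pair_rows, columns=["chr1", "start1", "end1", "chr2", "start2", "end2", "count"]
    )

    # ---- stage 5: proteins, programs, PPI --------------------------------
    dbps = [f"TF{i:03d}" for i in range(cfg.n_dbps)]
    others = [f"PR{i:04d}" for i in range(cfg.n_proteins - cfg.n_dbps)]
    side = cfg.program_dbps_per_side
    programs = {}
    for c in range(1, cfg.n_clusters + 1):
        base = (c - 1) * 2 * side
        ibase = (c - 1) * cfg.program_intermediates
        programs[c] = {
            "promoter_dbps": dbps[base:base + side],
            "enhancer_dbps": dbps[base + side:base + 2 * side],
            "intermediates": others[ibase:ibase + cfg.program_intermediates],
        }
    ppi_pairs = set()
    for c, prog in programs.items():
        for v in prog["intermediates"]:
            for p in rng.choice(prog["promoter_dbps"], size=3, replace=False):
                ppi_pairs.add(tuple(sorted((v, str(p)))))
            for e in rng.choice(prog["enhancer_dbps"], size=3, replace=False):
                ppi_pairs.add(tuple(sorted((v, str(e)))))
        for _ in range(4):
            p = str(rng.choice(prog["promoter_dbps"]))
            e = str(rng.choice(prog["enhancer_dbps"]))
            ppi_pairs.add(tuple(sorted((p, e))))
    all_prots = dbps + others
    while len(ppi_pairs) < cfg.ppi_background_edges:
        i, j = rng.choice(len(all_prots), size=2, replace=False)
        ppi_pairs.add(tuple(sorted((all_prots[int(i)], all_prots[int(j)]))))
    ppi_rows = [
        (a, b, "experimental", "Y2H;AP-MS", "prostate;prostate cancer", "nuclear;nucleoplasm")
        for a, b in sorted(ppi_pairs)
    ]
    # rows that must fail the context filters
    n_fail = int(cfg.failing_ppi_fraction * len(ppi_rows))
    for k in range(n_fail):
        i, j = rng.choice(len(all_prots), size=2, replace=False)
        a, b = sorted((all_prots[int(i)], all_prots[int(j)]))
        kind = k % 3
        if kind == 0:
            ppi_rows.append((a, b, "prediction", "Y2H;AP-MS", "prostate", "nuclear"))
        elif kind == 1:
            ppi_rows.append((a, b, "experimental", "Y2H", "prostate", "nuclear"))
        else:
            ppi_rows.append((a, b, "experimental", "Y2H;AP-MS", "prostate", "cytoplasm"))
    ppi_df = pd.DataFrame(
        ppi_rows,
        columns=["protein_a", "protein_b", "evidence_type", "methods", "tissues", "localizations"],
    )

    # ---- stage 6: expression ---------------------------------------------
    program_prots = {
        p for prog in programs.values() for lst in prog.values() for p in lst
    }
    expr_rows = []
    unexpressed = []
    for prot in all_prots:
        if prot not in program_prots and rng.random() < cfg.unexpressed_fraction:
            expr_rows.append((prot, 0.0005, 0.001))
            unexpressed.append(prot)
        else:
            expr_rows.append((prot, float(np.exp(rng.normal(1, 1))), float(np.exp(rng.normal(1, 1)))))
    for g in genes:
        expr_rows.append((g.gene_id, float(np.exp(rng.normal(1, 1))), float(np.exp(rng.normal(1, 1)))))
    expr_df = pd.DataFrame(expr_rows, columns=["gene_id", "rep1", "rep2"])

    # ---- stage 7: motif occurrences --------------------------------------
    motif_rows = []

    def add_hit(prot, chrom, start0, extra_p=1e-6):
        motif_rows.append(
            (f"M_{prot}", prot, chrom, start0 + 1, start0 + 10, "+", 12.0, extra_p, 1e-3, "N" * 10)
        )

    enh_by_gene: dict = {}
    for gid, chrom, center, d in enhancer_layout:
        enh_by_gene.setdefault(gid, []).append((chrom, center, d))
    for g in genes:
        gid, chrom, tss = g.gene_id, g.tss.chrom, g.tss.start
        prog = programs[clusters[gid]]
        for i, p in enumerate(prog["promoter_dbps"]):
            if rng.random() < cfg.program_motif_prob:
                add_hit(p, chrom, tss - 450 + i * 40)
        for p in dbps:
            if p not in prog["promoter_dbps"] and rng.random() < cfg.sprinkle_motif_prob:
                add_hit(p, chrom, tss - 450 + int(rng.integers(0, 880)))
        for chrom_e, center, _d in enh_by_gene.get(gid, []):
            pri = _predicted_prioritized(center, tss, cfg)
            for p in prog["enhancer_dbps"]:
                if rng.random() < cfg.program_motif_prob:
                    b = pri[int(rng.integers(0, len(pri)))]
                    off = center - 7000 + b * BIN + int(rng.integers(0, BIN - 10))
                    add_hit(p, chrom_e, off)
            for p in dbps:
                if p not in prog["enhancer_dbps"] and rng.random() < cfg.sprinkle_motif_prob:
                    b = int(rng.integers(0, 15))
                    off = center - 7000 + b * BIN + int(rng.integers(0, BIN - 10))
                    add_hit(p, chrom_e, off)
    motif_df = pd.DataFrame(
        motif_rows,
        columns=["motif_id", "motif_alt_id", "sequence_name", "start", "stop",
                 "strand", "score", "p-value", "q-value", "matched_sequence"],
    )

    # ---- stage 8: CTCF peaks ----------------------------------------------
    ctcf_rows = []
    ctcf_truth = {}
    for g in genes:
        gid, chrom, tss = g.gene_id, g.tss.chrom, g.tss.start
        prob = cfg.ctcf_prob_enriched if clusters[gid] in cfg.ctcf_clusters else cfg.ctcf_prob_base
        planted = rng.random() < prob
        ctcf_truth[gid] = bool(planted and enh_by_gene.get(gid))
        if planted and enh_by_gene.get(gid):
            ctcf_rows.append((chrom, tss + 2000, tss + 2300))
            _c, center, _d = enh_by_gene[gid][int(rng.integers(0, len(enh_by_gene[gid])))]
            ctcf_rows.append((chrom, center - 150, center + 150))
        elif rng.random() < 0.3:  # promoter-only peak: must label false
            ctcf_rows.append((chrom, tss + 2000, tss + 2300))

    # ---- stage 9: SNPs -----------------------------------------------------
    snp_rows = []
    snp_truth = {}
    rs = 0
    hit_index: dict = {}
    for row in motif_rows:
        chrom, start1 = row[2], row[3]
        hit_index.setdefault(chrom, []).append(row)
    for g in genes:
        gid, tss = g.gene_id, g.tss.start
        prob = cfg.snp_prob_enriched if clusters[gid] in cfg.snp_clusters else cfg.snp_prob_base
        planted = rng.random() < prob
        enh_hits = []
        for chrom_e, center, _d in enh_by_gene.get(gid, []):
            lo, hi = center - 7000, center + 8000
            enh_hits.extend(
                r for r in hit_index.get(chrom_e, []) if lo <= r[3] - 1 and r[4] <= hi
            )
        snp_truth[gid] = bool(planted and enh_hits)
        if planted and enh_hits:
            r = enh_hits[int(rng.integers(0, len(enh_hits)))]
            pos1 = int(rng.integers(r[3], r[4] + 1))  # 1-based inside the motif
            snp_rows.append((f"rs{rs:05d}", r[2], pos1, float(10 ** -rng.uniform(8, 30))))
            rs += 1
    # scenario-2 SNPs inside program-intermediate gene bodies (on chrP1 below)
    node_snp_prots = [
        p for prog in programs.values() for p in prog["intermediates"]
        if rng.random() < cfg.node_snp_prob
    ]
    # background SNPs
    for _ in range(cfg.n_background_snps):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        pos1 = int(rng.integers(500_000, cfg.chrom_size - 500_000))
        snp_rows.append((f"rs{rs:05d}", chrom, pos1, float(10 ** -rng.uniform(2, 7))))
        rs += 1

    # ---- stage 10: protein gene models (for scenario 2) -------------------
    protein_genes = []
    for i, prot in enumerate(all_prots):
        off = 100_000 + i * 12_000
        protein_genes.append(
            GeneModel(
                gene_id=prot,
                tss=GenomicInterval("chrP1", off, off + 1, "+"),
                body=GenomicInterval("chrP1", off, off + 8000, "+"),
            )
        )
    body_of = {g.gene_id: g.body for g in protein_genes}
    for prot in node_snp_prots:
        b = body_of[prot]
        pos1 = int(rng.integers(b.start + 1, b.end + 1))
        snp_rows.append((f"rs{rs:05d}", b.chrom, pos1, float(10 ** -rng.uniform(8, 25))))
        rs += 1
    snp_df = pd.DataFrame(snp_rows, columns=["rsid", "chrom", "pos", "assoc_p"])

    # ---- stage 11: oncogenes ----------------------------------------------
    oncogenes = []
    for g in genes:
        prob = cfg.onco_prob_enriched if clusters[g.gene_id] in cfg.ctcf_clusters else cfg.onco_prob_base
        if rng.random() < prob:
            oncogenes.append(g.gene_id)
    oncogenes += [f"EXT{i:03d}" for i in range(5)]  # list members outside the collection

    # ---- stage 12: DE labels ----------------------------------------------
    de_rows = []
    for name in all_prots + [g.gene_id for g in genes]:
        if rng.random() < cfg.de_covered_prob:
            de_rows.append((name, "DE" if rng.random() < cfg.de_prob else "not-DE"))
    de_df = pd.DataFrame(de_rows, columns=["gene_id", "status"])

    # ---- stage 13: trans-eQTL table ---------------------------------------
    eqtl_rows = []
    if len(snp_rows) > 0:
        gene_ids = [g.gene_id for g in genes]
        for r in snp_rows[:: max(1, len(snp_rows) // 30)]:
            n_assoc = int(rng.integers(1, 7))
            targets = rng.choice(gene_ids, size=min(n_assoc, len(gene_ids)), replace=False)
            eqtl_rows.append((r[0], ";".join(sorted(map(str, targets)))))
    eqtl_df = pd.DataFrame(eqtl_rows, columns=["rsid", "genes"])

    truth = {
        "biases": pd.DataFrame(
            [(c, s, s + BIN, b) for (c, s), b in sorted(betas.items())],
            columns=["chrom", "start", "end", "beta"],
        ),
        "clusters": clusters,
        "programs": programs,
        "ctcf_labels": ctcf_truth,
        "snp_labels": snp_truth,
        "unexpressed": unexpressed,
        "node_snp_proteins": node_snp_prots,
    }
    return SimulatedBundle(
        config=cfg,
        gene_models=genes + protein_genes,
        enhancer_layout=enhancer_layout,
        loops=loops_df,
        pair_counts=pair_df,
        enhancer_peaks=[GenomicInterval(c, s, e) for c, s, e in peak_rows],
        ctcf_peaks=[GenomicInterval(c, s, e) for c, s, e in ctcf_rows],
        motif_hits=motif_df,
        ppi=ppi_df,
        expression=expr_df,
        snps=snp_df,
        oncogenes=oncogenes,
        de_labels=de_df,
        eqtl=eqtl_df,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# spec-level operation views
# ---------------------------------------------------------------------------

def simulate_contacts(config: SimulationConfig):
    """Loop calls, 1-kb pair counts and the planted bias truth table."""
    b = simulate_bundle(config)
    return b.loops, b.pair_counts, b.truth["biases"]


def simulate_regulatory_layer(config: SimulationConfig):
    """Gene models, enhancer/CTCF peaks, motif hits, SNPs, oncogene list."""
    b = simulate_bundle(config)
    return {
        "gene_models": b.gene_models,
        "enhancer_peaks": b.enhancer_peaks,
        "ctcf_peaks": b.ctcf_peaks,
        "motif_hits": b.motif_hits,
        "snps": b.snps,
        "oncogenes": b.oncogenes,
        "truth": b.truth,
    }


def simulate_ppi_and_expression(config: SimulationConfig):
    b = simulate_bundle(config)
    return b.ppi, b.expression, b.truth["programs"]


def make_fixture_bundle(config: SimulationConfig, out_dir) -> dict:
    """Write a complete, format-valid input bundle plus truth tables.

    Returns the manifest (also written as ``manifest.json``)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    b = simulate_bundle(config)

    def tsv(df, name, **kw):
        p = out / name
        df.to_csv(p, sep="\t", index=False, **kw)
        return str(p)

    paths = {}
    paths["loops"] = tsv(b.loops, "loops.tsv")
    paths["pair_counts"] = tsv(b.pair_counts, "pair_counts.tsv")
    paths["motif_hits"] = tsv(b.motif_hits, "motif_hits.tsv")
    paths["ppi"] = tsv(b.ppi, "ppi.tsv")
    paths["expression"] = tsv(b.expression, "expression.tsv")
    paths["snps"] = tsv(b.snps, "snps.tsv")
    paths["de_labels"] = tsv(b.de_labels, "de_labels.tsv")
    paths["trans_eqtl"] = tsv(b.eqtl, "trans_eqtl.tsv")

    peaks = pd.DataFrame([(p.chrom, p.start, p.end) for p in b.enhancer_peaks])
    paths["enhancer_peaks"] = str(out / "enhancer_peaks.bed")
    peaks.to_csv(paths["enhancer_peaks"], sep="\t", index=False, header=False)
    cpeaks = pd.DataFrame([(p.chrom, p.start, p.end) for p in b.ctcf_peaks])
    paths["ctcf_peaks"] = str(out / "ctcf_peaks.bed")
    cpeaks.to_csv(paths["ctcf_peaks"], sep="\t", index=False, header=False)
    gdf = pd.DataFrame(
        [(g.body.chrom, g.body.start, g.body.end, g.gene_id, 0, g.body.strand)
         for g in b.gene_models]
    )
    paths["gene_models"] = str(out / "genes.bed")
    gdf.to_csv(paths["gene_models"], sep="\t", index=False, header=False)
    paths["oncogenes"] = str(out / "oncogenes.txt")
    Path(paths["oncogenes"]).write_text("\n".join(b.oncogenes) + "\n")

    paths["truth_biases"] = tsv(b.truth["biases"], "truth/biases.tsv")
    cl = pd.DataFrame(sorted(b.truth["clusters"].items()), columns=["gene_id", "cluster"])
    paths["truth_clusters"] = tsv(cl, "truth/clusters.tsv")
    for key in ("ctcf_labels", "snp_labels"):
        df = pd.DataFrame(
            sorted((g, int(v)) for g, v in b.truth[key].items()), columns=["gene_id", "label"]
        )
        paths[f"truth_{key}"] = tsv(df, f"truth/{key}.tsv")
    (out / "truth" / "programs.json").write_text(json.dumps(b.truth["programs"], indent=1))
    paths["truth_programs"] = str(out / "truth" / "programs.json")

    rel = {k: str(Path(v).relative_to(out)) for k, v in paths.items()}
    on_disk = {"seed": config.seed, "config": asdict(config), "paths": rel}
    (out / "manifest.json").write_text(json.dumps(on_disk, indent=1, sort_keys=True))
    return {"seed": config.seed, "config": asdict(config), "paths": paths}
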