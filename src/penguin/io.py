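"""Readers and writers for the standard-format inputs and tabular outputs.

Input dialects: BEDPE-like loop calls (FitHiChIP flavour, configurable column
mapping), BED / narrowPeak intervals, FIMO TSV motif occurrences, IID-style
PPI tables, BED-like gene models, SNP and expression TSVs. All coordinates
are normalized to 0-based half-open on ingest; outputs are deterministic,
sorted, tab-separated text.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .intervals import GenomicInterval

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LoopRecord:
    """A significant chromatin loop call: two same-chromosome anchors, a
    di-tag count and the FDR of the call."""

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    raw_count: float
    q_value: float

    def __post_init__(self) -> None:
        if self.anchor1.chrom != self.anchor2.chrom:
            raise ValueError("loop anchors must share a chromosome")
        if self.raw_count < 0:
            raise ValueError("raw_count must be non-negative")
        if not (0.0 <= self.q_value <= 1.0):
            raise ValueError("q_value must lie in [0, 1]")
        if self.anchor1.start > self.anchor2.start:
            a1, a2 = self.anchor2, self.anchor1
            object.__setattr__(self, "anchor1", a1)
            object.__setattr__(self, "anchor2", a2)


@dataclass(frozen=True)
class MotifHit:
    protein_id: str
    motif_id: str
    interval: GenomicInterval
    p_value: float
    q_value: float

    def __post_init__(self) -> None:
        if len(self.interval) < 4:
            raise ValueError("motif interval shorter than 4 bp is implausible")


@dataclass(frozen=True)
class SNPRecord:
    rsid: str
    position: GenomicInterval
    assoc_p: float

    def __post_init__(self) -> None:
        if len(self.position) != 1:
            raise ValueError("SNP position must span exactly 1 bp")
        if not (0.0 < self.assoc_p <= 1.0):
            raise ValueError("association p must lie in (0, 1]")


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    tss: GenomicInterval
    body: GenomicInterval

    def __post_init__(self) -> None:
        if not self.body.contains(self.tss):
            raise ValueError(f"TSS outside gene body for {self.gene_id}")
        if self.body.strand != self.tss.strand:
            raise ValueError(f"TSS/body strand mismatch for {self.gene_id}")


@dataclass(frozen=True)
class PPIEdge:
    """An unordered protein pair with evidence/tissue/localization annotations.

    The pair is stored canonically (lexicographic)."""

    protein_a: str
    protein_b: str
    evidence_type: str = "experimental"
    n_methods: int = 2
    tissues: frozenset = frozenset()
    localizations: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.protein_a == self.protein_b:
            raise ValueError("self-interactions are not allowed")
        if self.n_methods < 1:
            raise ValueError("n_methods must be >= 1")
        if self.protein_a > self.protein_b:
            a, b = self.protein_b, self.protein_a
            object.__setattr__(self, "protein_a", a)
            object.__setattr__(self, "protein_b", b)
        object.__setattr__(self, "tissues", frozenset(self.tissues))
        object.__setattr__(self, "localizations", frozenset(self.localizations))

    @property
    def pair(self) -> tuple:
        return (self.protein_a, self.protein_b)


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    fpkm: tuple

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.fpkm)
        if not vals:
            raise ValueError(f"no replicates for {self.gene_id}")
        if any(v != v or v in (float("inf"), float("-inf")) or v < 0 for v in vals):
            raise ValueError(f"non-finite or negative FPKM for {self.gene_id}")
        object.__setattr__(self, "fpkm", vals)


@dataclass
class PPIFilter:
    """Selection settings for the PPI table: evidence class, minimum number
    of independent assays, required tissue context and subcellular
    localization."""

    evidence: str = "experimental"
    min_methods: int = 2
    tissues: frozenset = frozenset({"prostate", "prostate cancer"})
    localization: str = "nuclear"


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

LOOP_COLUMNS = ("chr1", "start1", "end1", "chr2", "start2", "end2", "count", "qvalue")


def _read_tsv(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kw)


def read_loops(
    path,
    max_q: float = 0.01,
    columns: Mapping[str, str] | None = None,
) -> list[LoopRecord]:
    """Read significant loop calls from a BEDPE-like TSV.

    Only records with ``q_value < max_q`` are returned; anchors are ordered
    by start within each record. Inter-chromosomal rows are skipped with a
    warning; malformed coordinates raise an error naming the line.
    """
    df = _read_tsv(path)
    colmap = dict(zip(LOOP_COLUMNS, LOOP_COLUMNS))
    if columns:
        colmap.update(columns)
    missing = [c for c in colmap.values() if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing loop columns {missing}")
    records, skipped = [], 0
    for idx, r in enumerate(df.to_dict("records"), start=2):
        if r[colmap["chr1"]] != r[colmap["chr2"]]:
            skipped += 1
            continue
        try:
            a1 = GenomicInterval(str(r[colmap["chr1"]]), int(r[colmap["start1"]]), int(r[colmap["end1"]]))
            a2 = GenomicInterval(str(r[colmap["chr2"]]), int(r[colmap["start2"]]), int(r[colmap["end2"]]))
            rec = LoopRecord(a1, a2, float(r[colmap["count"]]), float(r[colmap["qvalue"]]))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: malformed loop at line {idx}: {exc}") from exc
        if rec.q_value < max_q:
            records.append(rec)
    if skipped:
        log.warning("%s: skipped %d inter-chromosomal loop(s)", path, skipped)
    return records


def read_pair_counts(path) -> dict:
    """Read 1-kb locus-pair counts (BEDPE-like, no q column) into a symmetric
    lookup keyed by ``(chrom, start_lo, start_hi)``."""
    df = _read_tsv(path)
    counts: dict = {}
    for idx, r in enumerate(df.to_dict("records"), start=2):
        if r["chr1"] != r["chr2"]:
            raise ValueError(f"{path}: inter-chromosomal pair at line {idx}")
        lo, hi = sorted((int(r["start1"]), int(r["start2"])))
        c = float(r["count"])
        if c < 0:
            raise ValueError(f"{path}: negative count at line {idx}")
        key = (str(r["chr1"]), lo, hi)
        counts[key] = counts.get(key, 0.0) + c
    return counts


def read_fimo_hits(path, max_p: float = 1e-4, max_q: float = 5e-2) -> list[MotifHit]:
    """Read FIMO TSV motif occurrences.

    FIMO reports 1-based inclusive coordinates; they are converted to the
    0-based half-open convention. The default significance filter
    (p <= 1e-4 and q <= 5e-2) is applied; a missing q column is treated as
    passing, with a warning.
    """
    try:
        df = _read_tsv(path)
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []
    cols = {c.lower().replace("-", "_"): c for c in df.columns}
    has_q = "q_value" in cols
    if not has_q:
        log.warning("%s: no q-value column; q filter not applied", path)
    protein_col = cols.get("motif_alt_id") or cols["motif_id"]
    hits = []
    for idx, row in df.iterrows():
        start1, stop1 = int(row[cols["start"]]), int(row[cols["stop"]])
        if start1 > stop1:
            raise ValueError(f"{path}: start > stop at line {idx + 2}")
        p = float(row[cols["p_value"]])
        q = float(row[cols["q_value"]]) if has_q else 0.0
        if p > max_p or q > max_q:
            continue
        hits.append(
            MotifHit(
                protein_id=str(row[protein_col]),
                motif_id=str(row[cols["motif_id"]]),
                interval=GenomicInterval(
                    str(row[cols["sequence_name"]]),
                    start1 - 1,
                    stop1,
                    str(row[cols["strand"]]) if "strand" in cols else ".",
                ),
                p_value=p,
                q_value=q,
            )
        )
    return hits


def read_ppi_table(path, filters: PPIFilter | None = None) -> list[PPIEdge]:
    """Read an IID-style PPI table and apply context filters.

    Edges are kept when the evidence class matches, >= ``min_methods``
    independent assays are listed, at least one requested tissue label is
    present, and the required localization is annotated. Duplicate pairs are
    merged with their annotations unioned (warning emitted).
    """
    filters = filters or PPIFilter()
    df = _read_tsv(path)
    merged: dict = {}
    dupes = 0
    for _, row in df.iterrows():
        a, b = str(row["protein_a"]), str(row["protein_b"])
        if a == b:
            continue
        methods = [m for m in str(row.get("methods", "")).split(";") if m and m != "nan"]
        edge = PPIEdge(
            a, b,
            evidence_type=str(row.get("evidence_type", "")),
            n_methods=max(1, len(methods)),
            tissues=frozenset(t for t in str(row.get("tissues", "")).split(";") if t and t != "nan"),
            localizations=frozenset(l for l in str(row.get("localizations", "")).split(";") if l and l != "nan"),
        )
        prev = merged.get(edge.pair)
        if prev is None:
            merged[edge.pair] = edge
        else:
            dupes += 1
            merged[edge.pair] = replace(
                prev,
                n_methods=max(prev.n_methods, edge.n_methods),
                tissues=prev.tissues | edge.tissues,
                localizations=prev.localizations | edge.localizations,
            )
    if dupes:
        log.warning("%s: %d duplicate PPI pair(s) merged", path, dupes)
    kept = [
        e for e in merged.values()
        if e.evidence_type == filters.evidence
        and e.n_methods >= filters.min_methods
        and (e.tissues & filters.tissues)
        and filters.localization in e.localizations
    ]
    return sorted(kept, key=lambda e: e.pair)


def read_bed_intervals(path) -> list[GenomicInterval]:
    """Read BED3+/narrowPeak rows verbatim (already 0-based half-open)."""
    df = _read_tsv(path, header=None)
    out = []
    for idx, row in df.iterrows():
        try:
            strand = str(row[5]) if len(row) > 5 and str(row[5]) in "+-" else "."
            out.append(GenomicInterval(str(row[0]), int(row[1]), int(row[2]), strand))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: bad interval at line {idx + 1}: {exc}") from exc
    return out


def read_gene_models(path) -> list[GeneModel]:
    """Read BED6-like gene bodies (chrom, start, end, gene_id, score, strand);
    the TSS is the 5' end of the body according to strand."""
    df = _read_tsv(path, header=None)
    genes = []
    for idx, row in df.iterrows():
        try:
            chrom, start, end = str(row[0]), int(row[1]), int(row[2])
            gene_id, strand = str(row[3]), str(row[5])
            tss_pos = start if strand == "+" else end - 1
            genes.append(
                GeneModel(
                    gene_id,
                    tss=GenomicInterval(chrom, tss_pos, tss_pos + 1, strand),
                    body=GenomicInterval(chrom, start, end, strand),
                )
            )
        except (ValueError, TypeError, KeyError) as exc:
            raise ValueError(f"{path}: bad gene model at line {idx + 1}: {exc}") from exc
    return genes


def read_snps(path) -> list[SNPRecord]:
    """Read SNPs from a TSV (rsid, chrom, pos, assoc_p); positions are
    1-based in the file and shifted to 0-based half-open."""
    df = _read_tsv(path)
    snps = []
    for idx, row in df.iterrows():
        try:
            pos1 = int(row["pos"])
            snps.append(
                SNPRecord(
                    rsid=str(row["rsid"]),
                    position=GenomicInterval(str(row["chrom"]), pos1 - 1, pos1),
                    assoc_p=float(row["assoc_p"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: bad SNP at line {idx + 2}: {exc}") from exc
    return snps


def read_expression(path) -> list[ExpressionRecord]:
    """Read a gene x replicate FPKM table (first column gene_id)."""
    df = _read_tsv(path)
    rep_cols = [c for c in df.columns if c != "gene_id"]
    records = []
    for _, row in df.iterrows():
        gene = str(row["gene_id"])
        vals = []
        for c in rep_cols:
            v = row[c]
            if pd.isna(v):
                raise ValueError(f"{path}: missing FPKM value for gene {gene}")
            vals.append(float(v))
        records.append(ExpressionRecord(gene, tuple(vals)))
    return records


def read_gene_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip() and not line.startswith("#")]


# ---------------------------------------------------------------------------
# writers (deterministic, sorted TSV)
# ---------------------------------------------------------------------------

def _write_df(df: pd.DataFrame, path: Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def write_loops(loops: Iterable[LoopRecord], path) -> Path:
    rows = sorted(
        (
            (l.anchor1.chrom, l.anchor1.start, l.anchor1.end,
             l.anchor2.chrom, l.anchor2.start, l.anchor2.end,
             l.raw_count, l.q_value)
            for l in loops
        )
    )
    return _write_df(pd.DataFrame(rows, columns=list(LOOP_COLUMNS)), path)


def write_cluster_assignments(assignment: Mapping[str, int], path) -> Path:
    rows = sorted(assignment.items())
    return _write_df(pd.DataFrame(rows, columns=["gene_id", "cluster"]), path)


def read_cluster_assignments(path) -> dict:
    df = _read_tsv(path)
    return {str(r.gene_id): int(r.cluster) for r in df.itertuples(index=False)}


def write_labels(labels: Mapping[str, bool], path) -> Path:
    rows = sorted((g, int(v)) for g, v in labels.items())
    return _write_df(pd.DataFrame(rows, columns=["gene_id", "label"]), path)


def read_labels(path) -> dict:
    df = _read_tsv(path)
    return {str(r.gene_id): bool(r.label) for r in df.itertuples(index=False)}


def write_enrichment_records(records, path) -> Path:
    rows = sorted(
        (r.unit, r.annotation, *r.table, r.odds_ratio, r.p_value, r.direction, r.p_bonferroni)
        for r in records
    )
    cols = ["unit", "annotation", "a", "b", "c", "d", "odds_ratio", "p_value", "direction", "p_bonferroni"]
    return _write_df(pd.DataFrame(rows, columns=cols), path)
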