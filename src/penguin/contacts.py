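"""Enhancer-promoter contact preparation.

Loops are classified into E-P contacts (exactly one padded anchor over a
promoter, the other over an enhancer peak), short- and long-range contacts
are removed, a distance-decay expectation E(d) is fitted, per-locus
multiplicative biases are solved in 3x3 sliding windows against the three
1-kb promoter loci, counts are normalized as N = O / (beta_x * beta_y), and
the most interacting 1-kb enhancer bins are prioritized.

The bias model is the standard multiplicative one used by matrix-balancing
normalizations: O_xy ~ s * beta_x * beta_y * E(d_xy). The six per-window
biases are gauge-fixed to geometric mean one; a free overall scale s absorbs
sequencing depth so that the biases depend only on count *ratios* (and the
normalized profile scales linearly with the raw counts).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import minimize

from .intervals import GenomicInterval
from .io import GeneModel, LoopRecord

log = logging.getLogger(__name__)

BIN = 1000  # working resolution in bp


@dataclass
class EPContact:
    """One promoter paired with one 15-kb enhancer region.

    ``raw_counts`` and ``normalized_counts`` are (n_bins x 3) tables over
    enhancer bins x the three 1-kb promoter loci (TSS-1kb .. TSS+2kb).
    """

    gene_id: str
    promoter_region: GenomicInterval          # TSS .. TSS+1kb (target locus)
    promoter_loci: list                       # 3 consecutive 1-kb intervals
    enhancer_region: GenomicInterval          # padded anchor (15 kb)
    enhancer_bins: list                       # 1-kb tiling of enhancer_region
    raw_counts: np.ndarray | None = None
    normalized_counts: np.ndarray | None = None
    enhancer_betas: np.ndarray | None = None
    promoter_betas: np.ndarray | None = None
    prioritized: list = field(default_factory=list)
    flags: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.promoter_region.chrom != self.enhancer_region.chrom:
            raise ValueError("promoter and enhancer must share a chromosome")
        tiled = self.enhancer_bins[0].start == self.enhancer_region.start and \
            self.enhancer_bins[-1].end == self.enhancer_region.end and \
            all(b.end - b.start == BIN for b in self.enhancer_bins) and \
            all(self.enhancer_bins[i + 1].start == self.enhancer_bins[i].end
                for i in range(len(self.enhancer_bins) - 1))
        if not tiled:
            raise ValueError("enhancer bins must tile the enhancer region exactly")

    @property
    def separation(self) -> float:
        """Midpoint-to-midpoint distance between the promoter target locus
        and the enhancer region."""
        return abs(self.promoter_region.midpoint - self.enhancer_region.midpoint)


@dataclass
class DistanceDecayModel:
    """Power-law expectation E(d) = exp(a + b log d), b <= 0."""

    distance_grid: np.ndarray
    expected_count: np.ndarray
    intercept: float
    slope: float

    def expected(self, d) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        return np.exp(self.intercept + self.slope * np.log(np.maximum(d, 1.0)))


@dataclass
class BiasWindow:
    promoter_betas: np.ndarray
    enhancer_betas: np.ndarray
    scale: float
    residual: float
    degenerate: bool = False


# ---------------------------------------------------------------------------
# classification and filtering
# ---------------------------------------------------------------------------

def _overlap_any(iv: GenomicInterval, others) -> list:
    return [o for o in others if iv.overlaps(o)]


def classify_ep_contacts(
    loops,
    gene_models,
    enhancer_peaks,
    pad: int = 5000,
    promoter_halfwidth: int = 500,
) -> list[EPContact]:
    """Classify loops into E-P contacts.

    Anchors are padded by ``pad`` bp on either side. A loop is E-P when
    exactly one padded anchor overlaps >=1 promoter region (TSS +/- 500 bp)
    and the other overlaps >=1 enhancer peak; one contact is produced per
    (promoter gene, loop). The promoter loci used downstream for
    normalization span TSS-1kb .. TSS+2kb.
    """
    promoters = {
        g.gene_id: GenomicInterval(
            g.tss.chrom,
            max(0, g.tss.start - promoter_halfwidth),
            g.tss.start + promoter_halfwidth + 1,
        )
        for g in gene_models
    }
    models = {g.gene_id: g for g in gene_models}
    by_chrom_prom: dict = {}
    for gid, iv in promoters.items():
        by_chrom_prom.setdefault(iv.chrom, []).append((gid, iv))
    by_chrom_enh: dict = {}
    for pk in enhancer_peaks:
        by_chrom_enh.setdefault(pk.chrom, []).append(pk)

    contacts = []
    for loop in loops:
        chrom = loop.anchor1.chrom
        padded = [loop.anchor1.expand(pad), loop.anchor2.expand(pad)]
        prom_hits = [
            [gid for gid, iv in by_chrom_prom.get(chrom, []) if a.overlaps(iv)]
            for a in padded
        ]
        enh_hits = [bool(_overlap_any(a, by_chrom_enh.get(chrom, []))) for a in padded]
        has_prom = [bool(h) for h in prom_hits]
        if has_prom[0] == has_prom[1]:
            continue  # promoter on both sides, or on neither
        p_side = 0 if has_prom[0] else 1
        e_side = 1 - p_side
        if not enh_hits[e_side]:
            continue
        enh_region = padded[e_side]
        if len(enh_region) % BIN:
            raise ValueError(
                f"padded anchor length {len(enh_region)} is not a multiple of {BIN} bp"
            )
        bins = [
            GenomicInterval(chrom, s, s + BIN)
            for s in range(enh_region.start, enh_region.end, BIN)
        ]
        for gid in prom_hits[p_side]:
            tss = models[gid].tss.start
            loci = [
                GenomicInterval(chrom, tss - BIN + i * BIN, tss + i * BIN)
                for i in range(3)
            ]
            contacts.append(
                EPContact(
                    gene_id=gid,
                    promoter_region=GenomicInterval(chrom, tss, tss + BIN),
                    promoter_loci=loci,
                    enhancer_region=enh_region,
                    enhancer_bins=bins,
                )
            )
    return contacts


def attach_counts(contacts, pair_counts: dict) -> None:
    """Fill each contact's raw (enhancer bin x promoter locus) count table
    from a 1-kb pair-count lookup (missing pairs read as 0)."""
    for c in contacts:
        chrom = c.enhancer_region.chrom
        O = np.zeros((len(c.enhancer_bins), 3))
        for i, b in enumerate(c.enhancer_bins):
            for j, p in enumerate(c.promoter_loci):
                lo, hi = sorted((b.start, p.start))
                O[i, j] = pair_counts.get((chrom, lo, hi), 0.0)
        c.raw_counts = O


def filter_short_range(contacts, min_sep: int = 10_000, max_sep: int = 3_000_000) -> list:
    """Drop contacts closer than ``min_sep`` (strict <) or farther than
    ``max_sep`` (strict >), midpoint-to-midpoint."""
    return [c for c in contacts if min_sep <= c.separation <= max_sep]


# ---------------------------------------------------------------------------
# distance decay
# ---------------------------------------------------------------------------

def fit_distance_decay(
    contacts, n_bins: int = 50, min_obs: int = 50, max_unique: int = 1000
) -> DistanceDecayModel:
    """Fit E(d) = exp(a + b log d) on log-transformed mean counts per
    distance bin by least squares; b <= 0 is enforced by projection.

    Observations are all (enhancer bin, promoter locus) midpoint distances
    with their raw counts. Distances are grouped exactly when few distinct
    values exist, otherwise into ``n_bins`` log-spaced bins.
    """
    dists, counts = [], []
    for c in contacts:
        if c.raw_counts is None:
            continue
        for i, b in enumerate(c.enhancer_bins):
            for j, p in enumerate(c.promoter_loci):
                dists.append(abs(b.midpoint - p.midpoint))
                counts.append(c.raw_counts[i, j])
    d = np.asarray(dists, dtype=float)
    y = np.asarray(counts, dtype=float)
    if d.size < min_obs:
        raise ValueError(f"need >= {min_obs} observations, got {d.size}")
    if d.max() / max(d.min(), 1.0) < 10.0:
        raise ValueError("distance range spans less than one decade")

    uniq = np.unique(d)
    if uniq.size <= max_unique:
        centers, means = [], []
        for u in uniq:
            m = y[d == u].mean()
            if m > 0:
                centers.append(u)
                means.append(m)
    else:
        edges = np.geomspace(d.min(), d.max() * (1 + 1e-12), n_bins + 1)
        which = np.clip(np.searchsorted(edges, d, side="right") - 1, 0, n_bins - 1)
        centers, means = [], []
        for k in range(n_bins):
            sel = which == k
            if sel.any() and y[sel].mean() > 0:
                centers.append(np.exp(np.log(d[sel]).mean()))
                means.append(y[sel].mean())
    centers = np.asarray(centers)
    means = np.asarray(means)
    if centers.size < 2:
        raise ValueError("degenerate distance profile")
    x = np.log(centers)
    z = np.log(means)
    slope, intercept = np.polyfit(x, z, 1)
    if slope > 0 or abs(slope) < 1e-12:  # projection onto b <= 0; snap fp dust
        slope, intercept = 0.0, float(z.mean())
    return DistanceDecayModel(
        distance_grid=centers,
        expected_count=np.exp(intercept + slope * x),
        intercept=float(intercept),
        slope=float(slope),
    )


# ---------------------------------------------------------------------------
# per-window bias solving and normalization
# ---------------------------------------------------------------------------

def solve_window_biases(
    O: np.ndarray,
    E: np.ndarray,
    beta_min: float = 1e-3,
    max_iter: int = 150,
    x0: np.ndarray | None = None,
) -> BiasWindow:
    """Solve the 9-equation window system min sum (O - s*bx*by*E)^2.

    Three enhancer-side and three promoter-side biases plus a free overall
    scale ``s``. The product model has two gauge freedoms (overall scale,
    and the enhancer/promoter scale split), fixed by constraining the
    geometric mean of each side's three biases to one; ``s`` absorbs depth,
    which makes the solved biases invariant under rescaling all counts.
    Solved by SQP (SLSQP) with an analytic gradient, started at beta = 1.
    All-zero windows or a non-converged solve return the flat fallback,
    flagged degenerate.
    """
    O = np.asarray(O, dtype=float)
    E = np.asarray(E, dtype=float)
    if O.shape != (3, 3) or E.shape != (3, 3):
        raise ValueError("window must be 3x3")
    if (E <= 0).any():
        raise ValueError("expectations must be strictly positive")
    if (O < 0).any():
        raise ValueError("counts must be non-negative")
    if not O.any():
        return BiasWindow(np.ones(3), np.ones(3), 0.0, 0.0, degenerate=True)

    def objective(theta):
        be, bp, s = theta[:3], theta[3:6], theta[6]
        M = s * np.outer(be, bp) * E
        R = O - M
        f = float((R ** 2).sum())
        G = -2.0 * R * M  # df/d log-model per cell
        grad = np.empty(7)
        grad[:3] = G.sum(axis=1) / be
        grad[3:6] = G.sum(axis=0) / bp
        grad[6] = G.sum() / s
        return f, grad

    s0 = O.sum() / E.sum()
    flat = np.array([1.0] * 6 + [max(s0, 1e-9)])
    # moment start: centred log row/column means of O/E
    logr = np.log(np.maximum(O, 0.05 * O.max()) / E)
    a = logr.mean(axis=1)
    b = logr.mean(axis=0)
    moment = np.concatenate([
        np.maximum(np.exp(a - a.mean()), beta_min),
        np.maximum(np.exp(b - b.mean()), beta_min),
        [max(np.exp(logr.mean()), 1e-9)],
    ])
    starts = [moment, flat] if x0 is None else [np.asarray(x0, dtype=float), moment, flat]
    cons = [
        {"type": "eq", "fun": lambda t: np.sum(np.log(t[:3])),
         "jac": lambda t: np.concatenate([1.0 / t[:3], np.zeros(4)])},
        {"type": "eq", "fun": lambda t: np.sum(np.log(t[3:6])),
         "jac": lambda t: np.concatenate([np.zeros(3), 1.0 / t[3:6], np.zeros(1)])},
    ]
    best = None
    for start in starts:
        res = minimize(
            objective, start, jac=True, method="SLSQP",
            bounds=[(beta_min, None)] * 6 + [(1e-12, None)],
            constraints=cons,
            options={"maxiter": max_iter, "ftol": 1e-12},
        )
        if res.success and (best is None or res.fun < best.fun):
            best = res
            break
    if best is None:
        log.debug("window bias solve did not converge; flat fallback used")
        return BiasWindow(np.ones(3), np.ones(3), s0, objective(flat)[0], degenerate=True)
    return BiasWindow(
        promoter_betas=np.asarray(best.x[3:6]),
        enhancer_betas=np.asarray(best.x[:3]),
        scale=float(best.x[6]),
        residual=float(best.fun),
        degenerate=False,
    )


def _geomean(v) -> float:
    return float(np.exp(np.mean(np.log(v))))


def normalize_contact(contact: EPContact, decay: DistanceDecayModel, beta_min: float = 1e-3) -> EPContact:
    """Estimate per-locus biases in overlapping 3-bin windows along the
    enhancer (always against the three promoter loci) and set
    N = O / (bx * by).

    Each window determines its three enhancer biases only up to a window
    scale, so consecutive windows are chained into a common scale via their
    two shared loci before each locus's bias is averaged (arithmetic mean)
    over the windows containing it. The final enhancer and promoter bias
    vectors are gauge-fixed to geometric mean one. Degenerate windows are
    excluded from chaining and averaging.
    """
    if contact.raw_counts is None:
        raise ValueError("contact has no raw counts")
    n = len(contact.enhancer_bins)
    O = contact.raw_counts
    d = np.array(
        [[abs(b.midpoint - p.midpoint) for p in contact.promoter_loci]
         for b in contact.enhancer_bins]
    )
    E = decay.expected(d)
    wins: dict = {}
    for w in range(n - 2):
        win = solve_window_biases(O[w:w + 3, :], E[w:w + 3, :], beta_min=beta_min)
        if win.degenerate:
            contact.flags.add("degenerate_window")
            continue
        wins[w] = win

    if not wins:
        contact.flags.add("all_windows_degenerate")
        bx = np.ones(n)
        by = np.ones(3)
    else:
        # Each window pins its enhancer triple only up to a window scale.
        # Register all windows onto a common scale by least squares in log
        # space (unknowns: per-bin log-bias u_b and per-window offset c_w),
        # which reduces to the plain per-bin mean when scales agree and is
        # exact on noiseless products.
        order = sorted(wins)
        widx = {w: i for i, w in enumerate(order)}
        rows, rhs = [], []
        for w in order:
            for k in range(3):
                row = np.zeros(n + len(order))
                row[w + k] = 1.0
                row[n + widx[w]] = 1.0
                rows.append(row)
                rhs.append(np.log(wins[w].enhancer_betas[k]))
        # gauge: mean of covered log-biases is 0
        covered = np.zeros(n, dtype=bool)
        for w in order:
            covered[w:w + 3] = True
        row = np.zeros(n + len(order))
        row[:n] = covered.astype(float)
        rows.append(row)
        rhs.append(0.0)
        sol, *_ = np.linalg.lstsq(np.asarray(rows), np.asarray(rhs), rcond=None)
        bx = np.where(covered, np.exp(sol[:n]), 1.0)
        by = np.array([
            np.mean([wins[w].promoter_betas[k] for w in order]) for k in range(3)
        ])
        by /= _geomean(by)
        bx = np.maximum(bx, beta_min)
        by = np.maximum(by, beta_min)
    contact.enhancer_betas = bx
    contact.promoter_betas = by
    contact.normalized_counts = O / np.outer(bx, by)
    return contact


def bias_recovery_correlation(contacts, beta_lookup: dict) -> float:
    """Pearson correlation between planted and recovered enhancer-locus
    biases, pooled over contacts after per-contact gauge alignment (each
    contact's bias vector is defined only up to a scale; both planted and
    recovered vectors are divided by their within-contact geometric mean)."""
    planted_all, recovered_all = [], []
    for c in contacts:
        if c.enhancer_betas is None:
            continue
        planted = np.array(
            [beta_lookup[(b.chrom, b.start)] for b in c.enhancer_bins]
        )
        rec = np.asarray(c.enhancer_betas)
        planted_all.append(planted / _geomean(planted))
        recovered_all.append(rec / _geomean(rec))
    p = np.concatenate(planted_all)
    r = np.concatenate(recovered_all)
    return float(np.corrcoef(p, r)[0, 1])


def prioritize_bins(contact: EPContact, fraction: float = 0.8) -> EPContact:
    """Select the most interacting 1-kb enhancer bins: every bin whose
    summed normalized count reaches ``fraction`` of the maximum bin (ties
    included). With all-zero scores no bin is selected and the contact is
    flagged."""
    if contact.normalized_counts is None:
        raise ValueError("contact not normalized")
    scores = contact.normalized_counts.sum(axis=1)
    top = scores.max()
    if top <= 0:
        contact.prioritized = []
        contact.flags.add("no_signal")
        return contact
    keep = (scores >= fraction * top) & (scores > 0)
    contact.prioritized = [b for b, k in zip(contact.enhancer_bins, keep) if k]
    return contact


# ---------------------------------------------------------------------------
# tabular round trip (one row per enhancer bin)
# ---------------------------------------------------------------------------

def write_contact_table(contacts, path):
    import pandas as pd

    rows = []
    for c in sorted(contacts, key=lambda c: (c.gene_id, c.enhancer_region.start)):
        pri = {b.start for b in c.prioritized}
        flags = ";".join(sorted(c.flags))
        for i, b in enumerate(c.enhancer_bins):
            row = {
                "gene_id": c.gene_id,
                "chrom": c.enhancer_region.chrom,
                "tss": c.promoter_region.start,
                "enh_start": c.enhancer_region.start,
                "enh_end": c.enhancer_region.end,
                "bin_start": b.start,
                "prioritized": int(b.start in pri),
                "flags": flags,
            }
            for j in range(3):
                row[f"O{j + 1}"] = c.raw_counts[i, j] if c.raw_counts is not None else ""
                row[f"N{j + 1}"] = (
                    c.normalized_counts[i, j] if c.normalized_counts is not None else ""
                )
            rows.append(row)
    df = pd.DataFrame(rows)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_contact_table(path):
    import pandas as pd

    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    contacts = []
    for (gid, chrom, tss, es, ee), grp in df.groupby(
        ["gene_id", "chrom", "tss", "enh_start", "enh_end"], sort=True
    ):
        grp = grp.sort_values("bin_start")
        bins = [GenomicInterval(chrom, s, s + BIN) for s in grp["bin_start"]]
        c = EPContact(
            gene_id=str(gid),
            promoter_region=GenomicInterval(chrom, int(tss), int(tss) + BIN),
            promoter_loci=[
                GenomicInterval(chrom, int(tss) - BIN + k * BIN, int(tss) + k * BIN)
                for k in range(3)
            ],
            enhancer_region=GenomicInterval(chrom, int(es), int(ee)),
            enhancer_bins=bins,
        )
        if (grp["O1"].astype(str) != "").all():
            c.raw_counts = grp[["O1", "O2", "O3"]].astype(float).to_numpy()
        if (grp["N1"].astype(str) != "").all():
            c.normalized_counts = grp[["N1", "N2", "N3"]].astype(float).to_numpy()
        c.prioritized = [b for b, p in zip(bins, grp["prioritized"]) if int(p)]
        fl = str(grp["flags"].iloc[0])
        c.flags = set(fl.split(";")) if fl else set()
        contacts.append(c)
    return contacts
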