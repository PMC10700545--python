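# Methods

This note documents the models, numerical choices and limitations behind
the package; the README gives the high-level tour.

## Coordinates and inputs

All genomic coordinates are 0-based half-open internally. BED/narrowPeak
rows are read verbatim; FIMO occurrences (1-based inclusive) and SNP
positions (1-based) are shifted on ingest. Strand is carried for reporting
but ignored by every overlap computation. Chromosome-name style mismatches
between files ("chr1" vs "1") are detected and raised, never silently
harmonized. Loop calls arrive as a BEDPE-like TSV with a configurable
column mapping (loop callers differ in column naming); 1-kb locus-pair
counts arrive in a second file of the same dialect because 5-kb loop calls
cannot carry the 1-kb resolution the normalization needs.

## E–P classification

Anchors are padded `anchor_pad` (default 5000 bp) per side, giving 15-kb
regions for 5-kb calls. A loop is E–P when exactly one padded anchor
overlaps ≥1 promoter window (TSS ± 500 bp) and the other ≥1 enhancer peak;
a loop whose both anchors overlap promoters is discarded. One contact is
produced per (promoter gene, loop). Two distinct promoter windows are in
play deliberately: motif scanning uses TSS ± 500 bp, while normalization
uses the three 1-kb loci TSS−1 kb…TSS+2 kb; they are independent settings.
Separation is measured midpoint-to-midpoint between the 1-kb promoter
target locus and the 15-kb enhancer region, with strict `<` at the 10-kb
minimum and strict `>` at the 3-Mb maximum.

## Distance decay

`E(d) = exp(a + b log d)` is fitted globally (not per chromosome) by
ordinary least squares on log mean counts per distance bin. Distances are
grouped exactly while ≤1000 distinct values exist (counts live on a 1-kb
grid, so ties are the norm; exact grouping keeps a pure power law exactly
recoverable), otherwise in 50 log-spaced bins represented by their
geometric-mean distance. `b > 0` is projected to 0 (flat profile), and
|b| < 1e-12 is snapped to 0 to avoid floating dust on exactly flat input.
The fit requires ≥50 observations spanning ≥1 decade of distance.

## Window bias model

Within a window of three enhancer loci × the three promoter loci,

    minimize  Σ_xy (O_xy − s·β_x·β_y·E_xy)²
    subject to β ≥ β_min (default 1e−3),
               geomean(β_enhancer) = 1,  geomean(β_promoter) = 1,

solved with SLSQP (an SQP method) using an analytic gradient. The product
model has *two* gauge freedoms — the overall scale and the
enhancer/promoter scale split — hence one geometric-mean constraint per
side; the free scale `s` absorbs sequencing depth, which is what makes the
solved biases exactly invariant under rescaling all counts (and the
normalized profile scale linearly with them). The solver starts from a
closed-form moment estimate (centred log row/column means of O/E) and
falls back to the flat start, then to β = 1 flagged `degenerate` if neither
converges; all-zero windows are degenerate by definition.

### Aggregation across windows

Each window pins its enhancer triple only up to a window scale, so the 13
per-window estimates cannot be averaged directly. They are registered onto
a common scale by least squares in log space — unknowns are one log-bias
per bin and one offset per window, with the mean covered log-bias fixed to
zero — which reduces to the plain per-bin arithmetic mean when the window
scales agree, is exact on noiseless products, and avoids the random-walk
drift a sequential chain stitch would accumulate. Promoter biases are the
plain mean of the per-window triples (their gauge is already common). Both
final vectors are gauge-fixed to geometric mean one, so recovered biases
are comparable *within* a contact only up to a contact-level scale; the
bias-recovery correlation is therefore computed after dividing planted and
recovered vectors by their within-contact geometric means. Degenerate
windows are excluded from registration; a contact with no usable window is
flagged and passed through unnormalized (β = 1).

## Prioritization

Per-bin score = Σ over the three promoter loci of N. Every bin whose score
reaches `prioritize_fraction` (default 0.8) of the maximum and is positive
is kept; ties at the threshold are all kept; all-zero contacts keep nothing
and are flagged. The exact "most interacting" rule is not canonical, so
the fraction is a config knob.

## EPIN construction

Bound sets are restricted to proteins present in the expression-filtered
PPI graph. Edges are (i) PPI edges with one endpoint promoter-bound and the
other enhancer-bound (direct), and (ii) for every protein v outside both
bound sets adjacent to ≥1 bound protein on *each* side, all v–bound edges,
with v recorded as an intermediate. Same-side bound–bound and
intermediate–intermediate edges are excluded; a protein bound on both
sides can serve either role in a direct edge but is never an intermediate.
The edge set provably equals the set of edges on promoter→enhancer paths
of length ≤2 with non-bound middle nodes; the tests assert this against
brute-force enumeration. The expression filter is strict (`FPKM >
0.003` in every replicate); proteins lacking an expression record are
excluded and counted.

## Clustering and enrichment

Distance: `1 − |E_A ∩ E_B| / |U|` over the edge universe U (union of all
EPIN edge sets), with the diagonal forced to 0 since the raw formula gives
`1 − |E_A|/|U|` on it; a Jaccard variant (a true pseudo-metric, used for
metric-property tests) is available. Ward linkage via scipy; cuts are
relabelled deterministically (decreasing size, then lexicographically
smallest leaf). Fisher tests report the unconditional sample odds ratio
ad/bc (0 and +∞ at the degenerate margins; the conditional MLE that scipy
reports by default is *not* used) with scipy's two-sided exact p. Branch
tests compare leaves under a branch against the rest of the tree at
α = 0.001, with a Bonferroni column emitted for information but no
correction applied to the decision. CTCF labels demand a peak within 10 kb
of the promoter *and* of ≥1 enhancer region (full 15-kb regions); SNP
labels use the prioritized 1-kb bins with a 10-kb window and four scope
variants. Hotspots merge intervals separated by strictly less than the gap
(15 kb enhancers, 20 kb eQTL clusters) per chromosome. NMI uses the
arithmetic normalization; single-class partitions are defined as NMI 0 and
flagged; the randomization p shuffles one partition's labels with a seeded
generator and carries the +1 correction.

## Centrality and specificity

Degree and unnormalized shortest-path betweenness (even splitting over
equally short paths) on each EPIN as a simple undirected graph.
Specificity S(P, C) is the ratio of P's mean centrality over the EPINs in
C to its mean over those outside, with absence counted as 0 in both means
(keeps S defined for rare proteins; stated here rather than hidden).
Unnormalized betweenness is used; normalization would not change
permutation ranks within an EPIN but would across EPINs of different
sizes. The permutation test draws `n_perm` (default 1000) same-size EPIN
subsets without replacement within each draw and reports
`(1 + #{S_rand ≥ S_obs}) / (n_perm + 1)` — conservative, never exactly 0;
an observed +∞ is matched only by a random +∞; 0/0 specificity is NaN and
excluded. "Significantly specific" proteins must pass degree p < α,
betweenness p < α, and presence enrichment p < α with OR > 1 (α default
0.01); an α ≥ 1 is treated as the degenerate no-filter threshold. No
protein is ever special-cased: a protein failing the presence test drops
out of the conjunction automatically.

## SNP paths

Scenario 1 requires the SNP strictly inside a motif occurrence overlapping
a prioritized bin — no 10-kb window here, since the disruption hypothesis
needs the variant inside the binding site; the window belongs to the
cluster-annotation layer only. Scenario 2 uses gene bodies exactly as
provided (no UTR/promoter extension). A SNP satisfying both scenarios
yields two records. Paths are all enhancer-bound → (≤1 intermediate) →
promoter-bound chains containing the affected protein, ordered
deterministically, and every emitted path is validated edge-by-edge
against the EPIN. DE enrichment is Fraction1/Fraction2 over *intermediates
only*, where Fraction1 is the DE fraction among covered intermediates on
SNP paths and Fraction2 the same over the whole EPIN; genes uncovered by
the DE data are excluded from numerators and denominators, and a zero
denominator yields an undefined sentinel rather than a number.

## Synthetic data

One generator, one seed, one documented draw order (gene layout →
enhancers/loops → biases → counts → PPI wiring → expression → motifs →
CTCF → SNPs → protein gene models → oncogenes → DE labels → eQTLs), so a
bundle is byte-identical under a fixed seed and partial regeneration is
impossible by design. It emulates: power-law distance decay with planted
lognormal per-locus biases (σ default 0.3) and Poisson counts (a noiseless
mode writes exact products, hence non-integer counts); per-cluster PPI
wiring programs (disjoint promoter-DBP/enhancer-DBP/intermediate triples)
over a random background graph; motif occurrences realizing the programs,
placed in the enhancer bins expected to be prioritized; planted CTCF,
SNP and oncogene enrichments per cluster; an expression table with a
planted unexpressed fraction; decoy loops (promoter–promoter pairs and
insignificant q-values) to exercise classification and the q filter.

Default scale: 200 promoters, 2 chromosomes (+1 carrying the protein gene
models), ~3 enhancers per promoter at 20–600 kb, 800 proteins, ~5000 PPI
edges, read depth 300 (mean 1-kb pair count at 20 kb — sized so a called
loop carries a di-tag total in the hundreds, as FDR < 0.01 calls do). The
full pipeline on this default runs in ~1–2 minutes on one CPU; the smaller
fixtures used throughout the tests use 25–40 promoters.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: actual sequence content or motif PWMs (hits are
planted, not scanned), GC/mappability structure behind the biases
(lognormal is an idealization), overdispersion beyond Poisson, shared
enhancers with conflicting multi-promoter signals, translocations or
inter-chromosomal contacts, and the incompleteness/ascertainment biases of
real PPI databases.

## Numerical conventions collected

- Fisher p-values: scipy's two-sided exact sum; odds ratio ad/bc.
- Empirical p-values: +1-corrected, in (0, 1].
- SLSQP: ftol 1e-12, max 150 iterations per window, analytic gradients.
- β floor 1e-3; E(d) floored at d = 1 bp when evaluated.
- All randomized procedures take explicit integer seeds; pipeline stages
  derive per-protein seeds as documented offsets from the run seed.
- Determinism: rerunning any stage on unchanged inputs reproduces its
  output files byte-identically (timestamps live only in run metadata).

## Known limitations

- The per-window system estimates 5 effective parameters from 9 cells;
  at mean counts below ~20 the bias estimates are noise-dominated, and
  bias recovery degrades accordingly (the unweighted least-squares
  objective follows the model definition; a Poisson-weighted variant
  would behave better at low counts but is not what the window system
  specifies).
- The prioritization rule (fraction-of-max, f = 0.8) is one reasonable
  reading of "most interacting"; results downstream of prioritization
  depend on it, which is why it is exposed in config.
- Branch enrichment reports raw p-values by design; with many branches
  the expected number of sub-α branches under the null is not small.
- Cluster-robustness assessment (e.g. Monte-Carlo significance of the
  dendrogram partitions) is out of scope; merge heights are exported so
  external tools can be applied.
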