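# Methods

## Model and estimator

Each analysed 3′UTR is assumed to express at most two isoforms: a short
one ending at an unannotated proximal PAS at offset `P` from the UTR 5′
end, and a long one spanning the full annotated UTR. Expected per-base
coverage is therefore a two-segment step, `w_short + w_long` before `P`
and `w_long` after. For a fixed `P` the least-squares solution is
closed-form: `w_long` is the mean of the distal segment and `w_short` the
mean of the proximal segment minus `w_long`, clamped at zero (abundances
cannot be negative; when the clamp binds, proximal residuals are
recomputed against `w_long` alone). The breakpoint is selected by
exhaustive search over candidates `margin ≤ P ≤ L − margin` (stride 1 nt),
minimising the residual sum of squares **summed over all samples of both
conditions**: a single shared breakpoint is what makes per-sample PDUIs,
and hence ΔPDUI, comparable. Residuals are weighted equally across bases
and samples; whether depth-weighting the joint fit would help is an open
modelling question we resolved in favour of the simplest estimator.
Candidate evaluation uses prefix sums (O(L) per sample per gene) and is
verified in the tests to agree exactly with direct per-candidate
evaluation.

Ties in the residual are broken toward the smallest `P` so output is
deterministic; for exactly flat coverage the fit therefore reports
`P = margin` with `w_short = 0` and PDUI 1.

### Distal end-zone exclusion

Real (and simulated) coverage decays over the final fragment length of a
transcript, because a read must end before the cleavage site. The
two-segment model has no step at the distal terminus to absorb that ramp,
and if it is left in, near-uniform (high-PDUI) genes get their breakpoint
dragged to the most distal candidate and PDUI collapses toward the ramp
ratio (~0.5). `pdui_table` therefore trims `end_trim` bases (default: the
search margin, 100 nt) from the 3′ end of every coverage array before
fitting, capped so at least `2·margin + 1` bases remain. This is a
deliberate departure from fitting the distal segment over the full `[P, L)`
window: the trimmed zone is exactly the cleavage-proximal region where the
step model is misspecified. `fit_breakpoint` itself is unmodified, so the
exactness and oracle-equivalence guarantees apply to whatever array it is
given.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `margin` | 100 nt | candidate breakpoints excluded this close to either UTR end; prevents degenerate segments |
| `end_trim` | = margin | distal bases excluded from the fit (see above) |
| `stride` | 1 nt | candidate spacing |
| `min_utr_length` | 150 nt | shorter extracted UTRs are skipped at annotation time |
| `min_mean_coverage` | 15 (per-million units) | expression filter, required in **every** sample |
| `delta_threshold` | 0.1 | inclusive |ΔPDUI| cutoff for a call |
| `alpha` | 0.05 | significance level on q (or raw p) |
| `p_mode` | `fdr` | `fdr` = BH-adjusted q; `raw` for small designs (e.g. few-donor tissue data) |

The expression filter applies to depth-normalised coverage
(reads-per-million via the externally supplied total mapped-read count);
PDUI itself is a within-sample ratio and is provably invariant to that
scaling (property-tested). Requiring the threshold in every sample, rather
than on the mean of means, prevents fitting a breakpoint to a sample with
no signal.

## Annotation extraction

3′UTRs are derived per gene from BED12 (or GTF) transcript models: the
transcript with the distal-most end defines both the distal end and the
CDS 3′ boundary, and the UTR spans between them. Coordinates are 0-based
half-open throughout (BED convention); GTF is converted at the reader
boundary. Regions overlapping an *exon* of another gene are flagged
`masked` (intronic overlap does not confound exonic coverage and is
ignored). Genes whose transcripts disagree on chromosome or strand are
skipped with a logged reason. Genes with multiple alternative last exons
are analysed on the distal-most last exon only — a known limitation;
isoform-aware extraction would require splice-graph analysis that is out
of scope.

## Per-gene test

No single canonical test exists for replicate-level PDUI differences.
With ≥2 replicates per group we use Welch's two-sample t-test on
per-sample PDUIs (zero-variance identical groups return p = 1); with a
single replicate in either group we fall back to a two-sided Fisher exact
test on the 2×2 table of rounded long/short read mass (weight × segment
length) pooled per group. This choice materially affects gene counts on
real data and is surfaced here deliberately. BH adjustment is the
standard step-up, written explicitly and cross-checked against
statsmodels in the tests.

Reported percentages (direction and binding summaries) are rounded
half-away-from-zero to one decimal, so boundary cases such as 51.25 and
16.25 print as 51.3 and 16.3.

## Binding-site integration

Binding assignment is at gene level: a gene is `utr3` if any site shares
≥1 base with its 3′UTR region, else `other_region` if a site overlaps the
gene body, else `none`. The signed distance from a site to the distal PAS
is the nearest-edge distance, negative transcript-5′ of the PAS, zero on
overlap; `|d| ≤ 75 nt` sets the proximity flag (the repressive window for
position-dependent RBP regulation of PAS usage). Overlap and
over-representation tests are exact hypergeometric upper tails
(scipy's log-space survival function, verified against rational
enumeration to ≤1e−12 for universes up to 25). The universe must be given
explicitly — e.g. all genes passing the expression filter — because
defaulting it silently would fabricate significance.

## Synthetic data

The generator emulates the two-isoform structure the estimator assumes:
per condition, expected short/long read counts are proportional to
`(1 − PDUI)` and `PDUI`, reads of fixed length start uniformly along their
isoform (with an upstream flank so coverage at the UTR 5′ end is full),
and counts are Poisson (negative binomial when `dispersion > 0`, variance
`μ(1 + αμ)`). Coverage is the per-base pileup, so the drop at the true
breakpoint is a ramp over ~one read length — recovery tolerances are tied
to the read length for that reason — and coverage also ramps down over
the final read length of each isoform, which is what motivates the
end-zone exclusion above.

Defaults describe the study design the pipeline targets: 3 vs 3
replicates, 100× 5′-end coverage, 100-nt reads, UTR lengths 800–2000 nt
with the true breakpoint ≥200 nt from either end, a 60/30/10 mixture of
null / lengthened (+0.3) / shortened (−0.3) genes, and binding sites
placed within 75 nt upstream of the distal PAS for half the lengthened
genes (repressive geometry). Baseline PDUIs are drawn uniformly at a
distance from the boundaries such that adding the effect never needs
clipping, so true ΔPDUI is exactly ±0.3 for non-null genes. Simulated
library sizes are written as exactly one million reads, so the per-million
depth factor is 1 and synthetic coverage is already in normalised units.
One global seed expands into per-gene Philox substreams keyed by a CRC of
the gene id, making subsets reproducible regardless of iteration order
and dataset writes byte-identical.

What the generator does **not** model: positional/GC bias, splicing and
intronic PAS, >2 isoforms, multimapping, or annotation error. Passing
recovery tests on this generator therefore demonstrates correctness of
the estimator under its own assumptions, not robustness to those
real-data complications.

## Problem sizes and numerics

The test suite and the reproduction script use 100 genes for parameter
recovery, 500 for null error control, 200 for the mixed end-to-end run,
and 100 random UTRs (≤500 nt) for oracle equivalence — sizes at which the
Monte-Carlo targets (median errors, false-positive and sign-consistency
rates) are stable across seeds while a full run stays in the seconds
range. Residual sums are clipped at zero against floating-point
cancellation; breakpoint ties resolve to the first (most proximal)
candidate via the argmin convention; hypergeometric p-values are clamped
to (0, 1].

## Known limitations

* Single breakpoint per UTR: genes with ≥3 PAS are summarised by the best
  two-segment approximation.
* The per-gene test is a package choice (see above); analyses using a
  different test will produce different gene counts at the same
  thresholds.
* Binding analysis is interval-based at gene level; no motif or summit
  resolution.
* The distal end-zone exclusion assumes the annotated distal end is the
  true dominant cleavage site to within about one read length.
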