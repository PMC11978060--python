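# Methods

This note records the model behind `promdyn`, the choices made where the
procedure was genuinely open, and what the synthetic studies used by the
tests do and do not demonstrate.

## Promoter model

A promoter is operationalized as a group of transcripts of one gene
whose first exons overlap by at least one base, closed under
single-linkage merging. This is a parameter-free surrogate for
"identical or very close TSSs": no distance threshold needs to be
chosen, and two first exons that share sequence almost certainly share
regulatory context. The promoter's TSS is the 5′-most member TSS
(minimum first-exon start on `+`, maximum first-exon end on `-`), and
`tss_rank` numbers promoters 1..K in transcription order.

The internal-promoter test is restricted to non-first exons *of the same
gene*: a first exon that overlaps an internal exon of a sibling isoform
produces junction reads indistinguishable from splicing of that isoform,
so such promoters are flagged and excluded from quantification.
Cross-gene overlaps are ignored — they are handled instead at the
junction level, where any junction claimed by more than one promoter
(same gene or not) is discarded as non-unique. Coordinates are 1-based
inclusive internally (GTF convention); only the BED export converts to
0-based half-open.

Genes whose transcripts are all mono-exonic have no first-intron
junction; their promoters are retained in the catalog but flagged
non-quantifiable and carry missing values (never zeros) downstream, so
"no data" and "no expression" stay distinguishable.

## Quantification and normalization

Only *unique* junction reads over *promoter-unique* first-intron
junctions are counted; multi-mapping reads and junctions absent from the
catalog are ignored (the analysis is annotation-driven). Undefined
strand in the input (STAR code 0) is resolved only when exactly one
catalog strand matches the coordinates; otherwise the record is dropped
with a warning. Junctions shared between promoters are excluded from
all of them rather than split fractionally — splitting would require an
allocation model that nothing in the data constrains.

Size factors are median-of-ratios (the DESeq2 estimator) computed on the
promoter count matrix itself: the reference is the per-promoter
geometric mean over samples, promoters with any zero or missing count
are excluded from the reference set, and each sample's factor is the
median ratio to the reference. Note the estimator is self-referential:
scaling one sample's counts by *c* changes its factor by *c* only
relative to the other samples (the geometric-mean reference absorbs
c^(1/m)); with tens of samples the absolute effect on log activities is
well under 1%.

Absolute activity uses `log2(x + 1)`; the pseudocount makes zero counts
map to zero activity. Gene expression is `log2(1 + sum of normalized
linear counts)` over the gene's quantifiable promoters — summing on the
linear scale, not summing log activities, because a sum of logarithms is
not an expression total. Relative activity divides each promoter's
normalized linear count by that linear gene total and is undefined
(missing) where the total is zero.

## Classification thresholds

Mean absolute activity is taken over *all* samples of the dataset. The
gene's top promoter is major provided its mean is at least the
inactivity threshold 0.25 (log2 scale; i.e. roughly 0.19 normalized
reads); means strictly below 0.25 are inactive; a mean of exactly 0.25
is active. Ties at the maximum break toward the 5′-most promoter — a
deterministic, biologically neutral rule that matters only for
degenerate (typically synthetic) data. "Multi-active" genes are those
with ≥ 2 active promoters whose mean relative contribution each exceeds
10%.

## Dynamic-promoter screen

Ordinal stage index is used as the time axis and standardized to zero
mean and unit variance before polynomial expansion; conditioning is the
only reason, and the fit is invariant to affine rescaling of the axis
(tested). The model is ordinary least squares of activity on
{1, t, t², t³}; significance is the F-test of the full cubic against the
intercept-only model; Benjamini–Hochberg FDR is applied across all
fitted promoters of an organ; and a promoter is a DDP iff q ≤ α
(default 0.05) **and** R² ≥ 0.3. Both gates are exposed separately in
configuration. This is a deliberate reduction of the maSigPro two-step
procedure: the stepwise term-selection stage selects *which* polynomial
terms matter, but the acceptance rule here is goodness of fit of the
full cubic, so the stepwise stage would only change coefficients, not
calls, and is omitted.

Promoters observed in fewer than 70% of an organ's samples, or with
fewer than 4 distinct time points after dropping missing values, are
skipped with the reason recorded — never silently treated as flat
evidence.

Trend direction is the sign of fitted(t_last) − fitted(t_first) for
DDPs, Flat otherwise; a dynamic but symmetric (hump-shaped) promoter is
therefore directionless (Flat) by construction. The eight pair
categories are a pure function of (major trend, minor trend); the
gene-level trend is computed with the same screen applied to gene
expression and carried along with a consistency flag, but an incoherent
combination (e.g. gene Down with both promoters Up) is reported, not
reassigned.

Bootstrap trajectory bands resample *promoters* (not samples) with
replacement, 1,000 times by default, and take the 2.5–97.5 percentile
range of the per-stage resampled means. DDP-vs-flat activity
comparisons use per-promoter max / mean / median over stage means and a
two-sided Wilcoxon rank-sum (Mann–Whitney U) test per metric.

## Cross-organ comparison

DDPs are matched across organs by *gene* identifier. A gene dynamic in
≥ 2 organs is common; in exactly one, organ-specific; dynamic only in
the related-organ group {brain, cerebellum} (configurable), set aside as
`excluded_pair`. A gene dynamic in brain, cerebellum *and* a third
organ is common (the exclusion applies only to the exact pair).

## Synthetic-data generator

The generator emulates a multi-organ developmental bulk RNA-seq design
at desk scale. Defaults, chosen once as the study conditions:

| parameter | default | meaning |
|---|---|---|
| stages × replicates | 16 × 2 | prenatal + postnatal ordinal design |
| organs | heart, liver | two independent organ series |
| n_genes | 150 | plus optional shared-junction gene pairs |
| promoters/gene | 1–4, P = (.76, .15, .06, .03) | ≈ 24% multi-promoter genes |
| baseline mean | 100 reads (major), ×0.3 (minor) | expected unique junction reads |
| dispersion | 0.05 | NB: var = μ + 0.05 μ² |
| effect size | 2.0 log2 units | end-to-end swing of planted trajectories |
| size factors | 2^U(−1, 1) | 4× depth range |
| dynamic fraction | 0.5 | genes with a planted non-flat pattern |

Expected counts follow `size_factor × baseline × 2^c(u)` with `c` a
cubic in normalized time drawn from a small library (flat, up, down,
hump); counts are negative binomial and are split across a promoter's
junctions with fixed proportions. The planted major promoter is the
5′-most with probability 0.75, mirroring the observation that roughly a
quarter of dominant promoters sit downstream of the first TSS. Planted
(major, minor) patterns are drawn from a configurable mix over the
eight categories. Internal promoters, cross-gene shared junctions,
undefined-strand records, novel junctions and near-silent minors are
planted to exercise every exclusion rule.

What the generator does **not** emulate: real exon structure and
sequence, GC/length biases, multi-mapping ambiguity, batch effects,
cell-composition shifts within organs, non-cubic temporal shapes, and
correlated noise between promoters of one gene. Passing tests therefore
demonstrate algorithmic correctness and calibration under the stated
noise model, not performance on real tissue data.

## Problem sizes and numerical choices

The test suite and `scripts/acceptance.py` use: a 40-gene study for the
exact counting oracle; 600 stable genes for size-factor recovery
(median-of-ratios recovery is defined under its majority-unchanged
assumption, so the recovery study plants flat trajectories; planted
factors are compared after normalizing both sides to unit geometric
mean, the scale on which the estimator is identifiable); 500 promoters
for the least-squares oracle (agreement to 1e-8 with an independent
normal-equations solve); 5 × 2,000 stable promoters for false-positive
control; and 160 two-promoter genes with the planted category mix for
pattern recovery. Degenerate inputs: a constant time course gets R² = 0,
zero slope coefficients and p = 1; a perfect fit gets p = 0; relative
activities within a gene-sample sum to 1 ± 1e-9 whenever the gene is
expressed. All randomness flows from explicit integer seeds; integer
outputs are bit-reproducible and the end-to-end pipeline reproduces
byte-identical tables across runs.

## Known limitations

- Promoter activity from junction reads cannot see promoters of
  mono-exonic transcripts, and shared first introns silence otherwise
  distinct promoters; both are reported as missing rather than guessed.
- The cubic screen has limited power for sharp, short-lived pulses
  confined to one or two stages.
- Cross-organ labels compare gene sets only; a gene can be "common"
  through *different* promoters in different organs (a promoter-level
  mode is available on the cross-organ API).
- The 0.25 activity cutoff and the R² ≥ 0.3 gate are fixed conventions
  of the method, exposed in configuration but not auto-calibrated.
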