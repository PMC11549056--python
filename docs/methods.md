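# Methods

## Quantification

Guide abundance is normalized as reads per million with the pseudocount
added **after** scaling (`count / colsum × 1e6 + 1`), so a zero count maps
to exactly 1 RPM. Replicate RPMs are averaged within condition and baseline
before the log ratio ("average-first"); the mean of per-replicate log
ratios is deliberately not used — for replicate RPMs {101, 303} against a
baseline of 101 the average-first value is 1.0 while the mean of ratios is
≈0.79, and the average-first convention is the one the z-score thresholds
were calibrated against. Per-replicate fold changes are retained for the
replicate-level hit criteria: each condition replicate is paired with the
replicate-matched baseline sample when the two arms have the same replicate
structure, otherwise with the baseline average (the plasmid library is a
single sample, so drug- and control-arm replicates are each compared with
it directly).

z-scores standardize L2FC over **all** QC-retained guides of a comparison,
targeting and controls alike; the control guides anchor the null.
The standard deviation is the sample sd (ddof = 1) — at library scale the
distinction from the population sd is negligible, but fixing it makes runs
reproducible to the last bit. Per-replicate z-scores are standardized by
that replicate's own mean and sd. The default baseline is the plasmid
library; a time-zero baseline is selectable.

QC flags: `multi_mapping` for more than two perfect genomic matches
(consumed as annotation, not recomputed); `low_count` for fewer than 100
raw reads in the plasmid or any time-zero sample; `replicate_discordant`
for a ≥10-fold raw-count difference between replicates of an arm, computed
as (max+1)/(min+1) to guard zero denominators, flagged at exactly tenfold.
The replicate rule is off by default and enabled per cell-line profile.
Flagged guides are excluded from standardization and classification rather
than labeled control.

## Variant classes

All threshold inequalities are strict (z > 2, not ≥). Drug addiction and
driver have disjoint control-arm conditions, so precedence between them
cannot arise; canonical resistance is explicitly the residual hit class.
A sensitizing call additionally requires the control arm to be *not*
depleted (z > −2, every replicate > −1), which separates drug-specific
sensitization from general essentiality — essential-splice controls deplete
in both arms and therefore classify as control, not sensitizing.

The secondary significance gate uses the empirical control-guide null
(nontargeting + intergenic + nonessential-splice categories): one-sided
p = (r+1)/(n_ctrl+1) where r counts control z-scores at least as extreme in
the tested direction, with Benjamini–Hochberg FDR across targeting guides
per direction, applied at P < 0.05 and FDR < 0.1. A rank-based permutation
statistic over an explicit control distribution was chosen over
re-implementing an RRA-style aggregator because guides are interpreted
individually here (no gene-level aggregation), making the control-null
rank test the natural significance measure. The gate applies to resistance
and sensitizing hits alike (`gate="resistance"` restricts it); it requires
at least 30 retained control guides and is skipped (`gate="auto"`) on
small synthetic libraries whose proportionally scaled control set is below
that minimum.

## Consequence prediction

Editor chemistry is C→T (CBE) or A→G (ABE) inside a configurable window,
default protospacer positions 4–9 inclusive, position 1 PAM-distal. Target
sites are located by exact protospacer match plus an IUPAC PAM (default
NGN) on either strand; zero matches or more than one match are hard errors.
The default reported allele is the **max-edit allele** — every editable
window base converted simultaneously — because high-efficiency editing
drives most alleles to completion (the synthetic amplicon panel's planted
VAF profile has median ≈0.92), and combined labels such as `P2L/R3C` are
the informative ones; `enumerate_alleles` provides all 2^k − 1 partial
outcomes (refusing k > 8 without an explicit override), deduplicated by
consequence.

Consequences are computed by mutating the locus, re-splicing and
re-translating the CDS, then diffing proteins; the report truncates at the
first gained stop. Class precedence: splice (canonical 2-bp GT donor / AG
acceptor dinucleotides only — deeper splice modeling is out of scope) >
start-lost > stop-gained > missense > synonymous > UTR > intronic. A
wild-type genome is assumed; cell-line-specific SNVs are not modeled.
Internal coordinates are 0-based half-open; protein and VCF coordinates are
1-based.

## Amplicon verification

Variants pass at depth > 1,000 **and** VAF > 0.1, both strict. Any variant
whose exact (pos, ref, alt) also passes those filters in the matched
unedited sample is background (pre-existing in the cell line) and removed
outright — no VAF-difference modeling. Passing SNVs on one amplicon are
phased as co-occurring (single-clone assumption) and translated jointly;
per-variant solo consequences are always reported alongside, so the
phasing assumption is auditable. A guide is `verified_nonsynonymous` when
at least one passing variant is nonsynonymous (missense, stop-gained,
start-lost or splice). The efficiency summary's median VAF is computed over
in-window passing variants only. VAF is treated per nucleotide variant.
Indels are annotated and skipped.

## Perturb-seq scores

Energy distance between two cell populations uses the V-statistic
estimator: E = 2·mean‖x−y‖ − mean‖x−x′‖ − mean‖y−y′‖ with all-ordered-pair
means (within-sample diagonals contribute zero). The V-statistic is used
because it is non-negative and exactly zero on identical samples, which the
distinct-pair U-statistic is not; a singleton sample's within-term is zero
either way. The normalized coefficient E/(2·mean‖x−y‖) is scale-free in
[0, 1] and is what the impact ranking sorts on (rank 1 = largest; guides
under 20 cells excluded). Expression is consumed already log-normalized;
cycle-phase labels and DE signatures are inputs (the bundled
mean-difference signature builder is for synthetic data only).

Cell-cycle shifts use a Pearson chi-squared on the 2 × 3 group × phase
contingency without continuity correction; phases absent from both groups
are dropped with the degrees of freedom adjusted. The PFS outcome score is
the Spearman correlation (ties mid-ranked) between a variant's signature
and the responder reference over their shared genes (≥10 required;
constant vectors are errors, not NaNs), with per-class two-sided Wilcoxon
rank-sum tests against NT guides. Both reference orientations are
supported (`--flip-reference`) since responder conventions differ.

## Resistance map

Rows are amplicon-verified protein variants keyed gene + consequence;
columns are screened drugs; cells carry the variant class, with `untested`
explicit. Multiple guides installing one variant are merged by majority
class, ties broken by strongest |z_drug|, and every disagreement is
recorded rather than silently overwritten. Alternative-therapy suggestions
list drugs whose cell is sensitizing (first) or control; rows containing a
drug-addiction cell are flagged as drug-holiday candidates. Concordance
with a curated list matches at amino-acid-position granularity by default
(curated substitutions rarely match the multi-edit alleles exactly;
`exact_substitution` tightens this), and reports two denominators because
the fair one is ambiguous: all curated entries, and only those reachable by
the screen (gene screened at that position, drug in the panel) — the
reachable-space fraction is the headline.

## Synthetic data

`simulate_screen` emulates the study design: a 2,000-guide library by
default (full-scale profile 22,816) whose control categories — 57
nontargeting, 168 intergenic, 87 nonessential-splice, 316 essential-splice
at full scale — are scaled proportionally; a single plasmid sample, and
time-zero/control/drug arms with two replicates each. Plasmid counts are
negative binomial with mean 500 and dispersion 0.1 (var = μ + 0.1μ², the
field-standard overdispersion for pooled screens); each arm count is NB
around the guide's **observed plasmid count** times 2^(planted L2FC), so
cells inherit the actual pool composition and library-representation noise
cancels from fold changes. Planted effects (L2FC drug/control): addiction
(+3, −3), canonical (+3, 0), driver (+3, +3), sensitizing (−3, 0),
essential-splice (−3, −3); planted counts default 10/30/24/111. Planted QC
failures (20 multi-mapping, 10 low-count via plasmid mean 30, 10
replicate-discordant via 20-fold down-sampling of one control replicate —
modest counts chosen to exercise each filter without distorting the score
distributions). Generators are pure functions of the config; identical
seeds give bitwise-identical output, and truth tables carry everything
needed for downstream confusion matrices.

`simulate_genotyping` builds 45 guides on random toy transcripts whose
max-edit allele is missense, plants in-window SNVs at Beta(8, 1) VAFs
(median ≈0.92, the high-efficiency profile) and Poisson(5,000) depths, two
failures (one low-depth, one low-VAF) and three background variants
duplicated into the unedited table. `simulate_perturbseq` draws Gaussian
log-expression over 200 genes with class-specific shifts on two disjoint
40-gene pathway-proxy blocks (MAPK-proxy +1 for resistance classes, +2 for
addiction; JAK-proxy −1.5 for addiction), S-phase-enriched cycle
multinomials for resistant classes (G1/S/G2M 0.40/0.45/0.15 vs
0.60/0.25/0.15), and a responder reference signature (MAPK-proxy −1,
JAK-proxy +0.5, small noise off the blocks to break rank ties).

What the generators do **not** model: guide-level biological heterogeneity
among "null" targeting guides (real tiling libraries contain many variants
of small real effect, which widens the z denominator relative to counting
noise), editing-efficiency heterogeneity across positions, raw reads, and
single-cell count-level noise (expression is generated on the normalized
scale). Passing tests therefore demonstrate the arithmetic and the
decision logic under the stated noise model, not performance on real
screens.

## Known limitations

- Under the default synthetic conditions the strict per-replicate
  control-arm criterion intrinsically rejects ~13% of true sensitizing
  guides: a null-behaving control arm has per-replicate z noise sd ≈0.68
  (counting noise relative to a spread only mildly inflated by planted
  effects), so each replicate falls below −1 with probability ≈7.5%.
  Measured pooled recovery over ten seeds is ≈87% for sensitizing versus
  100% for the other three classes, with 0% null false hits and zero
  control contamination. On real data the guide-to-guide spread is
  dominated by genuine biological effects, shrinking that noise ratio; the
  synthetic null understates it by construction (see above).
- Gene-level aggregation is out of scope; guides are interpreted
  individually.
- The concordance benchmark depends on a curated list the user supplies;
  no database retrieval is included.

## Problem sizes

The test suite and `scripts/acceptance.py` run 2,000-guide screens over a
ten-seed sweep, a 45-guide genotyping panel, 1,000 random toy transcripts
for the consequence-prediction oracle, and 2,500-cell perturb-seq
matrices — sizes chosen so every stage's statistical behavior is measurable
while the whole suite completes in well under a minute on one CPU.
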