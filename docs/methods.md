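# Methods

## Scope and data model

`panelfrag` operates on fragment-level cfDNA data: one BED interval per
sequenced fragment (0-based, half-open coordinates throughout, the bedtools
convention). Upstream concerns — alignment, UMI deduplication, variant
calling, ctDNA-fraction estimation from variants — are out of scope; fragment
records and per-sample tumor fractions are inputs. Retained fragments are
those with length in [20, 500] bp; both bounds are inclusive by default (the
boundary convention is a flag, `filter_by_length(..., inclusive=)`), and the
per-sample `total_reads` denominator used by normalized depth counts the
fragments that survive this filter, not raw reads.

## Region systems

* **Panel exons** carry gene symbol, transcript-order exon rank and a coding
  flag. Each gene's E1 window is its rank-1 coding exon or, when that exon is
  not on the panel, the *lowest-ranked* coding exon present. Rank order (not
  genomic distance) defines "closest": the E1 signal is motivated by
  TSS-proximal coverage, and transcript order is the natural metric for it.
  This is an interpretation; genes with no coding exon are dropped from E1
  features with a warning.
* **TFBS** records carry an experimental-support count. Per TF the `top_n`
  best-supported sites are kept (default 5000 at full scale; toy collections
  use smaller quotas) and TFs that cannot fill the quota are discarded. Ties
  at the quota boundary break deterministically by (support desc, chrom,
  start asc); the original procedure does not specify a tie rule.
* **Open chromatin** is one interval set per cancer type (23 types at full
  scale).

Overlap assignment requires ≥ 1 bp by default, and a fragment overlapping
several regions is used for every one of them. Within a pooled region set
(one TF's sites, one cancer type's regions) a fragment overlapping k regions
contributes k observations to the pooled length distribution, consistent with
the per-region rule.

## Metrics

Entropies are plug-in (maximum-likelihood) estimates in natural log — the
default of the R package the procedure references — with no small-sample bias
correction; the choice is recorded in table metadata. The motif diversity
score normalizes by ln 256, making it base-free. MDS pools 5' and 3' motifs
into a single count vector over the 256 4-mer motifs (a per-end mode exists
but is off by default). The 3' motif is read as the reverse complement of the
last four reference bases — the end-motif literature's convention of reading
into the fragment — with a plus-strand-literal mode available, since a
strand-unaware FASTA lookup yields the plus strand; neither is asserted to be
the original study's choice. Fragments with an ambiguous base (N) in a motif
window are excluded from motif counts.

Size-bin boundaries are read literally from the printed ranges (0–100,
101–150, 151–200, 201–250, 251–300, >300): integer lengths, upper edge
inclusive. The small-fragment rule is length ≤ 150.

Full-gene depth counts *distinct* fragments over the gene's exons (a
fragment spanning two exons counts once); per-exon double counting is
available via `count_once=False`. Whether the original procedure counted
once or twice is not stated.

Missing values arise where a region has no fragments: depth is then a true
zero, while an entropy/MDS/bin value is undefined. Imputation therefore fills
depth metrics with 0 and everything else with the per-feature median. Inside
cross-validation the medians come from training folds only (tables are
assembled un-imputed and the fold model imputes); cohort-level imputation is
available for standalone tables.

## Synthetic cohorts

No generative model exists in the source material (it analyzed sequenced
cohorts), so the simulator's distributions are stand-ins with the *structure*
the metrics respond to:

* fragment lengths from a truncated-normal mixture on [20, 500] with
  components short N(110, 15), mononucleosome N(167, 15), dinucleosome
  N(330, 30); healthy weights (0.08, 0.82, 0.10), cancer (0.25, 0.65, 0.10) —
  the mononucleosome mode dominates and tumor DNA is short-enriched;
* per-exon placement probability ∝ depth multiplier × exon length, with 10%
  of fragments placed uniformly off-target (so overlap filtering is
  exercised); placement jitters fragments around the chosen exon with ≥ 1 bp
  overlap guaranteed;
* end motifs drawn per fragment from a sample-level motif distribution, one
  Dirichlet draw per sample per origin (concentration 500 over 256 motifs;
  healthy uniform, cancer geometrically tilted with tilt 2.0, lowering its
  expected MDS). Motifs are generated directly on the fragments by default; a
  mode that leaves motifs to FASTA extraction exists for integration tests;
* sample-level tumor fraction: each fragment originates from the tumor
  process with probability equal to the sample's tumor fraction, otherwise
  from the healthy process. Healthy samples are fixed at 0.

Determinism: per-sample seeds are `SeedSequence([config_seed, sample_index])`
(a stable, documented hash), so any sample can be regenerated without the
cohort. The toy genome defaults to 6 genes × 2–3 exons of 120–200 bp on a
40 kb chromosome, 10 000 reads per sample.

What the generator does **not** model: sequencing error, GC bias, UMI
structure, mappability, inter-individual germline variation, realistic
linkage between depth, length and motif signals, or biological covariance
across exons. Passing tests on these cohorts demonstrate the *pipeline's*
correctness and statistical calibration, not expected performance on real
plasma data.

## Mixing design

Low-fraction specimens are emulated by uniform down-sampling without
replacement (the behavior of shuffling a fragment list and taking n lines)
and concatenation at healthy:partner ratios 50:50, 75:25, 90:10, 95:5, 99:1.
The partner share is `round(total · proportion)` with the healthy share
absorbing the rounding, so totals are exact to the fragment. Controls are
*ordered* healthy pairs without self-pairing — the only reading consistent
with the published |H|·(|H|−1)·|ratios| counts. A mixture's calculated ctDNA
fraction is (partner tumor fraction) × (partner read share); mixtures bin
into log decades [1e-4, 1e-3), [1e-3, 1e-2), [1e-2, 1e-1), [1e-1, 1], with
fractions below 1e-4 labelled sub-detection and excluded from binned
summaries. The two outer bins are named in the source text; the log-decade
partition of the interior is inferred. Total reads per mixture is a
parameter: the published experiment used 100 M, desk-scale runs here use
10 000.

## Evaluation protocol

Stratified 10-fold outer CV (stratification is not stated in the source but
small classes make unstratified folds degenerate), repeated 25 times; one
fold assignment per repeat shared across all metric tables. Hyperparameters
(α ∈ [0, 1]; λ ∈ [1e-4, 10] on a log scale — the original sampling ranges are
not printed) come from a 10-point Latin-hypercube sample evaluated by 5-fold
inner CV on the training fold, scored by macro-averaged one-vs-rest AUROC
(the multiclass reduction is likewise unstated; ties break toward smaller λ,
then smaller α). Minority classes are up-sampled with replacement to the
majority count inside training data only. Out-of-fold class probabilities
are pooled per repeat and reduced to a one-vs-rest AUROC per phenotype
(Mann–Whitney form, ties counting ½); medians over repeats are reported, and
commercial-panel comparisons report the median difference (subset minus full
panel).

The classifier is scikit-learn's saga solver with `C = 1/(N·λ)` and
`l1_ratio = α`, which reproduces the glmnet objective with unpenalized
intercepts; features are median-imputed and z-scored with training-fold
statistics. Numerical choices: candidate ranking inside the inner CV runs
the solver at max_iter 80 / tol 1e-2 (ranking is insensitive to trailing
digits), the winner is refit at max_iter 200 / tol 1e-3. At extreme λ the
saga solver leaves the unpenalized intercept short of the exact
class-frequency log-odds (a one-epoch stop on an intercept-only model); this
regime never wins model selection and does not affect rank-based scoring.

The dilution experiment follows the published design: donors are split
70/30 into training and validation pools *before* any mixing, every
within-pool combination is mixed at the five ratios, an elastic net is tuned
by nested CV on the training mixtures, refit, and scored once on the
validation mixtures, with AUROC computed per calculated-fraction bin
(positives: cancer mixtures in the bin; negatives: all validation controls).

## Calibration design

The null check re-simulates an **independent null cohort for each of the 25
repeats** (all phenotypes share the healthy parameters) and runs the full
nested-CV protocol once per cohort. On a single fixed cohort the out-of-fold
AUROC of a tuned classifier concentrates on that cohort's chance multivariate
structure (sd ≈ 0.075 at 60 + 60 samples, measured on iid-noise cohorts), so
refolding one cohort 25 times tests nothing useful; the median over
independent cohorts estimates the protocol's true null score (0.5) with
Monte-Carlo error ≈ 0.02 and is the check implemented here and in
`scripts/acceptance.py`.

## Problem sizes used by the packaged experiments

Chosen once as desk-scale defaults: effect/null cohorts of 2 phenotypes × 60
samples × 10 000 reads on the 6-gene toy panel (effect: multiplier 2.5 on the
first third of exons, 0.4 on the last third); toy region systems of 4 TFs
(quota 8 sites) and 3 ATAC types; dilution donors 8H + 10C training and
4H + 5C validation with 25 000 fragments each and donor tumor fractions
log-spaced over [0.01, 0.9], giving every fraction bin ≥ 12 positive
validation mixtures; 10 000-read mixtures.

## Known limitations

* Synthetic cohorts cannot validate absolute performance claims on real
  cohorts; published AUROCs on clinical datasets are context, not targets.
* The E1 "closest coding exon" rule and the 3'-motif strand convention are
  documented interpretations of under-specified procedure.
* TFBS/ATAC entropies use all sample reads (as described for the original
  panels); on very sparse region sets the pooled distributions are noisy and
  medians dominate summaries.
* GC-content correction is deliberately absent (the metrics are used
  uncorrected), as are Griffin-style site-averaged coverage profiles.
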