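# panelfrag

Fragmentomics analysis of **targeted cfDNA sequencing panels**: feature
extraction from fragment-level cell-free DNA data over panel exons,
transcription-factor binding sites and open-chromatin regions; in silico
dilution of tumor signal by down-sampling and mixing; and phenotype
classification with a penalized multinomial model under a repeated nested
cross-validation protocol.

## The problem

Cell-free DNA (cfDNA) in plasma is fragmented non-randomly: nucleosome
protection leaves a modal fragment length of ~167 bp, tumor-derived DNA is
enriched for shorter fragments, coverage dips where chromatin is open, and
fragment end motifs shift with the nuclease milieu of the tissue of origin.
Clinical cfDNA assays sequence targeted exon panels at high depth for variant
calling — and the very same reads carry this fragmentation signal.
`panelfrag` implements the feature classes needed to exploit it on a targeted
panel, and the simulation and evaluation machinery to study how well they
predict phenotype, down to very low circulating-tumor-DNA (ctDNA) fractions.

## Feature classes

For a sample with `N` retained fragments (20 ≤ length ≤ 500 bp, inclusive) and
a region `r` of size `|r|` bp, with `c_r` fragments overlapping `r` by ≥ 1 bp
(a fragment overlapping several regions counts for each):

* **normalized depth** `d_r = c_r / |r| / N` — per exon, per full gene
  (distinct fragments over all of a gene's exons), and per first coding exon
  (E1; when a gene's first coding exon is absent from the panel, the
  lowest-ranked coding exon present substitutes);
* **fragment-length Shannon entropy** `H = −Σ_l p_l ln p_l` over the observed
  length distribution at each exon (plug-in estimator, nats);
* **size-bin proportions** over 0–100, 101–150, 151–200, 201–250, 251–300
  and >300 bp (six features per exon), and the **small-fragment fraction**
  P(length ≤ 150);
* **motif diversity score** `MDS = H(motifs) / ln 256 ∈ [0, 1]` over the 256
  4-mer end motifs pooled from both fragment ends;
* **TFBS / open-chromatin entropy** — length entropy of all sample fragments
  pooled over each TF's top-5000 best-supported binding sites, or over each
  cancer type's ATAC region set.

That yields 13 metric tables (depth, entropy, MDS, small fragments at all
exons and/or E1, full-gene depth, fragment bins, TFBS entropy, ATAC entropy,
and the combined concatenation).

Classification uses the glmnet-style elastic net: minimize
`−(1/N)·loglik + λ[(1−α)/2‖β‖² + α‖β‖₁]`, with α, λ chosen per training fold
from a Latin-hypercube sample via nested 5-fold inner CV maximizing
one-vs-rest AUROC, minority classes up-sampled inside training folds, and
stratified 10-fold outer CV repeated 25 times with shared fold assignments
across metrics.

## Worked example

No public fragment-level cohort ships with the package; the synthetic module
generates cohorts with the relevant structure (depth multipliers, length
mixtures, motif composition, tumor fraction):

```python
import panelfrag as pf
from panelfrag import synthetic as syn

cfg = syn.effect_cohort_config(seed=7, n_samples_per_phenotype=10)
panel = syn.generate_panel(cfg)
samples, labels = syn.simulate_cohort(cfg, panel)
print(f"panel: {len(panel.genes)} genes, {len(panel.exons)} exons, {panel.total_bp} bp")
tables = pf.compute_feature_tables(
    samples, panel, metrics=["depth_all_exons", "entropy_all_exons"], impute=False
)
res = pf.run_repeated_cv(tables, pf.CVConfig(outer_folds=5, n_repeats=5, master_seed=7))
print(pf.summarize(res).to_string(index=False))
```

prints

```
panel: 6 genes, 15 exons, 2327 bp
           metric phenotype  median_auroc
  depth_all_exons    cancer           1.0
  depth_all_exons   healthy           1.0
entropy_all_exons    cancer           1.0
entropy_all_exons   healthy           1.0
```

The `effect` cohort carries a large copy-number-like depth effect plus the
default short-fragment shift of the cancer phenotype, so both normalized
depth and length entropy separate the classes perfectly; a `null` cohort
(`syn.null_cohort_config`) makes the same call sit at AUROC ≈ 0.5.

A thin CLI mirrors the stages: `panelfrag simulate / features / mix /
evaluate / summarize` (see `panelfrag --help`).

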