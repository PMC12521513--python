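"""Reproducible end-to-end experiment recipes on synthetic cohorts.

Three pre-registered experiments exercise the whole pipeline:

* **depth-effect recovery** — a cohort with a large copy-number-like depth
  effect must be nearly perfectly classifiable from normalized exon depth;
* **null calibration** — with both phenotypes sharing every generative
  parameter, no metric may score away from AUROC 0.5.  Each repeat draws an
  *independent* null cohort and runs the full nested-CV protocol once: the
  median over repeats then estimates the protocol's true null score with
  small Monte-Carlo error, instead of the chance multivariate structure of
  one finite cohort (which dominates when the same cohort is refolded 25
  times);
* **dilution series** — mixtures of cancer and healthy donor reads at the
  five standard ratios, evaluated per calculated-fraction bin: discrimination
  must decay toward 0.5 as the calculated ctDNA fraction drops.

All sample sizes here are desk-scale defaults chosen once; every function is
deterministic given its seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import synthetic as syn
from .evaluate import CVConfig, run_mixture_evaluation, run_repeated_cv
from .metrics import METRIC_NAMES, compute_feature_tables
from .mixing import DEFAULT_RATIOS, enumerate_design, realize_mixture
from .regions import select_tfbs_sites
from .synthetic import HEALTHY, SimulationConfig


def _derive(seed: int, *parts: int) -> int:
    return int(np.random.SeedSequence([seed, *parts]).generate_state(1)[0]) % (2**31)


def _cohort_tables(cfg: SimulationConfig, metrics, tfbs_top_n: int = 8):
    panel = syn.generate_panel(cfg)
    samples, _ = syn.simulate_cohort(cfg, panel)
    tfbs = select_tfbs_sites(syn.generate_tfbs_sites(cfg), top_n=tfbs_top_n)
    atac = syn.generate_atac_regions(cfg)
    return compute_feature_tables(
        samples, panel, tfbs=tfbs, atac=atac, metrics=metrics, impute=False
    )


def depth_effect_recovery(
    seed: int = 0,
    n_repeats: int = 25,
    n_samples_per_phenotype: int = 60,
    metric: str = "depth_all_exons",
) -> pd.DataFrame:
    """Repeated nested-CV AUROC of one metric on the large-depth-effect cohort.

    Returns the per-repeat results; the headline number is the median AUROC,
    expected >= 0.9 for ``depth_all_exons`` under the default effect size.
    """
    cfg = syn.effect_cohort_config(_derive(seed, 1), n_samples_per_phenotype)
    tables = _cohort_tables(cfg, [metric])
    config = CVConfig(n_repeats=n_repeats, master_seed=_derive(seed, 2))
    return run_repeated_cv(tables, config)


def null_calibration(
    seed: int = 0,
    n_repeats: int = 25,
    n_samples_per_phenotype: int = 60,
    metrics=tuple(METRIC_NAMES),
) -> pd.DataFrame:
    """Null AUROC calibration over independently re-simulated cohorts.

    Per repeat: a fresh null cohort (all phenotypes share the healthy
    generative parameters) and one pass of the stratified 10-fold nested-CV
    protocol.  Returns rows (metric, phenotype, repeat, auroc); medians per
    metric should sit at 0.5.
    """
    rows = []
    for r in range(n_repeats):
        cfg = syn.null_cohort_config(_derive(seed, 10, r), n_samples_per_phenotype)
        tables = _cohort_tables(cfg, list(metrics))
        config = CVConfig(n_repeats=1, master_seed=_derive(seed, 11, r))
        res = run_repeated_cv(tables, config)
        res["repeat"] = r
        rows.append(res)
    return pd.concat(rows, ignore_index=True)


def make_dilution_donors(
    seed: int,
    n_train_healthy: int = 8,
    n_train_cancer: int = 10,
    n_val_healthy: int = 4,
    n_val_cancer: int = 5,
    donor_reads: int = 25_000,
    tumor_fraction_range: tuple[float, float] = (0.01, 0.9),
):
    """Simulate the donor pools for the dilution experiment.

    Cancer donors carry known tumor fractions log-spaced over
    ``tumor_fraction_range`` (mimicking a cohort with variant-informed
    fraction estimates): each donor's fragments are generated as a
    tumor/healthy mixture at that fraction, and in silico mixing dilutes the
    tumor content further.
    Returns (donors dict, tumor fraction dict, split id lists, config).
    """
    cfg = SimulationConfig(seed=_derive(seed, 20), reads_per_sample=donor_reads)
    n_exons = len(syn.generate_panel(cfg).exons)
    cfg.depth_multipliers["cancer"] = syn.cna_like_multipliers(n_exons)
    panel = syn.generate_panel(cfg)

    donors: dict[str, object] = {}
    tumor_fractions: dict[str, float] = {}
    splits: dict[str, list[str]] = {
        "train_healthy": [],
        "train_cancer": [],
        "val_healthy": [],
        "val_cancer": [],
    }
    idx = 0
    for group, count, phenotype in (
        ("train_healthy", n_train_healthy, HEALTHY),
        ("val_healthy", n_val_healthy, HEALTHY),
        ("train_cancer", n_train_cancer, "cancer"),
        ("val_cancer", n_val_cancer, "cancer"),
    ):
        tfs = (
            np.geomspace(*tumor_fraction_range, count)
            if phenotype == "cancer"
            else np.zeros(count)
        )
        for k in range(count):
            # each cancer donor's fragments are a tumor/healthy mixture at its
            # own tumor fraction, so diluting its reads by the mixing share
            # scales the true tumor content exactly as the calculated fraction
            sid = f"{group}_{k + 1:02d}"
            s = syn.simulate_sample(
                cfg,
                phenotype,
                tumor_fraction=float(tfs[k]),
                sample_seed=_derive(seed, 21, idx),
                panel=panel,
                sample_id=sid,
            )
            donors[sid] = s.fragments
            tumor_fractions[sid] = float(tfs[k])
            splits[group].append(sid)
            idx += 1
    return donors, tumor_fractions, splits, cfg


def dilution_series_experiment(
    seed: int = 0,
    n_repeats: int = 25,
    total_reads: int = 10_000,
    metric: str = "depth_all_exons",
    **donor_kwargs,
) -> pd.DataFrame:
    """Full in silico dilution experiment on synthetic donors.

    Donors are split into training and validation pools before any mixing;
    each pool is expanded into every healthy x cancer and ordered healthy x
    healthy combination at the five standard ratios.  A healthy-vs-cancer
    elastic net is tuned by nested CV on the training mixtures, scored on the
    validation mixtures, and summarized as AUROC per calculated-fraction bin.
    Returns rows (repeat, fraction_bin, auroc, n_pos).
    """
    donors, tfs, splits, cfg = make_dilution_donors(seed, **donor_kwargs)
    panel = syn.generate_panel(cfg)

    def build(split: str, master: int):
        specs = enumerate_design(
            splits[f"{split}_healthy"],
            splits[f"{split}_cancer"],
            ratios=DEFAULT_RATIOS,
            total_reads=total_reads,
            tumor_fractions={
                k: (tfs[k] if k in splits[f"{split}_cancer"] else 0.0) for k in donors
            },
            master_seed=master,
        )
        mixtures = []
        labels = {}
        fractions = {}
        for spec in specs:
            sf = realize_mixture(spec, donors)
            mixtures.append(sf)
            labels[sf.sample_id] = "cancer" if spec.partner_is_cancer else HEALTHY
            fractions[sf.sample_id] = spec.calculated_fraction
        tables = compute_feature_tables(
            mixtures, panel, labels=labels, metrics=[metric], impute=False
        )
        return tables[metric], pd.Series(fractions)

    train_table, _ = build("train", _derive(seed, 30))
    val_table, val_fractions = build("val", _derive(seed, 31))
    config = CVConfig(n_repeats=n_repeats, master_seed=_derive(seed, 32))
    return run_mixture_evaluation(train_table, val_table, val_fractions, config)


def bin_medians(dilution_results: pd.DataFrame) -> pd.Series:
    """Median AUROC per calculated-fraction bin, highest bin first."""
    from .mixing import FRACTION_BIN_LABELS

    med = dilution_results.groupby("fraction_bin")["auroc"].median()
    order = [b for b in reversed(FRACTION_BIN_LABELS) if b in med.index]
    return med.reindex(order)
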