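"""The 13 fragmentomics feature classes and per-cohort feature tables.

Feature classes (metric names):

================== =========================================================
depth_all_exons     fragment count per exon / exon bp / total sample reads
depth_full_gene     distinct fragments over all exons of a gene, normalized
                    by summed exon bp and total reads
depth_E1            depth_all_exons restricted to each gene's E1 exon
entropy_all_exons   Shannon entropy (nats) of the per-exon fragment-length
                    distribution (plug-in estimator)
entropy_E1          entropy_all_exons restricted to E1
mds_all_exons       motif diversity score: entropy of the pooled 5'+3' 4-mer
                    end-motif counts normalized by log 256, in [0, 1]
mds_E1              mds_all_exons restricted to E1
smallfrag_all_exons per-exon fraction of fragments <= 150 bp
smallfrag_E1        smallfrag_all_exons restricted to E1
fragment_bins       per-exon proportions in size bins 0-100, 101-150,
                    151-200, 201-250, 251-300, >300 bp (6 features per exon)
tfbs_entropy        length entropy of all sample fragments pooled over each
                    TF's binding sites (one feature per TF)
atac_entropy        length entropy pooled over each cancer type's
                    open-chromatin regions (one feature per type)
combined            column-wise concatenation of the 12 tables above
================== =========================================================

E1 tables are column subsets extracted after computation at all exons.  A
fragment overlapping several regions contributes to each of them.  Entropies
use natural logarithms; the MDS normalization makes its base irrelevant.

Regions with no overlapping fragments yield missing values for the
length/motif metrics (an entropy of an empty set is undefined) while depth is
genuinely zero.  The imputation stage fills depth with 0 and everything else
with the per-feature median; inside cross-validation the median must come
from training folds only, so tables can also be assembled un-imputed.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .fragments import (
    MOTIF_INDEX,
    MOTIFS,
    ConfigError,
    GenomicInterval,
    SampleFragments,
    overlap_assign,
)
from .regions import ATACRegionSet, PanelDefinition, TFBSCollection

#: upper edges of the first five fragment-size bins (upper-inclusive)
FRAGMENT_BIN_EDGES = (100, 150, 200, 250, 300)
FRAGMENT_BIN_LABELS = ("0-100", "101-150", "151-200", "201-250", "251-300", "301+")
SMALL_FRAGMENT_MAX_BP = 150

METRIC_NAMES = (
    "depth_all_exons",
    "depth_full_gene",
    "depth_E1",
    "entropy_all_exons",
    "entropy_E1",
    "mds_all_exons",
    "mds_E1",
    "smallfrag_all_exons",
    "smallfrag_E1",
    "fragment_bins",
    "tfbs_entropy",
    "atac_entropy",
    "combined",
)

_DEPTH_METRICS = {"depth_all_exons", "depth_full_gene", "depth_E1"}


@dataclass
class LengthDistribution:
    """Counts of observed fragment lengths at one region (or pooled set)."""

    counts: dict[int, int]

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    @classmethod
    def from_lengths(cls, lengths: Iterable[int]) -> "LengthDistribution":
        return cls(dict(Counter(int(x) for x in lengths)))

    def lengths_array(self) -> np.ndarray:
        return np.repeat(
            np.fromiter(self.counts.keys(), dtype=np.int64, count=len(self.counts)),
            np.fromiter(self.counts.values(), dtype=np.int64, count=len(self.counts)),
        )


# ---------------------------------------------------------------------------
# scalar metrics
# ---------------------------------------------------------------------------

def normalized_depth(assigned_count: int, region_bp: int, total_reads: int) -> float:
    """Fragment count / region size (bp) / total retained sample reads."""
    if region_bp <= 0:
        raise ConfigError(f"region_bp must be positive, got {region_bp}")
    if total_reads <= 0:
        raise ConfigError("sample has no retained reads; depth undefined")
    return assigned_count / region_bp / total_reads


def shannon_entropy(dist: LengthDistribution | Mapping[int, int] | Sequence[int]) -> float:
    """Plug-in Shannon entropy in nats of an empirical count distribution.

    Accepts a :class:`LengthDistribution`, a mapping value->count, or a bare
    count vector.  Returns NaN for an empty distribution (imputed later).
    """
    if isinstance(dist, LengthDistribution):
        counts = np.fromiter(dist.counts.values(), dtype=float)
    elif isinstance(dist, Mapping):
        counts = np.fromiter(dist.values(), dtype=float)
    else:
        counts = np.asarray(dist, dtype=float)
    counts = counts[counts > 0]
    n = counts.sum()
    if n <= 0:
        return float("nan")
    p = counts / n
    return float(-(p * np.log(p)).sum())


def fragment_bin_proportions(
    dist: LengthDistribution | Iterable[int],
) -> np.ndarray:
    """Proportions over the six size bins (0-100, 101-150, ..., >300 bp).

    Bin edges are upper-inclusive on integer lengths: 100 falls in the first
    bin, 101 in the second.  Returns a vector of NaN for an empty input.
    """
    lengths = (
        dist.lengths_array()
        if isinstance(dist, LengthDistribution)
        else np.asarray(list(dist), dtype=np.int64)
    )
    if lengths.size == 0:
        return np.full(6, np.nan)
    idx = np.digitize(lengths, [e + 1 for e in FRAGMENT_BIN_EDGES])
    return np.bincount(idx, minlength=6) / lengths.size


def small_fragment_fraction(dist: LengthDistribution | Iterable[int]) -> float:
    """Fraction of fragments with length <= 150 bp (boundary inclusive)."""
    lengths = (
        dist.lengths_array()
        if isinstance(dist, LengthDistribution)
        else np.asarray(list(dist), dtype=np.int64)
    )
    if lengths.size == 0:
        return float("nan")
    return float((lengths <= SMALL_FRAGMENT_MAX_BP).mean())


def motif_diversity_score(motif_counts: Mapping[str, int] | Sequence[int]) -> float:
    """Normalized entropy of the 4-mer end-motif distribution, in [0, 1].

    MDS = H(P) / log 256 with P over all 256 motifs (unobserved motifs
    contribute nothing to the plug-in entropy).  Base-independent thanks to
    the normalization.  Empty input -> NaN.
    """
    if isinstance(motif_counts, Mapping):
        bad = set(motif_counts) - set(MOTIFS)
        if bad:
            raise ConfigError(f"unknown motifs: {sorted(bad)[:5]}")
        counts = np.fromiter(motif_counts.values(), dtype=float)
    else:
        counts = np.asarray(motif_counts, dtype=float)
        if counts.size != len(MOTIFS):
            raise ConfigError(f"expected {len(MOTIFS)} motif counts, got {counts.size}")
    if counts.sum() <= 0:
        return float("nan")
    return shannon_entropy(counts) / math.log(len(MOTIFS))


# ---------------------------------------------------------------------------
# per-sample extraction
# ---------------------------------------------------------------------------

def full_gene_depth(
    sample: SampleFragments,
    panel: PanelDefinition,
    gene: str,
    count_once: bool = True,
) -> float:
    """Normalized depth over all exons of one gene.

    With ``count_once`` (default) a fragment spanning two exons of the gene is
    counted a single time; the alternative counts it per exon.
    """
    exons = panel.exons_of(gene)
    if not exons:
        raise ConfigError(f"gene {gene} not on panel")
    assign = overlap_assign(sample, [e.interval for e in exons])
    idx = np.concatenate([assign[i] for i in range(len(exons))]) if exons else []
    count = len(np.unique(idx)) if count_once else len(idx)
    return normalized_depth(count, sum(e.length for e in exons), sample.total_reads)


def pooled_region_entropy(
    sample: SampleFragments, regions: Sequence[GenomicInterval]
) -> float:
    """Length entropy of fragments pooled over a region set (multi-assignment:
    a fragment overlapping k regions contributes k length observations)."""
    assign = overlap_assign(sample, regions)
    lengths = sample.lengths
    pooled = np.concatenate([lengths[assign[i]] for i in range(len(regions))]) if regions else np.empty(0)
    if pooled.size == 0:
        return float("nan")
    return shannon_entropy(LengthDistribution.from_lengths(pooled))


def tfbs_entropy(sample: SampleFragments, tfbs: TFBSCollection) -> dict[str, float]:
    """One pooled length-entropy per TF, using all sample reads."""
    return {tf: pooled_region_entropy(sample, tfbs.intervals(tf)) for tf in tfbs.tfs}


def atac_entropy(sample: SampleFragments, atac: ATACRegionSet) -> dict[str, float]:
    """One pooled length-entropy per cancer type, using all sample reads."""
    return {
        label: pooled_region_entropy(sample, atac.regions[label])
        for label in atac.cancer_types
    }


class FeatureExtractor:
    """Computes every per-sample base feature in one pass over the fragments.

    Exon assignment is done once and reused by all exon-level metrics; the
    TFBS/ATAC entropies pool all sample reads, not only exonic ones.
    """

    def __init__(
        self,
        panel: PanelDefinition,
        tfbs: TFBSCollection | None = None,
        atac: ATACRegionSet | None = None,
        count_gene_fragment_once: bool = True,
    ):
        self.panel = panel
        self.tfbs = tfbs
        self.atac = atac
        self.count_gene_fragment_once = count_gene_fragment_once
        self.exons = panel.exons  # deterministic (gene, rank) order
        self._exon_intervals = [e.interval for e in self.exons]
        self._gene_exon_idx: dict[str, list[int]] = {}
        for i, e in enumerate(self.exons):
            self._gene_exon_idx.setdefault(e.gene, []).append(i)
        self._e1_idx = {
            g: next(
                i
                for i, e in enumerate(self.exons)
                if e.gene == g and e.exon_rank == e1.exon_rank and e.start == e1.start
            )
            for g, e1 in panel.e1_map.items()
        }

    def sample_features(
        self, sample: SampleFragments, want: set[str] | None = None
    ) -> dict[str, pd.Series]:
        """Base feature vectors for one sample (NaN where undefined).

        ``want`` restricts computation to the named base metrics (E1 variants
        imply their all-exon parent); default computes everything available.
        """
        if want is None:
            want = {m for m in METRIC_NAMES if m != "combined"}
        need = set(want)
        for e1m in ("depth_E1", "entropy_E1", "mds_E1", "smallfrag_E1"):
            if e1m in need:
                need.add(e1m.replace("E1", "all_exons"))
        total = sample.total_reads
        if total == 0:
            raise ConfigError(f"sample {sample.sample_id} has no retained reads")
        lengths = sample.lengths
        assign = overlap_assign(sample, self._exon_intervals)

        do_ent = "entropy_all_exons" in need
        do_mds = "mds_all_exons" in need
        do_sfrac = "smallfrag_all_exons" in need
        do_bins = "fragment_bins" in need
        if do_mds:
            m5 = sample.df["motif5"].to_numpy(object)
            m3 = sample.df["motif3"].to_numpy(object)

        depth, ent, mds, sfrac = {}, {}, {}, {}
        bins: dict[str, float] = {}
        for i, e in enumerate(self.exons):
            idx = assign[i]
            key = e.label
            if "depth_all_exons" in need:
                depth[f"depth@{key}"] = normalized_depth(len(idx), e.length, total)
            if do_ent or do_sfrac or do_bins:
                sub = lengths[idx]
                dist = LengthDistribution.from_lengths(sub) if sub.size else None
                if do_ent:
                    ent[f"entropy@{key}"] = (
                        shannon_entropy(dist) if dist else np.nan
                    )
                if do_sfrac:
                    sfrac[f"sfrac@{key}"] = (
                        small_fragment_fraction(dist) if dist else np.nan
                    )
                if do_bins:
                    props = (
                        fragment_bin_proportions(dist)
                        if dist
                        else np.full(6, np.nan)
                    )
                    for b, lab in enumerate(FRAGMENT_BIN_LABELS):
                        bins[f"bin{lab}@{key}"] = props[b]
            if do_mds:
                motifs = [
                    m for arr in (m5[idx], m3[idx]) for m in arr if isinstance(m, str)
                ]
                if motifs:
                    counts = np.zeros(len(MOTIFS))
                    for m in motifs:
                        counts[MOTIF_INDEX[m]] += 1
                    mds[f"mds@{key}"] = motif_diversity_score(counts)
                else:
                    mds[f"mds@{key}"] = np.nan

        out: dict[str, pd.Series] = {}
        if "depth_all_exons" in need:
            out["depth_all_exons"] = pd.Series(depth)
        if "depth_full_gene" in need:
            gdepth = {}
            for gene in self.panel.genes:
                idxs = np.concatenate([assign[i] for i in self._gene_exon_idx[gene]])
                count = (
                    len(np.unique(idxs)) if self.count_gene_fragment_once else len(idxs)
                )
                bp = sum(self.exons[i].length for i in self._gene_exon_idx[gene])
                gdepth[f"gdepth@{gene}"] = normalized_depth(count, bp, total)
            out["depth_full_gene"] = pd.Series(gdepth)
        if do_ent:
            out["entropy_all_exons"] = pd.Series(ent)
        if do_mds:
            out["mds_all_exons"] = pd.Series(mds)
        if do_sfrac:
            out["smallfrag_all_exons"] = pd.Series(sfrac)
        if do_bins:
            out["fragment_bins"] = pd.Series(bins)
        for base, prefix in (
            ("depth_all_exons", "depth"),
            ("entropy_all_exons", "entropy"),
            ("mds_all_exons", "mds"),
            ("smallfrag_all_exons", "sfrac"),
        ):
            e1_name = base.replace("all_exons", "E1")
            if e1_name in want and base in out:
                e1_cols = [
                    f"{prefix}@{self.exons[i].label}"
                    for i in sorted(self._e1_idx.values())
                ]
                out[e1_name] = out[base][e1_cols]
        if self.tfbs is not None and "tfbs_entropy" in need:
            out["tfbs_entropy"] = pd.Series(
                {f"tfbs@{tf}": v for tf, v in tfbs_entropy(sample, self.tfbs).items()}
            )
        if self.atac is not None and "atac_entropy" in need:
            out["atac_entropy"] = pd.Series(
                {f"atac@{t}": v for t, v in atac_entropy(sample, self.atac).items()}
            )
        return out


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Samples x features matrix for one metric class, with phenotype labels."""

    metric_name: str
    values: pd.DataFrame  # index: sample ids, columns: feature names
    labels: pd.Series  # sample id -> phenotype
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.metric_name not in METRIC_NAMES:
            raise ConfigError(f"unknown metric {self.metric_name!r}")
        if self.values.columns.duplicated().any():
            raise ConfigError("duplicate feature names")
        if not self.values.index.equals(self.labels.index):
            self.labels = self.labels.reindex(self.values.index)
            if self.labels.isna().any():
                raise ConfigError("labels missing for some samples")

    @property
    def n_samples(self) -> int:
        return len(self.values)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def write_tsv(self, path: str | Path) -> None:
        """TSV with sample_id + phenotype + feature columns, plus a JSON
        sidecar recording metric and processing metadata."""
        path = Path(path)
        out = self.values.copy()
        out.insert(0, "phenotype", self.labels)
        out.to_csv(path, sep="\t", index_label="sample_id")
        sidecar = {
            "metric": self.metric_name,
            "entropy_base": "e",
            **self.metadata,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def read_tsv(cls, path: str | Path, metric_name: str | None = None) -> "FeatureTable":
        path = Path(path)
        df = pd.read_csv(path, sep="\t", index_col="sample_id")
        labels = df.pop("phenotype")
        meta = {}
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        return cls(metric_name or meta.get("metric", "combined"), df, labels, meta)


def impute_features(
    values: pd.DataFrame,
    metric_name: str,
    medians: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Fill missing values: 0 for depth metrics, per-feature median otherwise.

    Depth at an empty region is a true zero; an undefined entropy is not, so
    it gets the median of the samples where it is defined.  ``medians`` (from
    a training cohort) can be supplied to avoid information leaking from
    held-out samples; all-missing features fall back to 0.
    """
    if metric_name in _DEPTH_METRICS:
        return values.fillna(0.0), pd.Series(0.0, index=values.columns)
    med = values.median(axis=0, skipna=True) if medians is None else medians
    med = med.fillna(0.0)
    return values.fillna(med), med


def compute_feature_tables(
    samples: Sequence,
    panel: PanelDefinition,
    tfbs: TFBSCollection | None = None,
    atac: ATACRegionSet | None = None,
    labels: Mapping[str, str] | None = None,
    metrics: Sequence[str] = METRIC_NAMES,
    impute: bool = True,
) -> dict[str, FeatureTable]:
    """Assemble feature tables for a cohort.

    ``samples`` is a sequence of objects with ``sample_id``/``phenotype``/
    ``fragments`` attributes (synthetic samples) or of
    :class:`~panelfrag.fragments.SampleFragments` with labels supplied
    separately.  ``combined`` concatenates the 12 base tables with
    metric-prefixed column names.
    """
    unknown = set(metrics) - set(METRIC_NAMES)
    if unknown:
        raise ConfigError(f"unknown metrics: {sorted(unknown)}")
    base_metrics = [m for m in METRIC_NAMES if m != "combined"]
    need_combined = "combined" in metrics
    wanted_base = set(m for m in metrics if m != "combined")
    if need_combined:
        wanted_base = set(base_metrics)

    extractor = FeatureExtractor(panel, tfbs=tfbs, atac=atac)
    ids: list[str] = []
    phenos: list[str] = []
    rows: dict[str, list[pd.Series]] = {m: [] for m in base_metrics}
    for s in samples:
        if isinstance(s, SampleFragments):
            sf, sid = s, s.sample_id
            pheno = labels[sid] if labels else "unknown"
        else:
            sf, sid, pheno = s.fragments, s.sample_id, s.phenotype
        ids.append(sid)
        phenos.append(pheno)
        feats = extractor.sample_features(sf, want=wanted_base)
        for m in base_metrics:
            if m in wanted_base:
                if m not in feats:
                    raise ConfigError(
                        f"metric {m} requires {'TFBS' if 'tfbs' in m else 'ATAC'} regions"
                    )
                rows[m].append(feats[m])

    label_series = pd.Series(phenos, index=pd.Index(ids, name="sample_id"))
    tables: dict[str, FeatureTable] = {}
    meta = {
        "imputation": "zero-for-depth, per-feature median otherwise"
        if impute
        else "none",
        "entropy_estimator": "plug-in (ML), natural log",
        "motif_mode": "as extracted/generated (default: 3' reverse complement)",
    }
    for m in base_metrics:
        if m not in wanted_base:
            continue
        values = pd.DataFrame(rows[m], index=label_series.index)
        if impute:
            values, _ = impute_features(values, m)
        tables[m] = FeatureTable(m, values, label_series, dict(meta))
    if need_combined:
        parts = [
            tables[m].values.add_prefix(f"{m}|") for m in base_metrics if m in tables
        ]
        tables["combined"] = FeatureTable(
            "combined", pd.concat(parts, axis=1), label_series, dict(meta)
        )
    return {m: t for m, t in tables.items() if m in metrics}
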