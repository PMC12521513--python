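"""Synthetic cfDNA cohorts with the statistical structure the analysis assumes.

No public fragment-level cohort is bundled; instead this module generates toy
reference sequences, exon panels, TFBS/ATAC region sets, and fragment-level
samples whose distributions carry the signals the feature classes are meant
to detect:

* per-exon coverage modulated by phenotype through positive depth
  multipliers (expression/copy-number-like effects);
* fragment lengths from a truncated-normal mixture over a short (~110 bp),
  a mononucleosome (~167 bp, the modal cfDNA fragment length) and a
  dinucleosome (~330 bp) component, with a phenotype-dependent weight on the
  short component;
* 4-mer end-motif composition drawn per sample from a phenotype-specific
  Dirichlet over the 256 motifs (a Dirichlet-multinomial across fragments);
* sample-level tumor fraction: each fragment of a cancer sample originates
  from the tumor generative process with probability equal to the tumor
  fraction and from the healthy process otherwise.

All distributional choices are stand-ins: the real study analyzed sequenced
cohorts and provides no generative model.  Everything is deterministic given
the configuration seed; per-sample seeds are derived with
``numpy.random.SeedSequence([seed, index])``, a stable documented hash, so
individual samples can be re-generated without re-running the cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fragments import MOTIFS, ConfigError, SampleFragments
from .regions import ExonRegion, PanelDefinition, write_panel

HEALTHY = "healthy"

# internal SeedSequence stream tags so independent draws never share a stream
_REF_KEY, _PANEL_KEY, _TFBS_KEY, _ATAC_KEY, _SAMPLE_KEY = 11, 12, 13, 14, 15


class SizingError(ValueError):
    """The toy genome cannot fit the requested panel."""


@dataclass(frozen=True)
class LengthModel:
    """Truncated-normal mixture over fragment lengths, components
    (short, mononucleosome, dinucleosome).  Weights must sum to 1."""

    weights: tuple[float, float, float] = (0.08, 0.82, 0.10)
    means: tuple[float, float, float] = (110.0, 167.0, 330.0)
    sds: tuple[float, float, float] = (15.0, 15.0, 30.0)
    lo: int = 20
    hi: int = 500

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ConfigError(f"mixture weights sum to {sum(self.weights)}, not 1")
        if any(w < 0 for w in self.weights) or any(s < 0 for s in self.sds):
            raise ConfigError("negative weight or sd in length model")


def uniform_motif_concentration(strength: float = 500.0) -> np.ndarray:
    """Dirichlet concentration giving near-uniform motif usage."""
    return np.full(len(MOTIFS), strength / len(MOTIFS))


def tilted_motif_concentration(tilt: float, strength: float = 500.0) -> np.ndarray:
    """Concentration with geometrically decaying motif preference.

    ``tilt`` controls how uneven the expected motif distribution is
    (0 = uniform); larger tilt lowers the expected motif diversity score.
    """
    w = np.exp(-tilt * np.arange(len(MOTIFS)) / len(MOTIFS))
    return strength * w / w.sum()


@dataclass
class SimulationConfig:
    """Parameters of the toy genome, panel and per-phenotype fragment models.

    ``depth_multipliers`` maps phenotype to a per-exon positive multiplier
    vector (exons in panel order); ``None`` means flat coverage.  Healthy
    samples always have tumor fraction 0; other phenotypes default to the
    value in ``tumor_fractions`` (1.0 = pure tumor-process sample).
    """

    seed: int = 0
    n_genes: int = 6
    exons_per_gene: tuple[int, int] = (2, 3)
    exon_length_bp: tuple[int, int] = (120, 200)
    intron_gap_bp: tuple[int, int] = (60, 200)
    gene_gap_bp: tuple[int, int] = (400, 1200)
    genome_length_bp: int = 40_000
    chrom: str = "chrS"
    phenotypes: tuple[str, ...] = (HEALTHY, "cancer")
    n_samples_per_phenotype: int = 20
    reads_per_sample: int = 10_000
    offtarget_fraction: float = 0.10
    depth_multipliers: dict[str, np.ndarray | None] = field(default_factory=dict)
    length_models: dict[str, LengthModel] = field(default_factory=dict)
    motif_concentrations: dict[str, np.ndarray] = field(default_factory=dict)
    tumor_fractions: dict[str, float] = field(default_factory=dict)
    generate_motifs: bool = True  # False: leave motifs to FASTA extraction

    def __post_init__(self) -> None:
        if HEALTHY not in self.phenotypes:
            raise ConfigError("phenotypes must include 'healthy'")
        if self.reads_per_sample <= 0:
            raise ConfigError("reads_per_sample must be positive")
        if not 0 <= self.offtarget_fraction < 1:
            raise ConfigError("offtarget_fraction must be in [0, 1)")
        for ph in self.phenotypes:
            self.length_models.setdefault(
                ph,
                LengthModel()
                if ph == HEALTHY
                else LengthModel(weights=(0.25, 0.65, 0.10)),
            )
            self.motif_concentrations.setdefault(
                ph,
                uniform_motif_concentration()
                if ph == HEALTHY
                else tilted_motif_concentration(2.0),
            )
            self.tumor_fractions.setdefault(ph, 0.0 if ph == HEALTHY else 1.0)
            self.depth_multipliers.setdefault(ph, None)
        if abs(self.tumor_fractions[HEALTHY]) > 0:
            raise ConfigError("healthy tumor fraction must be 0")
        for ph, tf in self.tumor_fractions.items():
            if not 0.0 <= tf <= 1.0:
                raise ConfigError(f"tumor fraction {tf} for {ph} outside [0, 1]")
        for ph, mult in self.depth_multipliers.items():
            if mult is not None and np.any(np.asarray(mult) <= 0):
                raise ConfigError(f"non-positive depth multiplier for {ph}")

    def to_json(self) -> str:
        d = asdict(self)
        d["depth_multipliers"] = {
            k: (None if v is None else list(np.asarray(v, float)))
            for k, v in self.depth_multipliers.items()
        }
        d["motif_concentrations"] = {
            k: list(np.asarray(v, float)) for k, v in self.motif_concentrations.items()
        }
        return json.dumps(d, indent=1)


@dataclass
class SyntheticSample:
    sample_id: str
    phenotype: str
    tumor_fraction: float
    fragments: SampleFragments


def cna_like_multipliers(
    n_exons: int, gain: float = 2.5, loss: float = 0.4
) -> np.ndarray:
    """Block pattern of coverage gains/losses: first third of exons amplified,
    last third depleted, middle neutral — a crude copy-number caricature."""
    mult = np.ones(n_exons)
    third = max(1, n_exons // 3)
    mult[:third] = gain
    mult[-third:] = loss
    return mult


# ---------------------------------------------------------------------------
# reference + panel
# ---------------------------------------------------------------------------

def _panel_footprint(config: SimulationConfig) -> int:
    # worst-case packing length, used for the sizing precondition
    per_gene = (
        config.exons_per_gene[1] * config.exon_length_bp[1]
        + (config.exons_per_gene[1] - 1) * config.intron_gap_bp[1]
        + config.gene_gap_bp[1]
    )
    return 1000 + config.n_genes * per_gene


def generate_reference(config: SimulationConfig) -> str:
    """Uppercase A/C/G/T sequence of exactly ``genome_length_bp`` characters,
    deterministic given the seed."""
    if config.n_genes >= 1 and config.genome_length_bp < _panel_footprint(config):
        raise SizingError(
            f"genome of {config.genome_length_bp} bp cannot hold "
            f"{config.n_genes} genes (needs up to {_panel_footprint(config)} bp)"
        )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, _REF_KEY]))
    codes = rng.integers(0, 4, size=config.genome_length_bp)
    return "".join(np.array(list("ACGT"))[codes]) if config.genome_length_bp else ""


def generate_panel(config: SimulationConfig) -> PanelDefinition:
    """Pack non-overlapping genes (left to right) onto the toy genome."""
    if config.n_genes < 1:
        raise ConfigError("n_genes must be >= 1")
    if config.genome_length_bp < _panel_footprint(config):
        raise SizingError(
            f"genome of {config.genome_length_bp} bp cannot hold "
            f"{config.n_genes} genes (needs up to {_panel_footprint(config)} bp)"
        )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, _PANEL_KEY]))
    cursor = 1000
    exons: list[ExonRegion] = []
    for g in range(config.n_genes):
        gene = f"G{g + 1:02d}"
        n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        for rank in range(1, n_ex + 1):
            length = int(
                rng.integers(config.exon_length_bp[0], config.exon_length_bp[1] + 1)
            )
            exons.append(
                ExonRegion(config.chrom, cursor, cursor + length, gene, rank, True)
            )
            cursor += length + int(
                rng.integers(config.intron_gap_bp[0], config.intron_gap_bp[1] + 1)
            )
        cursor += int(rng.integers(config.gene_gap_bp[0], config.gene_gap_bp[1] + 1))
    if cursor > config.genome_length_bp:
        raise SizingError("panel packing exceeded the toy genome")
    return PanelDefinition(tuple(exons))


def generate_tfbs_sites(
    config: SimulationConfig,
    n_tfs: int = 4,
    sites_per_tf: int = 12,
    site_length_bp: tuple[int, int] = (150, 400),
) -> pd.DataFrame:
    """Toy GTRD-style site table (tf, chrom, start, end, support) scattered
    uniformly over the genome, deterministic given the config seed."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, _TFBS_KEY]))
    rows = []
    for t in range(n_tfs):
        tf = f"TF{t + 1:02d}"
        for _ in range(sites_per_tf):
            length = int(rng.integers(site_length_bp[0], site_length_bp[1] + 1))
            start = int(rng.integers(0, config.genome_length_bp - length))
            rows.append(
                {
                    "tf": tf,
                    "chrom": config.chrom,
                    "start": start,
                    "end": start + length,
                    "support": int(rng.integers(1, 1000)),
                }
            )
    return pd.DataFrame(rows)


def generate_atac_regions(
    config: SimulationConfig,
    cancer_types: Sequence[str] = ("typeA", "typeB", "typeC"),
    regions_per_type: int = 10,
    region_length_bp: tuple[int, int] = (300, 800),
):
    """Toy per-cancer-type open-chromatin interval sets."""
    from .regions import ATACRegionSet
    from .fragments import GenomicInterval

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, _ATAC_KEY]))
    out: dict[str, list[GenomicInterval]] = {}
    for label in cancer_types:
        ivs = []
        for _ in range(regions_per_type):
            length = int(rng.integers(region_length_bp[0], region_length_bp[1] + 1))
            start = int(rng.integers(0, config.genome_length_bp - length))
            ivs.append(GenomicInterval(config.chrom, start, start + length))
        out[label] = ivs
    return ATACRegionSet(out)


# ---------------------------------------------------------------------------
# fragment sampling
# ---------------------------------------------------------------------------

def _draw_lengths(model: LengthModel, n: int, rng: np.random.Generator) -> np.ndarray:
    comp = rng.choice(3, size=n, p=np.asarray(model.weights))
    lengths = np.empty(n, dtype=np.int64)
    for k in range(3):
        mask = comp == k
        m = int(mask.sum())
        if not m:
            continue
        mu, sd = model.means[k], model.sds[k]
        if sd == 0:
            draws = np.full(m, mu)
        else:
            a, b = (model.lo - mu) / sd, (model.hi - mu) / sd
            draws = stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=m, random_state=rng)
        lengths[mask] = np.clip(np.rint(draws), model.lo, model.hi).astype(np.int64)
    return lengths


def _place_on_target(
    exon_idx: np.ndarray,
    lengths: np.ndarray,
    starts: np.ndarray,
    ends: np.ndarray,
    genome_len: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Jitter fragments around their chosen exon, guaranteeing >=1 bp overlap."""
    lo = starts[exon_idx] - lengths + 1
    hi = ends[exon_idx]  # exclusive upper bound for start
    pos = rng.integers(lo, hi)
    return np.clip(pos, 0, genome_len - lengths)


def _place_off_target(
    n: int,
    lengths: np.ndarray,
    exon_starts: np.ndarray,
    exon_ends: np.ndarray,
    genome_len: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Uniform placement outside all exons, by rejection."""
    pos = rng.integers(0, np.maximum(genome_len - lengths, 1))
    padded_starts = np.append(exon_starts, np.iinfo(np.int64).max)
    for _ in range(200):
        # fragment [p, p+L) overlaps an exon iff the first exon ending after p
        # starts before p+L (exons are sorted and non-overlapping)
        i0 = np.searchsorted(exon_ends, pos, side="right")
        bad = padded_starts[i0] < pos + lengths
        if not bad.any():
            break
        pos[bad] = rng.integers(0, np.maximum(genome_len - lengths[bad], 1))
    return pos


def simulate_sample(
    config: SimulationConfig,
    phenotype: str,
    tumor_fraction: float | None = None,
    sample_seed: int = 0,
    panel: PanelDefinition | None = None,
    sample_id: str | None = None,
) -> SyntheticSample:
    """Draw one sample of ``reads_per_sample`` fragments.

    Each fragment independently (i) originates from the tumor process with
    probability ``tumor_fraction`` and the healthy process otherwise, (ii)
    lands off-target with probability ``offtarget_fraction`` or on an exon
    chosen proportionally to multiplier x exon length, (iii) gets a length
    from the origin phenotype's truncated mixture, and (iv) gets 5'/3' motifs
    from the origin phenotype's sample-level motif distribution (one Dirichlet
    draw per origin per sample).
    """
    if phenotype not in config.phenotypes:
        raise ConfigError(f"unknown phenotype {phenotype!r}")
    if tumor_fraction is None:
        tumor_fraction = config.tumor_fractions[phenotype]
    if not 0.0 <= tumor_fraction <= 1.0:
        raise ConfigError(f"tumor_fraction {tumor_fraction} outside [0, 1]")
    if panel is None:
        panel = generate_panel(config)
    exon_starts = np.array([e.start for e in panel.exons])
    exon_ends = np.array([e.end for e in panel.exons])
    exon_lens = exon_ends - exon_starts
    sort = np.argsort(exon_starts)
    sorted_starts, sorted_ends = exon_starts[sort], exon_ends[sort]

    rng = np.random.default_rng(np.random.SeedSequence([sample_seed, _SAMPLE_KEY]))
    n = config.reads_per_sample
    from_tumor = rng.random(n) < tumor_fraction

    pos = np.empty(n, dtype=np.int64)
    lengths = np.empty(n, dtype=np.int64)
    motif5 = np.empty(n, dtype=object)
    motif3 = np.empty(n, dtype=object)
    motif_arr = np.array(MOTIFS, dtype=object)

    for origin, mask in ((phenotype, from_tumor), (HEALTHY, ~from_tumor)):
        m = int(mask.sum())
        if not m:
            continue
        lengths_o = _draw_lengths(config.length_models[origin], m, rng)
        mult = config.depth_multipliers.get(origin)
        w = exon_lens.astype(float) * (
            np.ones(len(exon_lens)) if mult is None else np.asarray(mult, float)
        )
        w /= w.sum()
        offt = rng.random(m) < config.offtarget_fraction
        pos_o = np.empty(m, dtype=np.int64)
        n_on = int((~offt).sum())
        if n_on:
            exon_idx = rng.choice(len(exon_lens), size=n_on, p=w)
            pos_o[~offt] = _place_on_target(
                exon_idx, lengths_o[~offt], exon_starts, exon_ends,
                config.genome_length_bp, rng,
            )
        n_off = int(offt.sum())
        if n_off:
            pos_o[offt] = _place_off_target(
                n_off, lengths_o[offt], sorted_starts, sorted_ends,
                config.genome_length_bp, rng,
            )
        if config.generate_motifs:
            p = rng.dirichlet(np.asarray(config.motif_concentrations[origin], float))
            motif5[mask] = motif_arr[rng.choice(len(MOTIFS), size=m, p=p)]
            motif3[mask] = motif_arr[rng.choice(len(MOTIFS), size=m, p=p)]
        else:
            motif5[mask] = None
            motif3[mask] = None
        lengths[mask] = lengths_o
        pos[mask] = pos_o

    df = pd.DataFrame(
        {
            "chrom": config.chrom,
            "start": pos,
            "end": pos + lengths,
            "motif5": motif5,
            "motif3": motif3,
        }
    )
    sid = sample_id or f"{phenotype}_s{sample_seed}"
    return SyntheticSample(sid, phenotype, tumor_fraction, SampleFragments(sid, df))


def derive_sample_seed(config_seed: int, index: int) -> int:
    """Stable per-sample seed: first word of SeedSequence([seed, index])."""
    return int(np.random.SeedSequence([config_seed, index]).generate_state(1)[0]) % (
        2**31
    )


def simulate_cohort(
    config: SimulationConfig, panel: PanelDefinition | None = None
) -> tuple[list[SyntheticSample], pd.DataFrame]:
    """All phenotypes x ``n_samples_per_phenotype`` samples, plus a label table
    (sample_id, phenotype, tumor_fraction) aligned with the sample list."""
    if panel is None:
        panel = generate_panel(config)
    samples: list[SyntheticSample] = []
    index = 0
    for ph in config.phenotypes:
        for i in range(config.n_samples_per_phenotype):
            sid = f"{ph}_{i + 1:03d}"
            samples.append(
                simulate_sample(
                    config,
                    ph,
                    tumor_fraction=config.tumor_fractions[ph],
                    sample_seed=derive_sample_seed(config.seed, index),
                    panel=panel,
                    sample_id=sid,
                )
            )
            index += 1
    labels = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "phenotype": [s.phenotype for s in samples],
            "tumor_fraction": [s.tumor_fraction for s in samples],
        }
    )
    return samples, labels


def write_cohort(
    samples: Sequence[SyntheticSample],
    labels: pd.DataFrame,
    panel: PanelDefinition,
    outdir: str | Path,
    config: SimulationConfig | None = None,
    reference: str | None = None,
) -> None:
    """Write per-sample fragment BEDs, panel BED, labels TSV and optionally
    the reference FASTA and the config JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for s in samples:
        s.fragments.write_bed(outdir / f"{s.sample_id}.bed")
    write_panel(panel, outdir / "panel.bed")
    labels.to_csv(outdir / "labels.tsv", sep="\t", index=False)
    if config is not None:
        (outdir / "config.json").write_text(config.to_json())
    if reference is not None:
        chrom = config.chrom if config is not None else "chrS"
        with open(outdir / "reference.fa", "w") as fh:
            fh.write(f">{chrom}\n")
            for i in range(0, len(reference), 80):
                fh.write(reference[i : i + 80] + "\n")


# ---------------------------------------------------------------------------
# study-condition presets
# ---------------------------------------------------------------------------

def null_cohort_config(seed: int = 0, n_samples_per_phenotype: int = 60) -> SimulationConfig:
    """Two phenotypes sharing every generative parameter: the label carries no
    signal, so any classifier should sit at AUROC 0.5."""
    cfg = SimulationConfig(
        seed=seed,
        phenotypes=(HEALTHY, "cancer"),
        n_samples_per_phenotype=n_samples_per_phenotype,
        reads_per_sample=10_000,
    )
    cfg.length_models["cancer"] = cfg.length_models[HEALTHY]
    cfg.motif_concentrations["cancer"] = cfg.motif_concentrations[HEALTHY]
    cfg.depth_multipliers["cancer"] = None
    cfg.tumor_fractions["cancer"] = 0.0
    return cfg


def effect_cohort_config(
    seed: int = 0,
    n_samples_per_phenotype: int = 60,
    gain: float = 2.5,
    loss: float = 0.4,
) -> SimulationConfig:
    """Two phenotypes with a large copy-number-like depth effect (plus the
    default short-fragment and motif shifts of the cancer phenotype)."""
    cfg = SimulationConfig(
        seed=seed,
        phenotypes=(HEALTHY, "cancer"),
        n_samples_per_phenotype=n_samples_per_phenotype,
        reads_per_sample=10_000,
    )
    n_exons = len(generate_panel(cfg).exons)
    cfg.depth_multipliers["cancer"] = cna_like_multipliers(n_exons, gain, loss)
    return cfg
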