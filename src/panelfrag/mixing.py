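"""In silico down-sampling and mixing of cfDNA samples at fixed ratios.

Low tumor-fraction specimens are emulated by down-sampling fragments (uniform
without replacement, the behaviour of shuffling a fragment BED and taking the
first n lines) from a healthy donor and a partner (a cancer donor, or a
second healthy donor for the class-balance controls) and concatenating the
two draws at one of five healthy:partner ratios — 50:50, 75:25, 90:10, 95:5,
99:1 — to a fixed total read count.

Each mixture's *calculated ctDNA fraction* is the partner's tumor fraction
multiplied by the partner's share of reads; mixtures are binned by that
fraction into log-decade bins [1e-4, 1e-3), [1e-3, 1e-2), [1e-2, 1e-1),
[1e-1, 1].  The full design enumerates every healthy x cancer pair and every
ordered healthy x other-healthy pair at every ratio, separately for a
training and a validation donor split so no donor contributes to both.

At full scale this reproduces the printed design sizes (32 healthy x 71
cancer x 5 ratios = 11360 cancer mixtures plus 32 x 31 x 5 = 4960 controls
for training; 15 x 34 x 5 = 2550 plus 15 x 14 x 5 = 1050 for validation);
the total read count per mixture is a parameter, so desk-scale runs use
thousands of reads rather than 100 million.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fragments import ConfigError, SampleFragments

__all__ = [
    "MixingRatio",
    "MixingSpec",
    "DEFAULT_RATIOS",
    "FRACTION_BINS",
    "SUB_DETECTION_BIN",
    "InsufficientReadsError",
    "downsample",
    "mix",
    "enumerate_design",
    "calculated_ctdna_fraction",
    "assign_fraction_bin",
    "realize_mixture",
    "design_manifest",
    "depth_downsample_series",
]


class InsufficientReadsError(ValueError):
    """A source sample has fewer fragments than the requested draw."""


@dataclass(frozen=True)
class MixingRatio:
    """Healthy:partner split of a mixture's total reads, in percent."""

    healthy_pct: float
    partner_pct: float

    def __post_init__(self) -> None:
        if self.healthy_pct <= 0 or self.partner_pct <= 0:
            raise ConfigError("ratio shares must be positive")
        if abs(self.healthy_pct + self.partner_pct - 100.0) > 1e-9:
            raise ConfigError("ratio shares must sum to 100")

    @property
    def partner_proportion(self) -> float:
        return self.partner_pct / 100.0

    @property
    def label(self) -> str:
        def fmt(x: float) -> str:
            return f"{x:g}"

        return f"{fmt(self.healthy_pct)}:{fmt(self.partner_pct)}"


#: the study's five healthy:partner ratios
DEFAULT_RATIOS: tuple[MixingRatio, ...] = (
    MixingRatio(50, 50),
    MixingRatio(75, 25),
    MixingRatio(90, 10),
    MixingRatio(95, 5),
    MixingRatio(99, 1),
)

#: log-decade calculated-fraction bins, half-open except the top bin
FRACTION_BINS: tuple[tuple[float, float], ...] = (
    (1e-4, 1e-3),
    (1e-3, 1e-2),
    (1e-2, 1e-1),
    (1e-1, 1.0),
)
SUB_DETECTION_BIN = "sub-detection"


def _bin_label(lo: float, hi: float) -> str:
    return f"{lo:g}-{hi:g}"


FRACTION_BIN_LABELS: tuple[str, ...] = tuple(_bin_label(lo, hi) for lo, hi in FRACTION_BINS)


def calculated_ctdna_fraction(
    partner_tumor_fraction: float, partner_share_proportion: float
) -> float:
    """Tumor fraction of a mixture: partner's fraction times its read share."""
    if not 0.0 <= partner_tumor_fraction <= 1.0:
        raise ConfigError(f"tumor fraction {partner_tumor_fraction} outside [0, 1]")
    if not 0.0 <= partner_share_proportion <= 1.0:
        raise ConfigError(f"share {partner_share_proportion} outside [0, 1]")
    return partner_tumor_fraction * partner_share_proportion


def assign_fraction_bin(calculated_fraction: float) -> str:
    """Log-decade bin label for a positive calculated fraction.

    Fractions below 1e-4 are labelled ``sub-detection`` and are excluded from
    binned AUROC summaries.  Bin edges are half-open on the right except the
    top bin, which includes 1.
    """
    f = float(calculated_fraction)
    if not 0.0 < f <= 1.0:
        raise ConfigError(f"calculated fraction {f} outside (0, 1]")
    if f < FRACTION_BINS[0][0]:
        return SUB_DETECTION_BIN
    for lo, hi in FRACTION_BINS[:-1]:
        if lo <= f < hi:
            return _bin_label(lo, hi)
    lo, hi = FRACTION_BINS[-1]
    return _bin_label(lo, hi)


@dataclass(frozen=True)
class MixingSpec:
    """One synthetic mixture: donors, ratio, total reads and seed."""

    healthy_id: str
    partner_id: str
    partner_is_cancer: bool
    ratio: MixingRatio
    total_reads: int
    seed: int
    partner_tumor_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.healthy_id == self.partner_id:
            raise ConfigError("a sample cannot be mixed with itself")
        if self.total_reads <= 0:
            raise ConfigError("total_reads must be positive")
        if not self.partner_is_cancer and self.partner_tumor_fraction != 0.0:
            raise ConfigError("healthy partner must have tumor fraction 0")

    @property
    def calculated_fraction(self) -> float:
        return calculated_ctdna_fraction(
            self.partner_tumor_fraction, self.ratio.partner_proportion
        )

    @property
    def fraction_bin(self) -> str | None:
        if self.calculated_fraction <= 0.0:
            return None
        return assign_fraction_bin(self.calculated_fraction)

    @property
    def mixture_id(self) -> str:
        return f"{self.healthy_id}+{self.partner_id}@{self.ratio.label}"


def downsample(fragments: SampleFragments, n: int, seed: int) -> SampleFragments:
    """Uniform draw of exactly ``n`` fragments without replacement."""
    if n < 0:
        raise ConfigError("cannot draw a negative number of fragments")
    if n > len(fragments):
        raise InsufficientReadsError(
            f"{fragments.sample_id}: requested {n} of {len(fragments)} fragments"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(fragments), size=n, replace=False)
    return SampleFragments(fragments.sample_id, fragments.df.iloc[idx])


def mix(
    healthy: SampleFragments,
    partner: SampleFragments,
    ratio: MixingRatio,
    total_reads: int,
    seed: int,
) -> SampleFragments:
    """Down-sample both sources and concatenate to exactly ``total_reads``.

    The partner share is ``round(total_reads * partner_proportion)``; the
    healthy share absorbs the rounding so the total is exact.  Fragment origin
    is retained in an ``origin`` audit column.
    """
    if healthy.sample_id == partner.sample_id:
        raise ConfigError("healthy and partner sample ids must differ")
    n_partner = int(round(total_reads * ratio.partner_proportion))
    n_healthy = total_reads - n_partner
    ss = np.random.SeedSequence(seed)
    seed_h, seed_p = (int(s.generate_state(1)[0]) % 2**31 for s in ss.spawn(2))
    part_h = downsample(healthy, n_healthy, seed_h).df.assign(origin=healthy.sample_id)
    part_p = downsample(partner, n_partner, seed_p).df.assign(origin=partner.sample_id)
    mixed = pd.concat([part_h, part_p], ignore_index=True)
    sid = f"{healthy.sample_id}+{partner.sample_id}@{ratio.label}"
    return SampleFragments(sid, mixed)


def enumerate_design(
    healthy_ids: Sequence[str],
    cancer_ids: Sequence[str],
    ratios: Sequence[MixingRatio] = DEFAULT_RATIOS,
    total_reads: int = 10_000,
    tumor_fractions: Mapping[str, float] | None = None,
    master_seed: int = 0,
) -> list[MixingSpec]:
    """Enumerate the full mixing design for one donor split.

    Cancer mixtures: every healthy x cancer pair at every ratio.  Controls:
    every *ordered* healthy pair (no self-pairing) at every ratio — the only
    reading consistent with the printed |H| x (|H|-1) x |ratios| counts.
    Per-spec seeds derive deterministically from ``master_seed``.
    """
    healthy_ids = list(healthy_ids)
    cancer_ids = list(cancer_ids)
    overlap = set(healthy_ids) & set(cancer_ids)
    if overlap:
        raise ConfigError(f"ids in both donor sets: {sorted(overlap)[:5]}")
    if len(set(healthy_ids)) != len(healthy_ids) or len(set(cancer_ids)) != len(
        cancer_ids
    ):
        raise ConfigError("duplicate donor ids")
    if len(healthy_ids) < 2:
        raise ConfigError("need >=2 healthy donors for healthy-healthy controls")
    tf = dict(tumor_fractions or {})
    specs: list[MixingSpec] = []
    counter = 0

    def next_seed() -> int:
        nonlocal counter
        s = int(
            np.random.SeedSequence([master_seed, counter]).generate_state(1)[0]
        ) % (2**31)
        counter += 1
        return s

    for h in healthy_ids:
        for c in cancer_ids:
            for ratio in ratios:
                specs.append(
                    MixingSpec(
                        healthy_id=h,
                        partner_id=c,
                        partner_is_cancer=True,
                        ratio=ratio,
                        total_reads=total_reads,
                        seed=next_seed(),
                        partner_tumor_fraction=float(tf.get(c, 1.0)),
                    )
                )
    for h in healthy_ids:
        for h2 in healthy_ids:
            if h2 == h:
                continue
            for ratio in ratios:
                specs.append(
                    MixingSpec(
                        healthy_id=h,
                        partner_id=h2,
                        partner_is_cancer=False,
                        ratio=ratio,
                        total_reads=total_reads,
                        seed=next_seed(),
                        partner_tumor_fraction=0.0,
                    )
                )
    return specs


def realize_mixture(
    spec: MixingSpec, donors: Mapping[str, SampleFragments]
) -> SampleFragments:
    """Materialize one mixture from its spec and the donor fragment pools."""
    return mix(
        donors[spec.healthy_id],
        donors[spec.partner_id],
        spec.ratio,
        spec.total_reads,
        spec.seed,
    )


def design_manifest(specs: Sequence[MixingSpec]) -> pd.DataFrame:
    """Tabular manifest of a mixing design (one row per spec)."""
    return pd.DataFrame(
        {
            "mixture_id": [s.mixture_id for s in specs],
            "healthy_id": [s.healthy_id for s in specs],
            "partner_id": [s.partner_id for s in specs],
            "partner_is_cancer": [s.partner_is_cancer for s in specs],
            "ratio": [s.ratio.label for s in specs],
            "total_reads": [s.total_reads for s in specs],
            "seed": [s.seed for s in specs],
            "partner_tumor_fraction": [s.partner_tumor_fraction for s in specs],
            "calculated_fraction": [s.calculated_fraction for s in specs],
            "fraction_bin": [s.fraction_bin or "" for s in specs],
        }
    )


def write_manifest(specs: Sequence[MixingSpec], path: str | Path) -> None:
    design_manifest(specs).to_csv(path, sep="\t", index=False)


def depth_downsample_series(
    samples: Mapping[str, SampleFragments],
    depths: Sequence[int],
    seed: int = 0,
) -> dict[int, dict[str, SampleFragments]]:
    """One cohort per target depth, each sample independently down-sampled.

    Samples with fewer fragments than a requested depth are skipped at that
    depth with a warning.
    """
    out: dict[int, dict[str, SampleFragments]] = {}
    for d_i, depth in enumerate(depths):
        cohort: dict[str, SampleFragments] = {}
        for s_i, (sid, sf) in enumerate(samples.items()):
            if len(sf) < depth:
                warnings.warn(
                    f"{sid}: {len(sf)} fragments < target depth {depth}; skipped"
                )
                continue
            sub_seed = int(
                np.random.SeedSequence([seed, d_i, s_i]).generate_state(1)[0]
            ) % (2**31)
            cohort[sid] = downsample(sf, depth, sub_seed)
        out[depth] = cohort
    return out
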