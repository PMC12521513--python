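"""Region systems: panel exons with E1 designation, TFBS sets, open chromatin.

Three region systems drive the feature classes:

* the targeted panel's exons, annotated with gene symbol, exon rank
  (transcript order, 1-based) and a coding flag.  Each gene gets one "E1"
  exon: its first coding exon, or — when that exon is not on the panel — the
  closest coding exon that is, interpreted as the lowest exon rank present;
* transcription factor binding sites with experimental-support counts, of
  which the best-supported ``top_n`` per TF are retained and TFs that cannot
  fill the quota are dropped;
* per-cancer-type open-chromatin (ATAC) interval sets.

Commercial-panel experiments subset the panel to an external gene list.
Gene symbols are matched case-insensitively after trimming; alias resolution
is out of scope.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .fragments import BedParseError, ConfigError, GenomicInterval

logger = logging.getLogger(__name__)

TFBS_TOP_N = 5000  # sites kept per transcription factor at full scale


@dataclass(frozen=True)
class ExonRegion:
    """One panel exon: interval + gene symbol, transcript rank, coding flag."""

    chrom: str
    start: int
    end: int
    gene: str
    exon_rank: int
    is_coding: bool = True

    def __post_init__(self) -> None:
        if self.exon_rank < 1:
            raise ValueError(f"exon_rank must be >= 1, got {self.exon_rank}")
        GenomicInterval(self.chrom, self.start, self.end)  # validates coords

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, name=self.label)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def label(self) -> str:
        return f"{self.gene}:e{self.exon_rank}"


def designate_first_exons(
    exons: Sequence[ExonRegion], policy: str = "rank"
) -> dict[str, ExonRegion]:
    """Pick each gene's E1 exon: rank-1 coding exon, else lowest coding rank.

    Genes with no coding exon are omitted (with a warning): they contribute no
    E1 feature.  The result is independent of the order of ``exons``.
    """
    if policy != "rank":
        raise ConfigError(f"unknown e1 policy {policy!r}")
    e1: dict[str, ExonRegion] = {}
    genes = sorted({e.gene for e in exons})
    for gene in genes:
        coding = [e for e in exons if e.gene == gene and e.is_coding]
        if not coding:
            warnings.warn(f"gene {gene} has no coding exon; excluded from E1 features")
            continue
        e1[gene] = min(coding, key=lambda e: (e.exon_rank, e.chrom, e.start))
    return e1


@dataclass
class PanelDefinition:
    """A targeted panel: exon records plus the derived per-gene E1 map."""

    exons: tuple[ExonRegion, ...]
    e1_policy: str = "rank"
    e1_map: dict[str, ExonRegion] = field(init=False)

    def __post_init__(self) -> None:
        self.exons = tuple(
            sorted(self.exons, key=lambda e: (e.gene, e.exon_rank, e.chrom, e.start))
        )
        for gene in {e.gene for e in self.exons}:
            ivs = sorted(
                (e for e in self.exons if e.gene == gene), key=lambda e: (e.chrom, e.start)
            )
            for a, b in zip(ivs, ivs[1:]):
                if a.chrom == b.chrom and b.start < a.end:
                    raise ValueError(f"overlapping exons within gene {gene}")
        self.e1_map = designate_first_exons(self.exons, self.e1_policy)

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(sorted({e.gene for e in self.exons}))

    @property
    def total_bp(self) -> int:
        return sum(e.length for e in self.exons)

    def exons_of(self, gene: str) -> tuple[ExonRegion, ...]:
        return tuple(e for e in self.exons if e.gene == gene)


def load_panel(path: str | Path, e1_policy: str = "rank") -> PanelDefinition:
    """Read a panel BED6+: chrom, start, end, gene, exon_rank, is_coding."""
    path = Path(path)
    exons = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise BedParseError(f"{path}:{lineno}: expected 6 columns")
            try:
                exons.append(
                    ExonRegion(
                        chrom=parts[0],
                        start=int(parts[1]),
                        end=int(parts[2]),
                        gene=normalize_symbol(parts[3]),
                        exon_rank=int(parts[4]),
                        is_coding=parts[5] in ("1", "True", "true", "coding"),
                    )
                )
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return PanelDefinition(tuple(exons), e1_policy=e1_policy)


def write_panel(panel: PanelDefinition, path: str | Path) -> None:
    with open(path, "w") as fh:
        for e in panel.exons:
            fh.write(
                f"{e.chrom}\t{e.start}\t{e.end}\t{e.gene}\t{e.exon_rank}"
                f"\t{int(e.is_coding)}\n"
            )


# ---------------------------------------------------------------------------
# TFBS
# ---------------------------------------------------------------------------

@dataclass
class TFBSCollection:
    """Per-TF curated binding sites, each TF holding exactly ``top_n`` sites."""

    sites: dict[str, pd.DataFrame]  # columns chrom, start, end, support
    top_n: int

    @property
    def tfs(self) -> tuple[str, ...]:
        return tuple(sorted(self.sites))

    def intervals(self, tf: str) -> list[GenomicInterval]:
        df = self.sites[tf]
        return [
            GenomicInterval(c, int(s), int(e))
            for c, s, e in zip(df["chrom"], df["start"], df["end"])
        ]


def select_tfbs_sites(
    records: pd.DataFrame, top_n: int = TFBS_TOP_N
) -> TFBSCollection:
    """Keep the ``top_n`` best-supported sites per TF; drop TFs below quota.

    ``records`` needs columns tf, chrom, start, end, support.  Sites are
    ranked by support descending with a deterministic (chrom, start) ascending
    tie-break at the quota boundary.
    """
    required = {"tf", "chrom", "start", "end", "support"}
    missing = required - set(records.columns)
    if missing:
        raise ConfigError(f"TFBS table missing columns: {sorted(missing)}")
    out: dict[str, pd.DataFrame] = {}
    for tf, grp in records.groupby("tf", sort=True):
        if len(grp) < top_n:
            continue
        ranked = grp.sort_values(
            by=["support", "chrom", "start"], ascending=[False, True, True]
        ).head(top_n)
        out[str(tf)] = ranked[["chrom", "start", "end", "support"]].reset_index(
            drop=True
        )
    return TFBSCollection(out, top_n=top_n)


def load_tfbs_table(path: str | Path) -> pd.DataFrame:
    """Read a GTRD-style site table: headered TSV with chrom/start/end/tf and
    a support column (``support`` or ``exp_count``)."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lstrip("#").strip().lower() for c in df.columns]
    if "exp_count" in df.columns and "support" not in df.columns:
        df = df.rename(columns={"exp_count": "support"})
    return df


# ---------------------------------------------------------------------------
# Open chromatin (ATAC)
# ---------------------------------------------------------------------------

@dataclass
class ATACRegionSet:
    """Per-cancer-type open-chromatin intervals."""

    regions: dict[str, list[GenomicInterval]]

    @property
    def cancer_types(self) -> tuple[str, ...]:
        return tuple(sorted(self.regions))


def load_atac_regions(paths: Mapping[str, str | Path]) -> ATACRegionSet:
    """Load one BED per cancer-type label.  Duplicate labels are rejected by
    construction (mapping keys); an empty BED yields an empty set + warning."""
    out: dict[str, list[GenomicInterval]] = {}
    for label, path in paths.items():
        if label in out:
            raise ConfigError(f"duplicate cancer-type label {label!r}")
        ivs: list[GenomicInterval] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise BedParseError(f"{path}:{lineno}: expected >=3 columns")
                ivs.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2])))
        if not ivs:
            warnings.warn(f"ATAC BED for {label!r} is empty")
        out[label] = ivs
    return ATACRegionSet(out)


# ---------------------------------------------------------------------------
# Commercial-panel gene subsetting
# ---------------------------------------------------------------------------

def normalize_symbol(symbol: str) -> str:
    return symbol.strip().upper()


def read_gene_list(path: str | Path) -> set[str]:
    """One gene symbol per line; blank lines and ``#`` comments ignored."""
    genes: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.add(normalize_symbol(line))
    return genes


def gene_list_coverage(
    panel: PanelDefinition, gene_list: Iterable[str]
) -> tuple[int, float]:
    """(number of list genes on the panel, fraction of the list covered)."""
    wanted = {normalize_symbol(g) for g in gene_list}
    shared = wanted & set(panel.genes)
    return len(shared), len(shared) / len(wanted) if wanted else 0.0


def subset_panel(panel: PanelDefinition, gene_list: Iterable[str]) -> PanelDefinition:
    """Restrict the panel to genes present in ``gene_list``.

    The E1 map is recomputed on the subset.  Raises :class:`ConfigError` when
    the intersection is empty.  Subsetting by the panel's own gene set is the
    identity.
    """
    wanted = {normalize_symbol(g) for g in gene_list}
    kept = tuple(e for e in panel.exons if e.gene in wanted)
    if not kept:
        raise ConfigError("gene list shares no genes with the panel")
    n_shared, fraction = gene_list_coverage(panel, wanted)
    logger.info(
        "panel subset: %d/%d list genes on panel (%.1f%%)",
        n_shared,
        len(wanted),
        100 * fraction,
    )
    return PanelDefinition(kept, e1_policy=panel.e1_policy)
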