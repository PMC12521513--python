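"""Fragment-level I/O, length filtering, interval assignment and end motifs.

All coordinates are BED-style: 0-based, half-open ``[start, end)``.  A cfDNA
fragment is the genomic interval spanned by a sequenced DNA molecule; its
length in bp is ``end - start``.  Every length-based metric downstream
operates on fragments that survived the standard 20-500 bp size filter.

End motifs are the first four reference bases read inward from each fragment
end.  The 5' motif is the plus-strand sequence at ``[start, start+4)``.  For
the 3' end two conventions circulate: the reverse complement of
``[end-4, end)`` (reading into the fragment from its end, the convention of
the end-motif literature) or the literal plus-strand sequence (what a
strand-unaware FASTA lookup returns).  Both are supported; reverse complement
is the default and the choice is recorded wherever motifs are consumed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

BASES = "ACGT"
#: the 256 possible 4-mer end motifs, lexicographic order
MOTIFS: tuple[str, ...] = tuple("".join(p) for p in itertools.product(BASES, repeat=4))
MOTIF_INDEX: dict[str, int] = {m: i for i, m in enumerate(MOTIFS)}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: default fragment-size filter bounds (bp), inclusive
MIN_FRAGMENT_BP = 20
MAX_FRAGMENT_BP = 500

_FRAG_COLUMNS = ("chrom", "start", "end", "motif5", "motif3")


class BedParseError(ValueError):
    """A fragment/region file line could not be parsed."""


class ConfigError(ValueError):
    """Invalid parameter combination."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} in {self.chrom}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class FragmentRecord(NamedTuple):
    """One sequenced cfDNA fragment, with optional pre-extracted end motifs."""

    chrom: str
    start: int
    end: int
    five_prime_motif: str | None = None
    three_prime_motif: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


@dataclass(eq=False)
class SampleFragments:
    """All retained fragments of one sample, held as a columnar table.

    ``df`` has columns chrom/start/end and (possibly all-missing) motif5 and
    motif3.  ``total_reads`` is the number of retained fragments and is the
    per-sample denominator used by normalized depth.
    """

    sample_id: str
    df: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        df = self.df
        if df is None or len(df.columns) == 0:
            df = pd.DataFrame({c: [] for c in _FRAG_COLUMNS})
        df = df.copy()
        for col in ("motif5", "motif3"):
            if col not in df.columns:
                df[col] = pd.NA
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if len(df) and (df["start"] >= df["end"]).any():
            bad = int((df["start"] >= df["end"]).sum())
            raise ValueError(f"{bad} fragments with start >= end in {self.sample_id}")
        if len(df) and (df["start"] < 0).any():
            raise ValueError(f"negative coordinates in {self.sample_id}")
        order = [c for c in _FRAG_COLUMNS if c in df.columns]
        extra = [c for c in df.columns if c not in order]
        self.df = df[order + extra].reset_index(drop=True)

    # -- basic accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def total_reads(self) -> int:
        return len(self.df)

    @property
    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    def records(self) -> Iterator[FragmentRecord]:
        for row in self.df.itertuples(index=False):
            yield FragmentRecord(
                row.chrom,
                int(row.start),
                int(row.end),
                None if pd.isna(row.motif5) else row.motif5,
                None if pd.isna(row.motif3) else row.motif3,
            )

    @classmethod
    def from_records(
        cls, sample_id: str, records: Iterable[FragmentRecord | tuple]
    ) -> "SampleFragments":
        rows = [FragmentRecord(*r) for r in records]
        df = pd.DataFrame(
            {
                "chrom": [r.chrom for r in rows],
                "start": [r.start for r in rows],
                "end": [r.end for r in rows],
                "motif5": [r.five_prime_motif for r in rows],
                "motif3": [r.three_prime_motif for r in rows],
            }
        )
        return cls(sample_id, df)

    def equals(self, other: "SampleFragments") -> bool:
        a = self.df[list(_FRAG_COLUMNS)].fillna(".")
        b = other.df[list(_FRAG_COLUMNS)].fillna(".")
        return self.sample_id == other.sample_id and a.reset_index(drop=True).equals(
            b.reset_index(drop=True)
        )

    # -- serialization ---------------------------------------------------
    def write_bed(self, path: str | Path) -> None:
        """Write a fragment BED: 3 columns, plus motif columns 4-5 if set."""
        out = self.df[["chrom", "start", "end"]].copy()
        if self.df["motif5"].notna().any() or self.df["motif3"].notna().any():
            out["motif5"] = self.df["motif5"].fillna(".")
            out["motif3"] = self.df["motif3"].fillna(".")
        out.to_csv(path, sep="\t", header=False, index=False)


_MOTIF_TOKEN = {*MOTIFS, "."}


def read_fragment_bed(path: str | Path, sample_id: str | None = None) -> SampleFragments:
    """Read a fragment BED file (>=3 tab-separated columns per line).

    Columns 4-5 are parsed as 5'/3' end motifs when they look like 4-mer
    motifs (or the ``.`` placeholder); other extra columns are ignored.  No
    length filtering is applied here.  Malformed coordinates raise
    :class:`BedParseError` with the offending line number.
    """
    path = Path(path)
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    m5: list[object] = []
    m3: list[object] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >=3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start < 0 or start >= end:
                raise BedParseError(
                    f"{path}:{lineno}: invalid interval {parts[0]}:{start}-{end}"
                )
            chroms.append(parts[0])
            starts.append(start)
            ends.append(end)
            if len(parts) >= 5 and parts[3] in _MOTIF_TOKEN and parts[4] in _MOTIF_TOKEN:
                m5.append(parts[3] if parts[3] != "." else pd.NA)
                m3.append(parts[4] if parts[4] != "." else pd.NA)
            else:
                m5.append(pd.NA)
                m3.append(pd.NA)
    df = pd.DataFrame(
        {"chrom": chroms, "start": starts, "end": ends, "motif5": m5, "motif3": m3}
    )
    return SampleFragments(sample_id or path.stem, df)


def filter_by_length(
    fragments: SampleFragments,
    min_bp: int = MIN_FRAGMENT_BP,
    max_bp: int = MAX_FRAGMENT_BP,
    inclusive: bool = True,
) -> SampleFragments:
    """Retain fragments with ``min_bp <= length <= max_bp``.

    Bounds are inclusive by default (a 20 bp and a 500 bp fragment are both
    kept); set ``inclusive=False`` for strict inequalities.  Idempotent.
    """
    if min_bp > max_bp:
        raise ConfigError(f"min_bp {min_bp} > max_bp {max_bp}")
    lengths = fragments.df["end"] - fragments.df["start"]
    if inclusive:
        mask = (lengths >= min_bp) & (lengths <= max_bp)
    else:
        mask = (lengths > min_bp) & (lengths < max_bp)
    return SampleFragments(fragments.sample_id, fragments.df[mask])


def overlap_assign(
    fragments: SampleFragments | pd.DataFrame,
    regions: Sequence[GenomicInterval],
    min_overlap_bp: int = 1,
) -> dict[int, np.ndarray]:
    """Assign fragments to every region they overlap by >= ``min_overlap_bp``.

    Returns a map from region index (position in ``regions``) to the integer
    row indices of overlapping fragments.  A fragment overlapping several
    regions is assigned to each of them; fragments overlapping nothing appear
    nowhere.  Regions without fragments map to an empty array.
    """
    df = fragments.df if isinstance(fragments, SampleFragments) else fragments
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, grp in df.groupby("chrom", sort=False, observed=True):
        by_chrom[str(chrom)] = (
            grp["start"].to_numpy(np.int64),
            grp["end"].to_numpy(np.int64),
            grp.index.to_numpy(np.int64),
        )
    out: dict[int, np.ndarray] = {}
    for i, region in enumerate(regions):
        got = by_chrom.get(region.chrom)
        if got is None:
            out[i] = np.empty(0, dtype=np.int64)
            continue
        starts, ends, idx = got
        ov = np.minimum(ends, region.end) - np.maximum(starts, region.start)
        out[i] = idx[ov >= min_overlap_bp]
    return out


class _ReferenceView:
    """Uniform ``fetch(chrom, start, end)`` over a dict or a FASTA file."""

    def __init__(self, reference: Mapping[str, str] | str | Path):
        if isinstance(reference, (str, Path)):
            from pyfaidx import Fasta

            self._fasta = Fasta(str(reference))
            self._dict = None
        else:
            self._fasta = None
            self._dict = reference

    def length(self, chrom: str) -> int:
        if self._dict is not None:
            if chrom not in self._dict:
                raise KeyError(f"chromosome {chrom!r} not in reference")
            return len(self._dict[chrom])
        if chrom not in self._fasta:
            raise KeyError(f"chromosome {chrom!r} not in reference")
        return len(self._fasta[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if self._dict is not None:
            return self._dict[chrom][start:end]
        return str(self._fasta[chrom][start:end])


def extract_end_motifs(
    fragments: SampleFragments,
    reference: Mapping[str, str] | str | Path,
    three_prime_revcomp: bool = True,
) -> SampleFragments:
    """Populate 4-mer end motifs from a reference sequence.

    The 5' motif is the plus-strand reference at ``[start, start+4)``.  The 3'
    motif is by default the reverse complement of ``[end-4, end)``; with
    ``three_prime_revcomp=False`` it is the plus-strand literal.  Fragments
    whose motif windows contain an ambiguous base (N) get both motifs set to
    missing, which excludes them from motif counting downstream.

    Raises ``ValueError`` if any fragment extends outside the reference or is
    shorter than 4 bp.
    """
    ref = _ReferenceView(reference)
    df = fragments.df.copy()
    m5: list[object] = []
    m3: list[object] = []
    for chrom, start, end in zip(df["chrom"], df["start"], df["end"]):
        if end - start < 4:
            raise ValueError(f"fragment {chrom}:{start}-{end} shorter than 4 bp")
        if start < 0 or end > ref.length(chrom):
            raise ValueError(f"fragment {chrom}:{start}-{end} outside reference")
        five = ref.fetch(chrom, start, start + 4).upper()
        three_raw = ref.fetch(chrom, end - 4, end).upper()
        three = reverse_complement(three_raw) if three_prime_revcomp else three_raw
        if "N" in five or "N" in three:
            m5.append(pd.NA)
            m3.append(pd.NA)
        else:
            m5.append(five)
            m3.append(three)
    df["motif5"] = m5
    df["motif3"] = m3
    return SampleFragments(fragments.sample_id, df)
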