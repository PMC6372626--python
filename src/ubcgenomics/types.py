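"""Core domain containers shared by every analysis stage.

Coordinate conventions
----------------------
All *internal* interval arithmetic is 0-based, half-open.  Point mutations
(:class:`SnvRecord`) and breakends (:class:`SvRecord`) carry 1-based
positions, matching VCF; the conversion to/from 0-based file formats
(BED/BEDPE) happens only at file boundaries in :mod:`ubcgenomics.io`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

BASES = "ACGT"
_BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT_CODE = np.array([3, 2, 1, 0], dtype=np.uint8)  # A<->T, C<->G

SV_TYPES = (
    "deletion",
    "tandem_duplication",
    "inversion",
    "insertion",
    "translocation",
    "TEI",
    "VNTR",
    "complex",
)

ANNOTATION_CLASSES = ("promoter", "enhancer", "UTR", "intron", "TFBS", "blacklist")


class InvalidConfigError(ValueError):
    """A simulation or run configuration violates its invariants."""


class InputFormatError(ValueError):
    """A record in an input file violates the format contract."""


# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SnvRecord:
    """A somatic single-nucleotide variant (1-based position)."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref not in BASES or self.alt not in BASES:
            raise InputFormatError(
                f"SNV alleles must be single bases in ACGT: {self.ref}>{self.alt}"
            )
        if self.ref == self.alt:
            raise InputFormatError(f"ref equals alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise InputFormatError(f"1-based position must be >= 1, got {self.pos}")


@dataclass(frozen=True)
class SvRecord:
    """A somatic structural-variant breakpoint junction.

    ``homology_code`` follows the junction-homology convention of
    split-read SV callers: values >= 0 give the number of bases of
    microhomology shared by the two junction sides; values -1..-10 give
    the length of a short untemplated insertion at the junction.
    Orientation is the fused side of each breakend (``+`` = the junction
    continues rightward from the breakend); a fold-back inversion joins
    two nearby loci of one chromosome in the *same* orientation.
    """

    sample_id: str
    sv_type: str
    chrom1: str
    pos1: int
    strand1: str
    chrom2: str
    pos2: int
    strand2: str
    homology_code: int
    n_junctions: int = 2
    foldback: bool = False

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise InputFormatError(f"unknown sv_type {self.sv_type!r}")
        if not (-10 <= self.homology_code <= 10_000):
            raise InputFormatError(f"homology_code out of range: {self.homology_code}")
        if self.n_junctions < 1:
            raise InputFormatError("n_junctions must be >= 1")
        if self.strand1 not in "+-" or self.strand2 not in "+-":
            raise InputFormatError("breakend orientations must be '+' or '-'")
        if self.foldback:
            if self.sv_type != "inversion":
                raise InputFormatError("fold-back junctions must have sv_type=inversion")
            if self.chrom1 != self.chrom2 or self.strand1 != self.strand2:
                raise InputFormatError(
                    "fold-back junctions join one chromosome in equal orientations"
                )


@dataclass(frozen=True)
class CopyNumberSegment:
    """A tumor/normal copy-ratio segment (0-based half-open)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    copy_ratio: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise InputFormatError("segment end must exceed start")
        if self.copy_ratio <= 0:
            raise InputFormatError("copy_ratio must be positive")


# ---------------------------------------------------------------------------
# genome, layout, mask
# ---------------------------------------------------------------------------


class GenomeLayout:
    """Ordered chromosome names, lengths, and telomere coordinates.

    Telomeres are the two termini of each chromosome: position 0 and the
    chromosome length.
    """

    def __init__(self, lengths: Mapping[str, int]):
        if not lengths:
            raise InvalidConfigError("layout needs at least one chromosome")
        if len(set(lengths)) != len(list(lengths)):
            raise InvalidConfigError("chromosome names must be unique")
        for name, length in lengths.items():
            if length <= 0:
                raise InvalidConfigError(f"chromosome {name} has non-positive length")
        self._lengths = dict(lengths)

    @property
    def chromosomes(self) -> list[str]:
        return list(self._lengths)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self._lengths)

    def length(self, chrom: str) -> int:
        return self._lengths[chrom]

    def telomeres(self, chrom: str) -> tuple[int, int]:
        return (0, self._lengths[chrom])

    def telomere_distance(self, chrom: str, pos: int) -> int:
        """Distance (bp) from a 0-based position to the nearer terminus."""
        return min(pos, self._lengths[chrom] - pos)

    @property
    def total_length(self) -> int:
        return sum(self._lengths.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GenomeLayout) and self._lengths == other._lengths

    def __repr__(self) -> str:
        return f"GenomeLayout({len(self._lengths)} chromosomes, {self.total_length} bp)"


class Genome:
    """In-memory reference sequence, one uint8 code array per chromosome."""

    def __init__(self, codes: Mapping[str, np.ndarray]):
        self._codes = {c: np.asarray(a, dtype=np.uint8) for c, a in codes.items()}

    @classmethod
    def from_strings(cls, seqs: Mapping[str, str]) -> "Genome":
        return cls({c: encode_sequence(s) for c, s in seqs.items()})

    @property
    def layout(self) -> GenomeLayout:
        return GenomeLayout({c: len(a) for c, a in self._codes.items()})

    def codes(self, chrom: str) -> np.ndarray:
        return self._codes[chrom]

    def seq(self, chrom: str, start: int, end: int) -> str:
        """0-based half-open slice as an ACGT string."""
        return decode_sequence(self._codes[chrom][start:end])

    def base(self, chrom: str, pos1: int) -> str:
        """Single base at a 1-based position."""
        return BASES[self._codes[chrom][pos1 - 1]]

    def reverse_complement(self) -> "Genome":
        return Genome({c: _COMPLEMENT_CODE[a[::-1]] for c, a in self._codes.items()})

    def __iter__(self) -> Iterator[str]:
        return iter(self._codes)


def encode_sequence(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, 255, dtype=np.uint8)
    for base, code in _BASE_TO_CODE.items():
        codes[arr == ord(base)] = code
    if (codes == 255).any():
        bad = chr(arr[codes == 255][0])
        raise InputFormatError(f"non-ACGT base {bad!r} in sequence")
    return codes


def decode_sequence(codes: np.ndarray) -> str:
    lut = np.frombuffer(BASES.encode("ascii"), dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def _merge_intervals(iv: np.ndarray) -> tuple[np.ndarray, bool]:
    """Sort and merge possibly-overlapping intervals; report if merging occurred."""
    if len(iv) == 0:
        return iv.reshape(0, 2), False
    order = np.lexsort((iv[:, 1], iv[:, 0]))
    iv = iv[order]
    merged = [list(iv[0])]
    did_merge = False
    for s, e in iv[1:]:
        if s <= merged[-1][1]:
            if s < merged[-1][1]:
                did_merge = True
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=np.int64), did_merge


class CoverageMask:
    """Callable intervals per chromosome (0-based half-open, sorted, disjoint).

    The mask is the set of positions that passed the upstream depth filter
    (tumor > 14x and matched normal > 8x in the defining study design);
    every mutation-rate denominator in the pipeline is a callable length
    taken from this mask.
    """

    def __init__(self, intervals: Mapping[str, np.ndarray], layout: GenomeLayout | None = None):
        self._iv: dict[str, np.ndarray] = {}
        for chrom, iv in intervals.items():
            iv = np.asarray(iv, dtype=np.int64).reshape(-1, 2)
            if len(iv) and (iv[:, 1] <= iv[:, 0]).any():
                raise InputFormatError(f"empty/negative mask interval on {chrom}")
            merged, did_merge = _merge_intervals(iv)
            if did_merge:
                warnings.warn(f"overlapping mask intervals on {chrom} merged", stacklevel=2)
            if layout is not None:
                if chrom not in layout:
                    raise InputFormatError(f"mask chromosome {chrom} absent from layout")
                if len(merged) and merged[-1, 1] > layout.length(chrom):
                    raise InputFormatError(f"mask interval exceeds {chrom} length")
            self._iv[chrom] = merged

    @classmethod
    def full(cls, layout: GenomeLayout) -> "CoverageMask":
        return cls({c: np.array([[0, layout.length(c)]]) for c in layout.chromosomes}, layout)

    def intervals(self, chrom: str) -> np.ndarray:
        return self._iv.get(chrom, np.empty((0, 2), dtype=np.int64))

    @property
    def chromosomes(self) -> list[str]:
        return list(self._iv)

    def overlap_length(self, chrom: str, start: int, end: int) -> int:
        """Callable bp inside [start, end)."""
        iv = self.intervals(chrom)
        if len(iv) == 0 or end <= start:
            return 0
        s = np.clip(iv[:, 0], start, end)
        e = np.clip(iv[:, 1], start, end)
        return int(np.maximum(e - s, 0).sum())

    def contains(self, chrom: str, pos0: np.ndarray) -> np.ndarray:
        """Vectorized membership test for 0-based positions."""
        iv = self.intervals(chrom)
        pos0 = np.asarray(pos0)
        if len(iv) == 0:
            return np.zeros(pos0.shape, dtype=bool)
        idx = np.searchsorted(iv[:, 0], pos0, side="right") - 1
        ok = idx >= 0
        safe = np.where(ok, idx, 0)
        return ok & (pos0 < iv[safe, 1])

    @property
    def total_length(self) -> int:
        return int(sum((iv[:, 1] - iv[:, 0]).sum() for iv in self._iv.values()))

    def subtract(self, other_iv: Mapping[str, np.ndarray]) -> "CoverageMask":
        """Return a new mask with the given intervals removed."""
        out: dict[str, np.ndarray] = {}
        for chrom, iv in self._iv.items():
            cut, _ = _merge_intervals(
                np.asarray(other_iv.get(chrom, np.empty((0, 2))), dtype=np.int64).reshape(-1, 2)
            )
            if len(cut) == 0:
                out[chrom] = iv.copy()
                continue
            pieces = []
            for s, e in iv:
                cur = s
                for cs, ce in cut:
                    if ce <= cur or cs >= e:
                        continue
                    if cs > cur:
                        pieces.append((cur, min(cs, e)))
                    cur = max(cur, ce)
                    if cur >= e:
                        break
                if cur < e:
                    pieces.append((cur, e))
            out[chrom] = np.asarray(pieces, dtype=np.int64).reshape(-1, 2)
        return CoverageMask(out)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (chrom, int(s), int(e))
            for chrom, iv in self._iv.items()
            for s, e in iv
        ]
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])


# ---------------------------------------------------------------------------
# catalogs (DataFrame-backed)
# ---------------------------------------------------------------------------

SNV_COLUMNS = ["sample_id", "chrom", "pos", "ref", "alt"]
SV_COLUMNS = [
    "sample_id",
    "sv_type",
    "chrom1",
    "pos1",
    "strand1",
    "chrom2",
    "pos2",
    "strand2",
    "homology_code",
    "n_junctions",
    "foldback",
]
SEGMENT_COLUMNS = ["sample_id", "chrom", "start", "end", "copy_ratio"]


class SnvCatalog:
    """Cohort of somatic SNVs, stored columnar for vectorized analysis."""

    def __init__(self, df: pd.DataFrame, layout: GenomeLayout | None = None):
        df = df.reindex(columns=SNV_COLUMNS).reset_index(drop=True)
        if len(df):
            if (df["ref"] == df["alt"]).any():
                raise InputFormatError("SNV with ref == alt")
            if not df["ref"].isin(list(BASES)).all() or not df["alt"].isin(list(BASES)).all():
                raise InputFormatError("SNV alleles must be single ACGT bases")
            df["pos"] = df["pos"].astype(np.int64)
            if (df["pos"] < 1).any():
                raise InputFormatError("SNV positions are 1-based (>= 1)")
            if layout is not None:
                for chrom, sub in df.groupby("chrom", sort=False):
                    if chrom not in layout:
                        raise InputFormatError(f"SNV chromosome {chrom} absent from layout")
                    if int(sub["pos"].max()) > layout.length(str(chrom)):
                        raise InputFormatError(f"SNV beyond end of {chrom}")
        self.df = df

    @classmethod
    def from_records(cls, records: Iterable[SnvRecord], layout: GenomeLayout | None = None):
        rows = [(r.sample_id, r.chrom, r.pos, r.ref, r.alt) for r in records]
        return cls(pd.DataFrame(rows, columns=SNV_COLUMNS), layout)

    @classmethod
    def empty(cls) -> "SnvCatalog":
        return cls(pd.DataFrame(columns=SNV_COLUMNS))

    def records(self) -> Iterator[SnvRecord]:
        for row in self.df.itertuples(index=False):
            yield SnvRecord(row.sample_id, row.chrom, int(row.pos), row.ref, row.alt)

    @property
    def samples(self) -> list[str]:
        return sorted(self.df["sample_id"].unique())

    def for_sample(self, sample_id: str) -> pd.DataFrame:
        return self.df[self.df["sample_id"] == sample_id]

    def __len__(self) -> int:
        return len(self.df)


class SvCatalog:
    """Cohort of somatic SV breakpoint junctions."""

    def __init__(self, df: pd.DataFrame, layout: GenomeLayout | None = None):
        df = df.reindex(columns=SV_COLUMNS).reset_index(drop=True)
        if len(df):
            df["pos1"] = df["pos1"].astype(np.int64)
            df["pos2"] = df["pos2"].astype(np.int64)
            df["homology_code"] = df["homology_code"].astype(np.int64)
            df["n_junctions"] = df["n_junctions"].astype(np.int64)
            df["foldback"] = df["foldback"].astype(bool)
            if not df["sv_type"].isin(SV_TYPES).all():
                bad = df.loc[~df["sv_type"].isin(SV_TYPES), "sv_type"].iloc[0]
                raise InputFormatError(f"unknown sv_type {bad!r}")
            if ((df["homology_code"] < -10) | (df["homology_code"] > 10_000)).any():
                raise InputFormatError("homology_code out of range [-10, 10000]")
            fb = df[df["foldback"]]
            if len(fb):
                ok = (
                    (fb["sv_type"] == "inversion")
                    & (fb["chrom1"] == fb["chrom2"])
                    & (fb["strand1"] == fb["strand2"])
                )
                if not ok.all():
                    raise InputFormatError(
                        "fold-back junctions must be same-chromosome same-orientation inversions"
                    )
            if layout is not None:
                for col_c, col_p in (("chrom1", "pos1"), ("chrom2", "pos2")):
                    for chrom, sub in df.groupby(col_c, sort=False):
                        if chrom not in layout:
                            raise InputFormatError(f"SV chromosome {chrom} absent from layout")
                        if int(sub[col_p].max()) > layout.length(str(chrom)):
                            raise InputFormatError(f"SV breakend beyond end of {chrom}")
        self.df = df

    @classmethod
    def from_records(cls, records: Iterable[SvRecord], layout: GenomeLayout | None = None):
        rows = [
            (
                r.sample_id, r.sv_type, r.chrom1, r.pos1, r.strand1,
                r.chrom2, r.pos2, r.strand2, r.homology_code, r.n_junctions, r.foldback,
            )
            for r in records
        ]
        return cls(pd.DataFrame(rows, columns=SV_COLUMNS), layout)

    @classmethod
    def empty(cls) -> "SvCatalog":
        return cls(pd.DataFrame(columns=SV_COLUMNS))

    def records(self) -> Iterator[SvRecord]:
        for row in self.df.itertuples(index=False):
            yield SvRecord(
                row.sample_id, row.sv_type, row.chrom1, int(row.pos1), row.strand1,
                row.chrom2, int(row.pos2), row.strand2, int(row.homology_code),
                int(row.n_junctions), bool(row.foldback),
            )

    @property
    def samples(self) -> list[str]:
        return sorted(self.df["sample_id"].unique())

    def for_sample(self, sample_id: str) -> pd.DataFrame:
        return self.df[self.df["sample_id"] == sample_id]

    def breakends(self) -> pd.DataFrame:
        """Long-form table with one row per breakend (1-based pos)."""
        a = self.df[["sample_id", "chrom1", "pos1", "strand1"]].rename(
            columns={"chrom1": "chrom", "pos1": "pos", "strand1": "strand"}
        )
        b = self.df[["sample_id", "chrom2", "pos2", "strand2"]].rename(
            columns={"chrom2": "chrom", "pos2": "pos", "strand2": "strand"}
        )
        a = a.assign(breakend=1, sv_index=self.df.index)
        b = b.assign(breakend=2, sv_index=self.df.index)
        return pd.concat([a, b], ignore_index=True)

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class RegionAnnotations:
    """Labeled regulatory intervals (0-based half-open) with target genes."""

    df: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["chrom", "start", "end", "label", "gene"])
    )

    def __post_init__(self) -> None:
        self.df = self.df.reindex(columns=["chrom", "start", "end", "label", "gene"])
        if len(self.df):
            if not self.df["label"].isin(ANNOTATION_CLASSES).all():
                bad = self.df.loc[~self.df["label"].isin(ANNOTATION_CLASSES), "label"].iloc[0]
                raise InputFormatError(f"unknown annotation class {bad!r}")
            self.df["start"] = self.df["start"].astype(np.int64)
            self.df["end"] = self.df["end"].astype(np.int64)

    def of_class(self, label: str) -> pd.DataFrame:
        return self.df[self.df["label"] == label]

    @property
    def blacklist(self) -> pd.DataFrame:
        return self.of_class("blacklist")

    @property
    def regulatory(self) -> pd.DataFrame:
        return self.df[self.df["label"] != "blacklist"]
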