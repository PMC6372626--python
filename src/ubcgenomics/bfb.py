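"""Breakage-fusion-bridge (BFB) detection from fold-back inversions.

A BFB cycle — telomere loss, sister-chromatid fusion, anaphase breakage —
leaves a characteristic footprint: fold-back inversion junctions (two
nearby loci of one chromosome joined in the same orientation), copy-number
amplification stepping at the junctions, and proximity to a chromosome
terminus.  An event is called per sample and chromosome when at least two
fold-back junctions each satisfy all of:

1. fold-back inversion (same chromosome, equal breakend orientations);
2. breakend separation < 20 kb;
3. a significant copy-number change at the junction, quantified as a
   >= ``cn_fold_min`` (default 2.0) fold change between the mean copy
   ratios of the two 100 kb windows flanking the junction;
4. junction within ``telomere_margin`` (default 5 Mb) of a chromosome end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import GenomeLayout, SvCatalog

JUNCTION_COLUMNS = [
    "sample_id", "chrom", "pos1", "pos2", "separation",
    "left_ratio", "right_ratio", "cn_fold_change", "telomere_distance", "passes",
]


@dataclass
class BfbEvent:
    sample_id: str
    chrom: str
    junctions: pd.DataFrame = field(repr=False)  # passing junctions with metrics

    @property
    def n_junctions(self) -> int:
        return len(self.junctions)


def find_foldbacks(catalog: SvCatalog, max_sep: int = 20_000) -> pd.DataFrame:
    """Fold-back junctions with breakend separation below ``max_sep``."""
    df = catalog.df
    fb = df[df["foldback"]].copy()
    fb["separation"] = (fb["pos2"] - fb["pos1"]).abs()
    return fb[fb["separation"] < max_sep].reset_index(drop=True)


def flank_copy_ratio(
    segments: pd.DataFrame, chrom: str, pos0: int, flank: int = 100_000
) -> tuple[float, float]:
    """Length-weighted mean copy ratio of the two windows flanking ``pos0``.

    ``segments`` is one sample's table (chrom, start, end, copy_ratio,
    0-based half-open).  Returns NaN for a window with no coverage.
    """
    sub = segments[segments["chrom"] == chrom]

    def window_mean(ws: int, we: int) -> float:
        if we <= ws or sub.empty:
            return float("nan")
        s = np.maximum(sub["start"].to_numpy(), ws)
        e = np.minimum(sub["end"].to_numpy(), we)
        w = np.maximum(e - s, 0).astype(float)
        if w.sum() == 0:
            return float("nan")
        return float((w * sub["copy_ratio"].to_numpy()).sum() / w.sum())

    return window_mean(pos0 - flank, pos0), window_mean(pos0, pos0 + flank)


def call_bfb(
    catalog: SvCatalog,
    segments: pd.DataFrame,
    layout: GenomeLayout,
    cn_fold_min: float = 2.0,
    telomere_margin: int = 5_000_000,
    foldback_max_sep: int = 20_000,
    flank: int = 100_000,
) -> tuple[list[BfbEvent], pd.DataFrame]:
    """Detect BFB events; returns (events, per-junction metric table).

    Junction copy-number change is measured at the junction midpoint;
    telomere distance is the smaller distance of either breakend to
    either chromosome terminus.  Junctions at loci with no copy-number
    coverage are excluded with a warning.  A sample that has fold-back
    junctions but no copy-number segments at all raises an error.
    """
    fb = find_foldbacks(catalog, foldback_max_sep)
    rows = []
    for row in fb.itertuples(index=False):
        sample_segments = segments[segments["sample_id"] == row.sample_id]
        if sample_segments.empty:
            raise ValueError(f"no copy-number segments for sample {row.sample_id}")
        mid0 = (int(row.pos1) + int(row.pos2)) // 2 - 1
        left, right = flank_copy_ratio(sample_segments, row.chrom1, mid0, flank)
        if np.isnan(left) or np.isnan(right):
            import warnings

            warnings.warn(
                f"fold-back at {row.chrom1}:{row.pos1} of {row.sample_id} lacks "
                "copy-number coverage; junction excluded",
                stacklevel=2,
            )
            continue
        fold = max(left / right, right / left)
        tel = min(
            layout.telomere_distance(row.chrom1, int(row.pos1)),
            layout.telomere_distance(row.chrom1, int(row.pos2)),
        )
        passes = fold >= cn_fold_min and tel <= telomere_margin
        rows.append(
            (row.sample_id, row.chrom1, int(row.pos1), int(row.pos2), int(row.separation),
             left, right, fold, int(tel), passes)
        )
    junctions = pd.DataFrame(rows, columns=JUNCTION_COLUMNS)
    events = []
    if len(junctions):
        passing = junctions[junctions["passes"]]
        for (sample, chrom), grp in passing.groupby(["sample_id", "chrom"], sort=True):
            if len(grp) >= 2:
                events.append(
                    BfbEvent(sample_id=str(sample), chrom=str(chrom),
                             junctions=grp.reset_index(drop=True))
                )
    return events, junctions


def events_frame(events: list[BfbEvent]) -> pd.DataFrame:
    """Flatten events to one row per passing junction, for reporting."""
    if not events:
        return pd.DataFrame(columns=["event_id"] + JUNCTION_COLUMNS)
    parts = []
    for i, ev in enumerate(events):
        part = ev.junctions.copy()
        part.insert(0, "event_id", f"{ev.sample_id}:{ev.chrom}")
        parts.append(part)
    return pd.concat(parts, ignore_index=True)


def validate_event(
    event: BfbEvent,
    catalog: SvCatalog,
    segments: pd.DataFrame,
    layout: GenomeLayout,
    cn_fold_min: float = 2.0,
    telomere_margin: int = 5_000_000,
    foldback_max_sep: int = 20_000,
    flank: int = 100_000,
) -> bool:
    """Independently re-check the four BFB standards for one emitted event.

    Works from the raw catalog and segment table with its own arithmetic,
    not from the detector's intermediate tables.
    """
    if len(event.junctions) < 2:
        return False
    raw = catalog.df
    seg = segments[
        (segments["sample_id"] == event.sample_id) & (segments["chrom"] == event.chrom)
    ]
    L = layout.length(event.chrom)
    for j in event.junctions.itertuples(index=False):
        match = raw[
            (raw["sample_id"] == event.sample_id)
            & (raw["chrom1"] == event.chrom)
            & (raw["pos1"] == j.pos1)
            & (raw["pos2"] == j.pos2)
        ]
        # standard 1: a fold-back inversion exists in the catalog
        if not ((match["foldback"]) & (match["strand1"] == match["strand2"])).any():
            return False
        # standard 2: breakends < 20 kb apart
        if abs(j.pos2 - j.pos1) >= foldback_max_sep:
            return False
        # standard 3: flank copy-ratio fold change at the junction
        mid = (j.pos1 + j.pos2) // 2 - 1

        def mean_ratio(a: int, b: int) -> float:
            total, weight = 0.0, 0.0
            for s in seg.itertuples(index=False):
                lo, hi = max(s.start, a), min(s.end, b)
                if hi > lo:
                    total += (hi - lo) * s.copy_ratio
                    weight += hi - lo
            return total / weight if weight else float("nan")

        lm = mean_ratio(mid - flank, mid)
        rm = mean_ratio(mid, mid + flank)
        if not (lm > 0 and rm > 0):
            return False
        if max(lm / rm, rm / lm) < cn_fold_min:
            return False
        # standard 4: adjacent to a telomere
        dist = min(j.pos1, j.pos2, L - j.pos1, L - j.pos2)
        if dist > telomere_margin:
            return False
    return True
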