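"""Binomial recurrence scan for hypermutated 1 kb genomic tiles.

The genome is divided into coterminous 1 kb tiles and the pooled count of
somatic events (SNVs and/or SV breakends, all samples) in each tile is
tested against two backgrounds:

* **local** — the 1 Mb flanking region (500 kb upstream + 500 kb
  downstream, truncated at chromosome ends, tile excluded), and
* **global** — the whole callable genome minus the tile.

Under the null each pooled event falls into the tile with probability
``p0 = effective_tile_length / effective_total_length`` where effective
lengths are callable base pairs from the coverage mask, so the tile count
is Binomial(k_total, p0) and the reported p-value is its upper tail.
Benjamini-Hochberg adjustment is applied separately per approach across
all tiles with at least one event; a region is called significant when
both adjusted values fall below ``alpha``.  Tiles overlapping blacklist
intervals are removed before testing, and blacklist base pairs are
excluded from event counting and from every effective length.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .types import CoverageMask, GenomeLayout, RegionAnnotations, SnvCatalog, SvCatalog

RESULT_COLUMNS = [
    "chrom", "start", "end", "effective_length",
    "k_region", "n_samples_hit",
    "k_background_local", "eff_len_local",
    "k_background_global", "eff_len_global",
    "p_local", "p_global", "q_local", "q_global",
    "significant", "annotation_classes", "genes",
]


def tile_genome(layout: GenomeLayout, mask: CoverageMask, width: int = 1000) -> pd.DataFrame:
    """Coterminous tiles covering every chromosome, with callable lengths.

    Tiles abut and do not overlap; the terminal tile of a chromosome keeps
    the remainder width.
    """
    rows = []
    for chrom in layout.chromosomes:
        length = layout.length(chrom)
        starts = np.arange(0, length, width, dtype=np.int64)
        ends = np.minimum(starts + width, length)
        iv = mask.intervals(chrom)
        if len(iv):
            # callable bp per tile via cumulative mask coverage at tile edges
            bounds = np.concatenate([starts, [length]])
            cum = np.zeros(len(bounds), dtype=np.int64)
            for j, b in enumerate(bounds):
                s = np.clip(iv[:, 0], 0, b)
                e = np.clip(iv[:, 1], 0, b)
                cum[j] = np.maximum(e - s, 0).sum()
            eff = np.diff(cum)
        else:
            eff = np.zeros(len(starts), dtype=np.int64)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends,
                                  "effective_length": eff}))
    return pd.concat(rows, ignore_index=True)


def _event_table(
    snvs: SnvCatalog, svs: SvCatalog, mask: CoverageMask, mode: str = "combined"
) -> pd.DataFrame:
    """Pooled events (0-based positions) inside the mask.

    Each SV contributes up to two breakend events; events at positions
    outside the callable mask are excluded.
    """
    if mode not in ("snv", "sv", "combined"):
        raise ValueError(f"unknown counting mode {mode!r}")
    parts = []
    if mode in ("snv", "combined") and len(snvs):
        parts.append(snvs.df[["sample_id", "chrom", "pos"]])
    if mode in ("sv", "combined") and len(svs):
        parts.append(svs.breakends()[["sample_id", "chrom", "pos"]])
    if not parts:
        return pd.DataFrame(columns=["sample_id", "chrom", "pos0"])
    ev = pd.concat(parts, ignore_index=True)
    ev["pos0"] = ev["pos"].astype(np.int64) - 1
    keep = np.zeros(len(ev), dtype=bool)
    for chrom, sub in ev.groupby("chrom", sort=False):
        keep[sub.index] = mask.contains(str(chrom), sub["pos0"].to_numpy())
    return ev.loc[keep, ["sample_id", "chrom", "pos0"]].reset_index(drop=True)


def count_events(
    tiles: pd.DataFrame,
    snvs: SnvCatalog,
    svs: SvCatalog,
    mask: CoverageMask,
    mode: str = "combined",
    width: int = 1000,
) -> pd.DataFrame:
    """Per-tile pooled event count and number of distinct samples hit."""
    ev = _event_table(snvs, svs, mask, mode)
    tiles = tiles.copy()
    tiles["k_region"] = 0
    tiles["n_samples_hit"] = 0
    for chrom, sub in ev.groupby("chrom", sort=False):
        sel = tiles["chrom"] == chrom
        idx = tiles.index[sel]
        n_tiles = len(idx)
        tile_of = (sub["pos0"] // width).astype(np.int64)
        tile_of = tile_of[tile_of < n_tiles]
        counts = np.bincount(tile_of, minlength=n_tiles)
        tiles.loc[idx, "k_region"] = counts
        hits = (
            sub.assign(tile=tile_of)
            .dropna(subset=["tile"])
            .groupby("tile")["sample_id"]
            .nunique()
        )
        tiles.loc[idx[hits.index.astype(int)], "n_samples_hit"] = hits.to_numpy()
    return tiles


def binomial_region_test(
    k_region: int, k_total: int, eff_len_region: int, eff_len_total: int
) -> float:
    """Upper-tail binomial p-value P(X >= k_region), X ~ Bin(k_total, p0).

    ``p0 = eff_len_region / eff_len_total``: under the null each pooled
    event lands in the region with probability proportional to its
    callable length.
    """
    if eff_len_region <= 0:
        if k_region > 0:
            raise ValueError("events in a region with zero callable length (inconsistent mask)")
        return 1.0
    if eff_len_total < eff_len_region:
        raise ValueError("background length smaller than region length")
    if k_total < k_region:
        raise ValueError("k_total must include the region's events")
    if k_region <= 0:
        return 1.0
    p0 = eff_len_region / eff_len_total
    return float(sps.binom.sf(k_region - 1, k_total, p0))


def _overlapping_tiles(tiles: pd.DataFrame, intervals: pd.DataFrame) -> np.ndarray:
    """Boolean: tile overlaps any of the given (chrom,start,end) intervals."""
    hit = np.zeros(len(tiles), dtype=bool)
    for chrom, sub in intervals.groupby("chrom", sort=False):
        sel = (tiles["chrom"] == chrom).to_numpy()
        if not sel.any():
            continue
        ts = tiles.loc[sel, "start"].to_numpy()
        te = tiles.loc[sel, "end"].to_numpy()
        local = np.zeros(sel.sum(), dtype=bool)
        for s, e in sub[["start", "end"]].to_numpy():
            local |= (ts < e) & (te > s)
        hit[sel] = local
    return hit


def scan(
    snvs: SnvCatalog,
    svs: SvCatalog,
    layout: GenomeLayout,
    mask: CoverageMask,
    annotations: RegionAnnotations | None = None,
    alpha: float = 0.05,
    width: int = 1000,
    flank: int = 500_000,
    mode: str = "combined",
    restrict_to_annotations: bool = False,
) -> pd.DataFrame:
    """Run the dual-background recurrence scan over the whole genome.

    Returns one row per tested tile (pooled count > 0) with local/global
    p- and q-values, the ``significant`` flag (both q < alpha), and the
    regulatory classes and target genes overlapping the tile.
    """
    if mask.total_length == 0:
        raise ValueError("coverage mask is empty")
    if annotations is None:
        annotations = RegionAnnotations()
    blacklist = annotations.blacklist
    working_mask = mask
    if len(blacklist):
        working_mask = mask.subtract(
            {c: sub[["start", "end"]].to_numpy() for c, sub in blacklist.groupby("chrom")}
        )

    tiles = tile_genome(layout, working_mask, width)
    tiles = count_events(tiles, snvs, svs, working_mask, mode, width)

    tested = (tiles["k_region"] > 0) & (tiles["effective_length"] > 0)
    if len(blacklist):
        tested &= ~_overlapping_tiles(tiles, blacklist)
    if restrict_to_annotations:
        tested &= _overlapping_tiles(tiles, annotations.regulatory)
    tiles = tiles[tested].reset_index(drop=True)
    if tiles.empty:
        return pd.DataFrame(columns=RESULT_COLUMNS)

    ev = _event_table(snvs, svs, working_mask, mode)
    pos_by_chrom = {
        str(chrom): np.sort(sub["pos0"].to_numpy())
        for chrom, sub in ev.groupby("chrom", sort=False)
    }
    k_genome = len(ev)
    eff_genome = working_mask.total_length

    def flank_stats(chrom: str, start: int, end: int) -> tuple[int, int]:
        pos = pos_by_chrom.get(chrom, np.empty(0, dtype=np.int64))
        length = layout.length(chrom)
        ls, le = max(0, start - flank), start
        rs, re = end, min(length, end + flank)
        k = int(np.searchsorted(pos, le) - np.searchsorted(pos, ls))
        k += int(np.searchsorted(pos, re) - np.searchsorted(pos, rs))
        eff = working_mask.overlap_length(chrom, ls, le)
        eff += working_mask.overlap_length(chrom, rs, re)
        return k, eff

    p_local = np.empty(len(tiles))
    p_global = np.empty(len(tiles))
    k_bg_local = np.empty(len(tiles), dtype=np.int64)
    eff_local = np.empty(len(tiles), dtype=np.int64)
    for i, row in enumerate(tiles.itertuples(index=False)):
        k_flank, eff_flank = flank_stats(str(row.chrom), int(row.start), int(row.end))
        k_bg_local[i] = k_flank
        eff_local[i] = eff_flank
        p_local[i] = binomial_region_test(
            int(row.k_region), int(row.k_region) + k_flank,
            int(row.effective_length), int(row.effective_length) + eff_flank,
        )
        p_global[i] = binomial_region_test(
            int(row.k_region), k_genome, int(row.effective_length), eff_genome
        )
    q_local = multipletests(p_local, method="fdr_bh")[1]
    q_global = multipletests(p_global, method="fdr_bh")[1]

    tiles["k_background_local"] = k_bg_local
    tiles["eff_len_local"] = eff_local
    tiles["k_background_global"] = k_genome - tiles["k_region"]
    tiles["eff_len_global"] = eff_genome - tiles["effective_length"]
    tiles["p_local"] = p_local
    tiles["p_global"] = p_global
    tiles["q_local"] = q_local
    tiles["q_global"] = q_global
    tiles["significant"] = (q_local < alpha) & (q_global < alpha)

    classes = [""] * len(tiles)
    genes = [""] * len(tiles)
    reg = annotations.regulatory
    if len(reg):
        for i, row in enumerate(tiles.itertuples(index=False)):
            sub = reg[
                (reg["chrom"] == row.chrom)
                & (reg["start"] < row.end)
                & (reg["end"] > row.start)
            ]
            if len(sub):
                classes[i] = ",".join(sorted(set(sub["label"])))
                genes[i] = ",".join(sorted({g for g in sub["gene"] if g}))
    tiles["annotation_classes"] = classes
    tiles["genes"] = genes
    return tiles.reindex(columns=RESULT_COLUMNS)


def significant_regions(results: pd.DataFrame) -> pd.DataFrame:
    return results[results["significant"]].reset_index(drop=True)
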