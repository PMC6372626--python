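"""Per-sample detection of kataegis (localized somatic hypermutation).

A kataegis event is called from three conjunctive rules:

1. a maximal run of six or more consecutive same-sample mutations with
   every intermutation distance <= 1 kb;
2. a cluster mutation rate significantly higher (one-sided binomial,
   p < alpha for both tests) than the pooled rate of the two 50 kb
   flanking windows and than the sample's genome-wide rate, all rates
   using callable lengths from the coverage mask;
3. at least one same-sample SV breakend within ``sv_window`` (default
   50 kb) of the cluster span — the rearrangement-adjacency requirement.

No multiplicity correction is applied across candidates: the rate test is
one screen inside a conjunction of three filters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import CoverageMask, GenomeLayout, SnvCatalog, SvCatalog

EVENT_COLUMNS = [
    "sample_id", "chrom", "start", "end", "n_mutations", "max_spacing",
    "p_vs_flank", "p_vs_genome", "nearest_sv_distance", "flank_test_skipped",
]


@dataclass(frozen=True)
class KataegisEvent:
    sample_id: str
    chrom: str
    start: int  # 1-based first mutation position
    end: int  # 1-based last mutation position
    n_mutations: int
    max_spacing: int
    p_vs_flank: float
    p_vs_genome: float
    nearest_sv_distance: int
    flank_test_skipped: bool = False


def find_candidate_clusters(
    positions: np.ndarray, max_spacing: int = 1000, min_mutations: int = 6
) -> list[tuple[int, int]]:
    """Maximal runs (start_idx, end_idx inclusive) of closely spaced positions.

    ``positions`` must be sorted.  Runs are maximal by construction:
    extending a run on either side would cross a gap > ``max_spacing``.
    """
    positions = np.asarray(positions)
    if len(positions) < min_mutations:
        return []
    gaps = np.diff(positions)
    breaks = np.flatnonzero(gaps > max_spacing)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(positions) - 1]])
    return [(int(s), int(e)) for s, e in zip(starts, ends) if e - s + 1 >= min_mutations]


def cluster_rate_test(
    positions: np.ndarray,
    run: tuple[int, int],
    sample_positions_by_chrom: dict[str, np.ndarray],
    chrom: str,
    mask: CoverageMask,
    layout: GenomeLayout,
    flank_bp: int = 50_000,
) -> tuple[float, float, bool]:
    """One-sided binomial tests of a candidate's rate vs flanks and genome.

    Returns ``(p_vs_flank, p_vs_genome, flank_skipped)``.  When both 50 kb
    flanks have zero callable length the flank test is skipped (p = NaN
    reported, genome test decides) and flagged.
    """
    s_idx, e_idx = run
    first0 = int(positions[s_idx]) - 1
    last0 = int(positions[e_idx]) - 1
    span_start, span_end = first0, max(last0 + 1, first0 + 1)  # >= 1 bp
    k_cluster = e_idx - s_idx + 1
    eff_cluster = max(mask.overlap_length(chrom, span_start, span_end), 1)

    length = layout.length(chrom)
    ls, le = max(0, span_start - flank_bp), span_start
    rs, re = span_end, min(length, span_end + flank_bp)
    chrom_pos0 = sample_positions_by_chrom.get(chrom, np.empty(0, np.int64)) - 1
    chrom_pos0 = np.sort(chrom_pos0)
    k_flank = int(np.searchsorted(chrom_pos0, le) - np.searchsorted(chrom_pos0, ls))
    k_flank += int(np.searchsorted(chrom_pos0, re) - np.searchsorted(chrom_pos0, rs))
    eff_flank = mask.overlap_length(chrom, ls, le) + mask.overlap_length(chrom, rs, re)

    flank_skipped = eff_flank == 0
    if flank_skipped:
        p_flank = float("nan")
    else:
        p0 = eff_cluster / (eff_cluster + eff_flank)
        p_flank = float(sps.binom.sf(k_cluster - 1, k_cluster + k_flank, p0))

    k_genome = int(sum(len(v) for v in sample_positions_by_chrom.values()))
    eff_genome = mask.total_length
    p0g = eff_cluster / eff_genome
    p_genome = float(sps.binom.sf(k_cluster - 1, k_genome, p0g))
    return p_flank, p_genome, flank_skipped


def call_kataegis(
    snvs: SnvCatalog,
    svs: SvCatalog,
    mask: CoverageMask,
    layout: GenomeLayout,
    alpha: float = 0.05,
    sv_window: int = 50_000,
    max_spacing: int = 1000,
    min_mutations: int = 6,
    flank_bp: int = 50_000,
) -> pd.DataFrame:
    """Apply all three rules per sample; returns one row per called event."""
    rows = []
    sv_breakends = svs.breakends() if len(svs) else pd.DataFrame(
        columns=["sample_id", "chrom", "pos"]
    )
    for sample in snvs.samples:
        sub = snvs.for_sample(sample)
        pos_by_chrom = {
            str(c): np.sort(g["pos"].to_numpy(np.int64))
            for c, g in sub.groupby("chrom", sort=False)
        }
        sample_sv = sv_breakends[sv_breakends["sample_id"] == sample]
        for chrom, positions in pos_by_chrom.items():
            runs = find_candidate_clusters(positions, max_spacing, min_mutations)
            for run in runs:
                p_flank, p_genome, skipped = cluster_rate_test(
                    positions, run, pos_by_chrom, chrom, mask, layout, flank_bp
                )
                if p_genome >= alpha:
                    continue
                if not skipped and p_flank >= alpha:
                    continue
                start = int(positions[run[0]])
                end = int(positions[run[1]])
                bp = sample_sv[sample_sv["chrom"] == chrom]["pos"].to_numpy(np.int64)
                if len(bp) == 0:
                    continue
                dist = np.where(
                    (bp >= start) & (bp <= end), 0,
                    np.minimum(np.abs(bp - start), np.abs(bp - end)),
                )
                nearest = int(dist.min())
                if nearest > sv_window:
                    continue
                spac = np.diff(positions[run[0]: run[1] + 1])
                rows.append(
                    (sample, chrom, start, end, run[1] - run[0] + 1,
                     int(spac.max()) if len(spac) else 0,
                     p_flank, p_genome, nearest, skipped)
                )
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


# ---------------------------------------------------------------------------
# independent validator (shares no detection logic with the caller above)
# ---------------------------------------------------------------------------


def validate_event(
    event, snvs: SnvCatalog, svs: SvCatalog, mask: CoverageMask, layout: GenomeLayout,
    alpha: float = 0.05, sv_window: int = 50_000,
) -> bool:
    """Re-check the three kataegis rules for one emitted event from raw data.

    The binomial tails are recomputed by explicit pmf summation rather
    than a survival-function call, and mutation counting is re-derived
    from the raw catalog.
    """
    sample = event.sample_id
    sub = snvs.for_sample(sample)
    on_chrom = sorted(int(p) for p in sub[sub["chrom"] == event.chrom]["pos"])
    inside = [p for p in on_chrom if event.start <= p <= event.end]
    # rule 1: >= 6 mutations, every adjacent spacing <= 1 kb, run maximal
    if len(inside) < 6:
        return False
    if any(b - a > 1000 for a, b in zip(inside, inside[1:])):
        return False
    before = [p for p in on_chrom if p < event.start]
    after = [p for p in on_chrom if p > event.end]
    if before and inside[0] - before[-1] <= 1000:
        return False
    if after and after[0] - inside[-1] <= 1000:
        return False

    def binom_tail(k: int, n: int, p: float) -> float:
        xs = np.arange(k, n + 1)
        return float(min(sps.binom.pmf(xs, n, p).sum(), 1.0))

    span_s0, span_e0 = event.start - 1, event.end
    eff_c = max(mask.overlap_length(event.chrom, span_s0, span_e0), 1)
    L = layout.length(event.chrom)
    ls, le = max(0, span_s0 - 50_000), span_s0
    rs, re = span_e0, min(L, span_e0 + 50_000)
    k_flank = sum(1 for p in on_chrom if ls < p <= le or rs < p <= re)
    eff_f = mask.overlap_length(event.chrom, ls, le) + mask.overlap_length(event.chrom, rs, re)
    if eff_f > 0:
        p_f = binom_tail(len(inside), len(inside) + k_flank, eff_c / (eff_c + eff_f))
        if p_f >= alpha:
            return False
    n_genome = len(sub)
    p_g = binom_tail(len(inside), n_genome, eff_c / mask.total_length)
    if p_g >= alpha:
        return False
    # rule 3: a same-sample breakend within the window
    bes = svs.breakends()
    bes = bes[(bes["sample_id"] == sample) & (bes["chrom"] == event.chrom)]
    ok = False
    for p in bes["pos"]:
        d = 0 if event.start <= p <= event.end else min(abs(p - event.start), abs(p - event.end))
        if d <= sv_window:
            ok = True
            break
    return ok
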