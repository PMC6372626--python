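"""Genome tiling, event counting, binomial tails, BH, and the dual scan."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import bh_stepup, binom_tail_bruteforce
from statsmodels.stats.multitest import multipletests

from ubcgenomics import recurrence, synthetic
from ubcgenomics.types import (
    CoverageMask,
    GenomeLayout,
    RegionAnnotations,
    SnvCatalog,
    SnvRecord,
    SvCatalog,
    SvRecord,
)


class TestTiling:
    def test_exact_division(self):
        layout = GenomeLayout({"chr1": 10_000})
        tiles = recurrence.tile_genome(layout, CoverageMask.full(layout))
        assert len(tiles) == 10
        assert (tiles["end"] - tiles["start"] == 1000).all()
        assert (tiles["effective_length"] == 1000).all()

    def test_terminal_remainder(self):
        layout = GenomeLayout({"chr1": 10_500})
        tiles = recurrence.tile_genome(layout, CoverageMask.full(layout))
        assert len(tiles) == 11
        assert int(tiles.iloc[-1]["end"] - tiles.iloc[-1]["start"]) == 500

    def test_half_masked_tile(self):
        layout = GenomeLayout({"chr1": 2000})
        mask = CoverageMask({"chr1": np.array([[0, 500], [1000, 2000]])}, layout)
        tiles = recurrence.tile_genome(layout, mask)
        assert list(tiles["effective_length"]) == [500, 1000]

    def test_tiles_abut_without_overlap(self):
        layout = GenomeLayout({"chr1": 5_300, "chr2": 1_000})
        tiles = recurrence.tile_genome(layout, CoverageMask.full(layout))
        for _, sub in tiles.groupby("chrom"):
            assert (sub["start"].to_numpy()[1:] == sub["end"].to_numpy()[:-1]).all()


class TestCounting:
    def test_no_events_all_zero(self):
        layout = GenomeLayout({"chr1": 5_000})
        mask = CoverageMask.full(layout)
        tiles = recurrence.tile_genome(layout, mask)
        out = recurrence.count_events(tiles, SnvCatalog.empty(), SvCatalog.empty(), mask)
        assert out["k_region"].sum() == 0 and out["n_samples_hit"].sum() == 0

    def test_sv_contributes_two_breakends_one_sample(self):
        layout = GenomeLayout({"chr1": 5_000})
        mask = CoverageMask.full(layout)
        tiles = recurrence.tile_genome(layout, mask)
        svs = SvCatalog.from_records(
            [SvRecord("S0", "deletion", "chr1", 1100, "+", "chr1", 1900, "-", 0)]
        )
        out = recurrence.count_events(tiles, SnvCatalog.empty(), svs, mask)
        row = out[out["start"] == 1000].iloc[0]
        assert row["k_region"] == 2 and row["n_samples_hit"] == 1

    def test_masked_out_event_not_counted(self):
        layout = GenomeLayout({"chr1": 5_000})
        mask = CoverageMask({"chr1": np.array([[0, 1000]])}, layout)
        tiles = recurrence.tile_genome(layout, mask)
        snvs = SnvCatalog.from_records([SnvRecord("S0", "chr1", 2500, "A", "C")])
        out = recurrence.count_events(tiles, snvs, SvCatalog.empty(), mask)
        assert out["k_region"].sum() == 0

    def test_mode_selects_event_classes(self):
        layout = GenomeLayout({"chr1": 5_000})
        mask = CoverageMask.full(layout)
        tiles = recurrence.tile_genome(layout, mask)
        snvs = SnvCatalog.from_records([SnvRecord("S0", "chr1", 100, "A", "C")])
        svs = SvCatalog.from_records(
            [SvRecord("S1", "deletion", "chr1", 200, "+", "chr1", 4900, "-", 0)]
        )
        assert recurrence.count_events(tiles, snvs, svs, mask, "snv")["k_region"].sum() == 1
        assert recurrence.count_events(tiles, snvs, svs, mask, "sv")["k_region"].sum() == 2
        assert recurrence.count_events(tiles, snvs, svs, mask, "combined")["k_region"].sum() == 3


class TestBinomialTest:
    def test_zero_count_gives_one(self):
        assert recurrence.binomial_region_test(0, 100, 1000, 10_000) == 1.0

    def test_closed_form_two_of_two(self):
        assert recurrence.binomial_region_test(2, 2, 500, 1000) == pytest.approx(0.25)

    def test_matches_bruteforce_tail(self):
        p = recurrence.binomial_region_test(3, 10, 1, 1000)
        assert p == pytest.approx(binom_tail_bruteforce(3, 10, 0.001), abs=1e-15)

    def test_inconsistent_mask_rejected(self):
        with pytest.raises(ValueError):
            recurrence.binomial_region_test(5, 10, 0, 1000)

    @given(
        k_total=st.integers(0, 50),
        k_region=st.integers(0, 50),
        p0=st.sampled_from([1e-4, 1e-3, 1e-2, 0.5]),
    )
    @settings(max_examples=200, deadline=None)
    def test_bruteforce_equivalence_property(self, k_total, k_region, p0):
        if k_region > k_total:
            k_region = k_total
        eff_total = 1_000_000
        eff_region = int(round(p0 * eff_total))
        p = recurrence.binomial_region_test(k_region, k_total, eff_region, eff_total)
        oracle = binom_tail_bruteforce(k_region, k_total, eff_region / eff_total)
        assert abs(p - oracle) < 1e-12


class TestBenjaminiHochberg:
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=1000))
    @settings(max_examples=50, deadline=None)
    def test_matches_textbook_stepup(self, pvals):
        ours = multipletests(pvals, method="fdr_bh")[1]
        oracle = bh_stepup(pvals)
        np.testing.assert_allclose(ours, oracle, atol=1e-12)
        assert (ours >= np.asarray(pvals) - 1e-12).all()


def _uniform_cohort(seed, n_samples=40, length=2_000_000, rate=2e-5, hotspots=()):
    ref = synthetic.synthetic_signatures(2, seed=3)
    cfg = synthetic.SimulationConfig(
        seed=seed, n_samples=n_samples, chrom_lengths={"chr1": length},
        background_rate=rate, signature_mixture=np.tile([0.6, 0.4], (n_samples, 1)),
        hotspots=list(hotspots),
    )
    return synthetic.simulate_cohort(cfg, ref)


class TestScan:
    def test_planted_strong_hotspot_detected(self):
        hs = synthetic.Hotspot("chr1", 1_000_000, 1_001_000, 200.0)
        cohort = _uniform_cohort(seed=21, hotspots=[hs])
        res = recurrence.scan(cohort.snvs, SvCatalog.empty(), cohort.layout, cohort.mask)
        row = res[res["start"] == 1_000_000]
        assert len(row) == 1 and bool(row["significant"].iloc[0])

    def test_blacklisted_tile_absent_even_with_huge_count(self):
        hs = synthetic.Hotspot("chr1", 1_000_000, 1_001_000, 500.0)
        cohort = _uniform_cohort(seed=22, hotspots=[hs])
        ann = RegionAnnotations(pd.DataFrame(
            [("chr1", 1_000_200, 1_000_300, "blacklist", "")],
            columns=["chrom", "start", "end", "label", "gene"],
        ))
        res = recurrence.scan(cohort.snvs, SvCatalog.empty(), cohort.layout, cohort.mask, ann)
        assert (res["start"] != 1_000_000).all()

    def test_annotation_classes_reported(self):
        hs = synthetic.Hotspot("chr1", 1_000_000, 1_001_000, 200.0)
        cohort = _uniform_cohort(seed=23, hotspots=[hs])
        ann = RegionAnnotations(pd.DataFrame(
            [("chr1", 1_000_100, 1_000_400, "enhancer", "ADGRG6")],
            columns=["chrom", "start", "end", "label", "gene"],
        ))
        res = recurrence.scan(cohort.snvs, SvCatalog.empty(), cohort.layout, cohort.mask, ann)
        row = res[res["start"] == 1_000_000].iloc[0]
        assert row["annotation_classes"] == "enhancer" and row["genes"] == "ADGRG6"

    def test_global_p_invariant_to_sample_permutation(self):
        cohort = _uniform_cohort(seed=24, n_samples=10)
        res1 = recurrence.scan(cohort.snvs, SvCatalog.empty(), cohort.layout, cohort.mask)
        df = cohort.snvs.df.copy()
        perm = {s: f"P{i}" for i, s in enumerate(reversed(sorted(df["sample_id"].unique())))}
        df["sample_id"] = df["sample_id"].map(perm)
        res2 = recurrence.scan(SnvCatalog(df), SvCatalog.empty(), cohort.layout, cohort.mask)
        np.testing.assert_allclose(res1["p_global"], res2["p_global"])

    def test_global_p_invariant_to_genome_doubling(self):
        """Two identical chromosomes side by side leave each tile's p_global unchanged.

        The binomial null has k_total doubled and p0 halved, which is
        invariant exactly in the Poisson limit; at these counts the
        residual drift is ~1%, so the check uses a 5% tolerance.
        """
        cohort = _uniform_cohort(seed=25, n_samples=10, length=500_000)
        snv1 = cohort.snvs.df
        doubled = pd.concat([snv1, snv1.assign(chrom="chr2")], ignore_index=True)
        layout2 = GenomeLayout({"chr1": 500_000, "chr2": 500_000})
        res1 = recurrence.scan(cohort.snvs, SvCatalog.empty(), cohort.layout, cohort.mask)
        res2 = recurrence.scan(SnvCatalog(doubled), SvCatalog.empty(), layout2,
                               CoverageMask.full(layout2))
        merged = res1.merge(res2[res2["chrom"] == "chr1"], on="start", suffixes=("_1", "_2"))
        assert len(merged) == len(res1)
        np.testing.assert_allclose(merged["p_global_1"], merged["p_global_2"], rtol=0.05)

    def test_empty_mask_rejected(self):
        layout = GenomeLayout({"chr1": 1000})
        with pytest.raises(ValueError):
            recurrence.scan(SnvCatalog.empty(), SvCatalog.empty(), layout,
                            CoverageMask({"chr1": np.empty((0, 2))}))
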