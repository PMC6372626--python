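"""Generator correctness: determinism, planted structure, truth labels."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ubcgenomics import bfb, spectra, synthetic
from ubcgenomics.types import InvalidConfigError


def _cfg(**kwargs):
    defaults = dict(seed=7, n_samples=1, chrom_lengths={"chr1": 100_000},
                    background_rate=0.0)
    defaults.update(kwargs)
    return synthetic.SimulationConfig(**defaults)


class TestReference:
    def test_deterministic_by_seed(self):
        cfg = _cfg(chrom_lengths={"chr1": 10_000})
        g1, _ = synthetic.simulate_reference(cfg)
        g2, _ = synthetic.simulate_reference(cfg)
        assert np.array_equal(g1.codes("chr1"), g2.codes("chr1"))
        g3, _ = synthetic.simulate_reference(_cfg(seed=8, chrom_lengths={"chr1": 10_000}))
        assert not np.array_equal(g1.codes("chr1"), g3.codes("chr1"))

    def test_layout_bookkeeping(self):
        cfg = _cfg(chrom_lengths={"chr1": 1_000_000, "chr2": 1_000_000})
        _, layout = synthetic.simulate_reference(cfg)
        assert layout.chromosomes == ["chr1", "chr2"]
        assert layout.total_length == 2_000_000
        assert layout.telomeres("chr1") == (0, 1_000_000)

    def test_gc_fraction_near_half(self):
        genome, _ = synthetic.simulate_reference(_cfg(chrom_lengths={"chr1": 1_000_000}))
        codes = genome.codes("chr1")
        gc = int(((codes == 1) | (codes == 2)).sum())
        n, p = 1_000_000, 0.5
        assert abs(gc - n * p) < 3 * np.sqrt(n * p * (1 - p))

    def test_zero_length_chromosome_rejected(self):
        with pytest.raises(InvalidConfigError):
            _cfg(chrom_lengths={"chr1": 0})


class TestSnvCatalog:
    def test_zero_rate_empty_catalog(self, three_signatures):
        cfg = _cfg(signature_mixture=np.array([[1.0, 0.0, 0.0]]))
        genome, _ = synthetic.simulate_reference(cfg)
        catalog, truth = synthetic.simulate_snv_catalog(cfg, genome, three_signatures)
        assert len(catalog) == 0 and len(truth) == 0

    def test_single_signature_spectrum_close_in_tv(self, three_signatures):
        # ~10,000 mutations from one signature: empirical channel frequencies
        # within total-variation distance 0.05 of the planted profile
        cfg = _cfg(chrom_lengths={"chr1": 10_000_000}, background_rate=1e-3,
                   signature_mixture=np.array([[1.0, 0.0, 0.0]]))
        genome, _ = synthetic.simulate_reference(cfg)
        catalog, _ = synthetic.simulate_snv_catalog(cfg, genome, three_signatures)
        assert len(catalog) > 5_000
        spec = spectra.build_spectrum(catalog, genome)
        emp = spec.matrix[:, 0] / spec.matrix[:, 0].sum()
        planted = three_signatures.to_numpy()[:, 0]
        assert 0.5 * np.abs(emp - planted).sum() < 0.05

    def test_mixture_marginals_chi_square(self, three_signatures):
        # truth signature indices follow the configured mixture
        mix = np.array([[0.5, 0.3, 0.2]])
        cfg = _cfg(chrom_lengths={"chr1": 3_000_000}, background_rate=1e-3,
                   signature_mixture=mix)
        genome, _ = synthetic.simulate_reference(cfg)
        _, truth = synthetic.simulate_snv_catalog(cfg, genome, three_signatures)
        obs = truth["signature_index"].value_counts().reindex([0, 1, 2]).to_numpy()
        stat, p = sps.chisquare(obs, f_exp=obs.sum() * mix[0])
        assert p > 1e-3

    def test_planted_kataegis_run(self, three_signatures):
        spec = synthetic.KataegisSpec(sample=0, chrom="chr1", start=10_000,
                                      n_mutations=8, spacing_bp=300)
        cfg = _cfg(kataegis_specs=[spec])
        genome, _ = synthetic.simulate_reference(cfg)
        catalog, truth = synthetic.simulate_snv_catalog(cfg, genome, three_signatures)
        kat = catalog.df[truth["origin"] == "kataegis"]
        assert len(kat) == 8
        pos = np.sort(kat["pos"].to_numpy())
        assert pos[-1] - pos[0] == 7 * 300  # 2,100 bp span
        assert np.diff(pos).max() <= 1000 and len(pos) >= 6  # rule 1 by construction

    def test_catalog_deterministic_and_sample_stable(self, three_signatures):
        mix3 = np.tile([0.5, 0.3, 0.2], (3, 1))
        mix5 = np.tile([0.5, 0.3, 0.2], (5, 1))
        cfg3 = _cfg(n_samples=3, chrom_lengths={"chr1": 500_000}, background_rate=1e-4,
                    signature_mixture=mix3)
        cfg5 = _cfg(n_samples=5, chrom_lengths={"chr1": 500_000}, background_rate=1e-4,
                    signature_mixture=mix5)
        genome, _ = synthetic.simulate_reference(cfg3)
        c3, _ = synthetic.simulate_snv_catalog(cfg3, genome, three_signatures)
        c3b, _ = synthetic.simulate_snv_catalog(cfg3, genome, three_signatures)
        c5, _ = synthetic.simulate_snv_catalog(cfg5, genome, three_signatures)
        pd.testing.assert_frame_equal(c3.df, c3b.df)
        # adding samples leaves earlier samples' records untouched
        pd.testing.assert_frame_equal(
            c3.df[c3.df["sample_id"] == "S00"].reset_index(drop=True),
            c5.df[c5.df["sample_id"] == "S00"].reset_index(drop=True),
        )

    def test_hotspot_enrichment(self, three_signatures):
        hs = synthetic.Hotspot("chr1", 50_000, 51_000, 200.0)
        cfg = _cfg(n_samples=20, chrom_lengths={"chr1": 200_000}, background_rate=1e-5,
                   signature_mixture=np.tile([1.0, 0, 0], (20, 1)), hotspots=[hs])
        genome, _ = synthetic.simulate_reference(cfg)
        catalog, truth = synthetic.simulate_snv_catalog(cfg, genome, three_signatures)
        in_hs = catalog.df["pos"].between(50_001, 51_000)
        assert in_hs.sum() > 10  # ~40 expected vs ~0.04 background
        assert set(truth.loc[in_hs[in_hs].index, "origin"]) <= {"hotspot", "background"}


class TestSvCatalog:
    def test_exact_counts_and_target_fraction(self):
        spec = synthetic.SvSpec(n_sv=100, target_chrom="chr1", target_chrom_fraction=0.4)
        cfg = _cfg(chrom_lengths={"chr1": 2_000_000, "chr2": 2_000_000}, sv_specs=[spec])
        svs, truth, _, _ = synthetic.simulate_sv_catalog(cfg, synthetic.simulate_reference(cfg)[1])
        assert len(svs) == 100
        on_chr1 = ((svs.df["chrom1"] == "chr1") | (svs.df["chrom2"] == "chr1")).sum()
        assert on_chr1 == 40

    def test_exact_count_49(self):
        spec = synthetic.SvSpec(n_sv=49)
        cfg = _cfg(chrom_lengths={"chr1": 2_000_000}, sv_specs=[spec])
        svs, _, _, _ = synthetic.simulate_sv_catalog(cfg, synthetic.simulate_reference(cfg)[1])
        assert len(svs) == 49

    def test_pure_nhej_homology_codes(self):
        spec = synthetic.SvSpec(n_sv=200, mechanism_mix={"NHEJ": 1.0})
        cfg = _cfg(chrom_lengths={"chr1": 5_000_000}, sv_specs=[spec])
        svs, _, _, _ = synthetic.simulate_sv_catalog(cfg, synthetic.simulate_reference(cfg)[1])
        allowed = set(range(-10, 0)) | {0, 1, 2}
        assert set(svs.df["homology_code"]) <= allowed

    def test_mechanism_mix_chi_square(self):
        mix = {"NHEJ": 0.3, "alt-EJ": 0.4, "FoSTeS/MMBIR": 0.1, "TEI": 0.1, "VNTR": 0.1}
        spec = synthetic.SvSpec(n_sv=2000, mechanism_mix=mix)
        cfg = _cfg(chrom_lengths={"chr1": 5_000_000}, sv_specs=[spec])
        _, truth, _, _ = synthetic.simulate_sv_catalog(cfg, synthetic.simulate_reference(cfg)[1])
        obs = truth["mechanism"].value_counts().reindex(list(mix)).fillna(0).to_numpy()
        _, p = sps.chisquare(obs, f_exp=2000 * np.array(list(mix.values())))
        assert p > 1e-3

    def test_bad_target_fraction_rejected(self):
        with pytest.raises(InvalidConfigError):
            _cfg(sv_specs=[synthetic.SvSpec(n_sv=10, target_chrom_fraction=1.5)])

    def test_foldback_pairs_satisfy_bfb_geometry(self):
        spec = synthetic.SvSpec(n_sv=0, n_foldback_pairs=2, telomere_margin_bp=1_000_000)
        cfg = _cfg(chrom_lengths={"chr1": 5_000_000, "chr2": 5_000_000}, sv_specs=[spec])
        layout = synthetic.simulate_reference(cfg)[1]
        svs, truth, segments, regions = synthetic.simulate_sv_catalog(cfg, layout)
        fb = svs.df[svs.df["foldback"]]
        assert len(fb) == 4 and len(regions) == 2
        assert (fb["strand1"] == fb["strand2"]).all()
        assert ((fb["pos2"] - fb["pos1"]).abs() < 20_000).all()
        for row in fb.itertuples(index=False):
            tel = min(layout.telomere_distance(row.chrom1, row.pos1),
                      layout.telomere_distance(row.chrom1, row.pos2))
            assert tel <= 1_000_000
            mid0 = (row.pos1 + row.pos2) // 2 - 1
            seg = segments[segments["sample_id"] == row.sample_id]
            left, right = bfb.flank_copy_ratio(seg, row.chrom1, mid0)
            assert max(left / right, right / left) >= 2.0

    def test_kataegis_support_breakend_near_cluster(self, three_signatures):
        ks = synthetic.KataegisSpec(sample=0, chrom="chr1", start=500_000, n_mutations=8,
                                    spacing_bp=300, place_sv_within_bp=10_000)
        cfg = _cfg(chrom_lengths={"chr1": 2_000_000}, kataegis_specs=[ks],
                   sv_specs=[synthetic.SvSpec(n_sv=0)])
        layout = synthetic.simulate_reference(cfg)[1]
        svs, truth, _, _ = synthetic.simulate_sv_catalog(cfg, layout)
        sup = svs.df[truth["origin"] == "kataegis_support"]
        assert len(sup) == 1
        span_end = 500_000 + 7 * 300 + 1
        assert 0 < int(sup["pos1"].iloc[0]) - span_end <= 10_000

    def test_rerun_reproduces_identical_catalog(self):
        spec = synthetic.SvSpec(n_sv=60, n_foldback_pairs=1, telomere_margin_bp=1_000_000)
        cfg = _cfg(chrom_lengths={"chr1": 4_000_000}, sv_specs=[spec])
        layout = synthetic.simulate_reference(cfg)[1]
        a = synthetic.simulate_sv_catalog(cfg, layout)
        b = synthetic.simulate_sv_catalog(cfg, layout)
        pd.testing.assert_frame_equal(a[0].df, b[0].df)
        pd.testing.assert_frame_equal(a[2], b[2])
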