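"""Orchestration: run every analysis stage from one validated configuration.

Stages run in dependency order (load -> spectrum -> signatures, scan,
kataegis, svclass, subtype, bfb) and each writes one TSV.  A JSON manifest
records the seed, every parameter, input checksums, and per-stage record
counts; reruns with identical configuration and inputs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, bfb, io, kataegis, recurrence, spectra, sv
from .types import InvalidConfigError

logger = logging.getLogger(__name__)

STAGE_ORDER = ("spectrum", "signatures", "scan", "kataegis", "svclass", "subtype", "bfb")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def _from_mapping(cls, data: dict, context: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise InvalidConfigError(f"unknown keys in {context}: {sorted(unknown)}")
    return cls(**data)


@dataclass
class SignatureParams:
    k: int | None = None  # fixed rank; None -> select over [k_min, k_max]
    k_min: int = 2
    k_max: int = 15
    n_restarts: int = 10
    max_iter: int = 1000
    tol: float = 1e-6
    stability_floor: float = 0.8


@dataclass
class ScanParams:
    tile_width: int = 1000
    alpha: float = 0.05
    mode: str = "combined"
    flank: int = 500_000
    restrict_to_annotations: bool = False


@dataclass
class KataegisParams:
    alpha: float = 0.05
    sv_window: int = 50_000
    max_spacing: int = 1000
    min_mutations: int = 6
    flank_bp: int = 50_000


@dataclass
class SvParams:
    recurrent_min_tumors: int = 5
    significant_fraction: float = 0.10


@dataclass
class BfbParams:
    cn_fold_min: float = 2.0
    telomere_margin: int = 5_000_000
    foldback_max_sep: int = 20_000
    flank: int = 100_000


@dataclass
class RunConfig:
    """Validated run configuration; unknown keys are rejected on load."""

    snv_vcf: str
    sv_bedpe: str
    out_dir: str
    fasta: str | None = None
    chrom_sizes: str | None = None
    mask_bed: str | None = None
    segments_tsv: str | None = None
    annotations_bed: str | None = None
    genes_bed: str | None = None
    reference_signatures_tsv: str | None = None
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGE_ORDER))
    signatures: SignatureParams = field(default_factory=SignatureParams)
    scan: ScanParams = field(default_factory=ScanParams)
    kataegis: KataegisParams = field(default_factory=KataegisParams)
    sv: SvParams = field(default_factory=SvParams)
    bfb: BfbParams = field(default_factory=BfbParams)

    def __post_init__(self) -> None:
        for stage in self.stages:
            if stage not in STAGE_ORDER:
                raise InvalidConfigError(f"unknown stage {stage!r}")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        for key, sub_cls in (
            ("signatures", SignatureParams), ("scan", ScanParams),
            ("kataegis", KataegisParams), ("sv", SvParams), ("bfb", BfbParams),
        ):
            if key in data and isinstance(data[key], dict):
                data[key] = _from_mapping(sub_cls, data[key], key)
        return _from_mapping(cls, data, "run config")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages; returns the manifest dictionary."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    input_paths = {
        name: getattr(config, name)
        for name in ("snv_vcf", "sv_bedpe", "fasta", "chrom_sizes", "mask_bed",
                     "segments_tsv", "annotations_bed", "genes_bed",
                     "reference_signatures_tsv")
        if getattr(config, name)
    }
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": config.to_dict(),
        "input_checksums": {k: io.sha256_of(v) for k, v in input_paths.items()},
        "stages": {},
        "status": "incomplete",
    }
    results: dict[str, pd.DataFrame] = {}

    bundle = io.load_inputs(
        snv_vcf=config.snv_vcf, sv_bedpe=config.sv_bedpe, fasta=config.fasta,
        chrom_sizes=config.chrom_sizes, mask_bed=config.mask_bed,
        segments_tsv=config.segments_tsv, annotations_bed=config.annotations_bed,
    )
    manifest["n_snvs"] = len(bundle.snvs)
    manifest["n_svs"] = len(bundle.svs)
    manifest["n_skipped_non_snv"] = bundle.stats.n_skipped_non_snv

    selected = [s for s in STAGE_ORDER if s in config.stages]
    spectrum_obj = None

    def need_spectrum():
        nonlocal spectrum_obj
        if spectrum_obj is None:
            if bundle.genome is None:
                raise PipelineError("spectrum: a FASTA reference is required")
            spectrum_obj = spectra.build_spectrum(bundle.snvs, bundle.genome)
        return spectrum_obj

    for stage in selected:
        t0 = time.monotonic()
        keys_before = set(results)
        try:
            if stage == "spectrum":
                spec = need_spectrum()
                out = spec.counts.reset_index(names="channel")
                results["spectrum"] = out
            elif stage == "signatures":
                spec = need_spectrum()
                p = config.signatures
                if p.k is not None:
                    chosen = p.k
                    table = pd.DataFrame()
                else:
                    k_hi = min(p.k_max, len(spec.samples))
                    chosen, table = spectra.select_rank(
                        spec, range(p.k_min, k_hi + 1), n_restarts=p.n_restarts,
                        max_iter=p.max_iter, tol=p.tol, seed=config.seed,
                        stability_floor=p.stability_floor,
                    )
                sigs = spectra.nmf_decompose(
                    spec, chosen, n_restarts=p.n_restarts, max_iter=p.max_iter,
                    tol=p.tol, seed=config.seed,
                )
                results["signatures_w"] = sigs.W.reset_index(names="channel")
                results["signatures_h"] = sigs.H.reset_index(names="signature")
                results["rank_selection"] = table
                if config.reference_signatures_tsv:
                    ref = pd.read_csv(config.reference_signatures_tsv, sep="\t", index_col=0)
                    results["signature_matches"] = spectra.match_to_reference(sigs.W, ref)
                manifest["chosen_rank"] = int(chosen)
                manifest["reconstruction_error"] = sigs.reconstruction_error
            elif stage == "scan":
                p = config.scan
                results["recurrence"] = recurrence.scan(
                    bundle.snvs, bundle.svs, bundle.layout, bundle.mask, bundle.annotations,
                    alpha=p.alpha, width=p.tile_width, flank=p.flank, mode=p.mode,
                    restrict_to_annotations=p.restrict_to_annotations,
                )
            elif stage == "kataegis":
                p = config.kataegis
                results["kataegis"] = kataegis.call_kataegis(
                    bundle.snvs, bundle.svs, bundle.mask, bundle.layout,
                    alpha=p.alpha, sv_window=p.sv_window, max_spacing=p.max_spacing,
                    min_mutations=p.min_mutations, flank_bp=p.flank_bp,
                )
            elif stage == "svclass":
                results["sv_mechanisms"] = sv.classify_mechanisms(bundle.svs)
                if config.genes_bed:
                    genes = pd.read_csv(
                        config.genes_bed, sep="\t", header=None,
                        names=["chrom", "start", "end", "gene"],
                    )
                    results["gene_recurrence"] = sv.gene_breakpoint_recurrence(
                        bundle.svs, genes, n_samples=len(bundle.snvs.samples) or
                        len(bundle.svs.samples),
                        recurrent_min_tumors=config.sv.recurrent_min_tumors,
                        significant_fraction=config.sv.significant_fraction,
                    )
            elif stage == "subtype":
                results["subtypes"] = sv.classify_subtypes(bundle.svs)
            elif stage == "bfb":
                p = config.bfb
                events, junctions = bfb.call_bfb(
                    bundle.svs, bundle.segments, bundle.layout,
                    cn_fold_min=p.cn_fold_min, telomere_margin=p.telomere_margin,
                    foldback_max_sep=p.foldback_max_sep, flank=p.flank,
                )
                results["bfb_events"] = bfb.events_frame(events)
                results["bfb_junctions"] = junctions
        except Exception as exc:
            manifest["failed_stage"] = stage
            io.write_report(results, out_dir, summary=manifest)
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = {
            "n_records": int(sum(len(results[k]) for k in set(results) - keys_before)),
        }
        logger.info("stage %s finished in %.2fs", stage, time.monotonic() - t0)

    manifest["status"] = "complete"
    manifest["record_counts"] = {k: int(len(v)) for k, v in results.items()}
    io.write_report(results, out_dir, summary=manifest)
    return manifest
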