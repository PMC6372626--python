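"""Readers and writers for every file format the pipeline touches.

Conventions
-----------
* VCF positions are 1-based and preserved as such in :class:`SnvRecord`.
* BED / BEDPE files are 0-based half-open; breakend positions convert to
  1-based on load (``start + 1``) and back on write.
* The SV dialect is BEDPE with extra named columns
  (``sv_type``, ``homology_code``, ``n_junctions``, ``foldback``), since
  junction-centric caller output maps naturally onto BEDPE.
* Loaders never silently drop a record: every skip increments a counter
  that is reported back to the caller.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    ANNOTATION_CLASSES,
    BASES,
    CopyNumberSegment,
    CoverageMask,
    Genome,
    GenomeLayout,
    InputFormatError,
    RegionAnnotations,
    SEGMENT_COLUMNS,
    SnvCatalog,
    SvCatalog,
)

logger = logging.getLogger(__name__)

BEDPE_COLUMNS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2",
    "name", "score", "strand1", "strand2",
    "sv_type", "homology_code", "n_junctions", "foldback",
]


# ---------------------------------------------------------------------------
# FASTA / layout
# ---------------------------------------------------------------------------


def write_fasta(genome: Genome, path: str | Path, line_width: int = 60) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = genome.seq(chrom, 0, len(genome.codes(chrom)))
            for i in range(0, len(seq), line_width):
                fh.write(seq[i:i + line_width] + "\n")


def read_fasta(path: str | Path) -> Genome:
    from pyfaidx import Fasta

    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
    return Genome.from_strings({name: str(fa[name][:]) for name in fa.keys()})


def write_chrom_sizes(layout: GenomeLayout, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for chrom in layout.chromosomes:
            fh.write(f"{chrom}\t{layout.length(chrom)}\n")


def read_chrom_sizes(path: str | Path) -> GenomeLayout:
    lengths: dict[str, int] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise InputFormatError(f"{path}:{ln}: expected two tab-separated columns")
        lengths[parts[0]] = int(parts[1])
    return GenomeLayout(lengths)


# ---------------------------------------------------------------------------
# VCF (SNVs)
# ---------------------------------------------------------------------------


def write_snv_vcf(catalog: SnvCatalog, layout: GenomeLayout, path: str | Path) -> None:
    """Write a cohort VCF with the originating sample in INFO/SAMPLE."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=ubcgenomics\n")
        for chrom in layout.chromosomes:
            fh.write(f"##contig=<ID={chrom},length={layout.length(chrom)}>\n")
        fh.write('##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Originating sample">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        df = catalog.df.sort_values(["chrom", "pos", "sample_id"], kind="stable")
        for row in df.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t"
                f"SAMPLE={row.sample_id}\n"
            )


@dataclass
class LoadStats:
    """Per-loader skip counters; nothing is dropped silently."""

    n_loaded: int = 0
    n_skipped_non_snv: int = 0
    n_skipped_no_sample: int = 0
    skipped_lines: list[str] = field(default_factory=list)


def read_snv_vcf(
    path: str | Path,
    layout: GenomeLayout | None = None,
    sample_id: str | None = None,
) -> tuple[SnvCatalog, LoadStats]:
    """Load somatic SNVs from a VCF.

    Multi-allelic rows are split into one record per ALT; rows whose
    REF/ALT is not a single A/C/G/T base (indels, MNVs, symbolic alleles)
    are skipped and counted.  The sample comes from INFO/SAMPLE unless a
    fixed ``sample_id`` is supplied (one-file-per-sample layout).
    """
    from cyvcf2 import VCF

    stats = LoadStats()
    rows = []
    vcf = VCF(str(path))
    for variant in vcf:
        ref = variant.REF
        sample = sample_id or dict(variant.INFO).get("SAMPLE")
        for alt in variant.ALT:
            if len(ref) != 1 or len(alt) != 1 or ref not in BASES or alt not in BASES:
                stats.n_skipped_non_snv += 1
                continue
            if sample is None:
                stats.n_skipped_no_sample += 1
                continue
            rows.append((str(sample), variant.CHROM, variant.POS, ref, alt))
    df = pd.DataFrame(rows, columns=["sample_id", "chrom", "pos", "ref", "alt"])
    try:
        catalog = SnvCatalog(df, layout)
    except InputFormatError as exc:
        raise InputFormatError(f"{path}: {exc}") from exc
    stats.n_loaded = len(catalog)
    if stats.n_skipped_non_snv:
        logger.info("%s: skipped %d non-SNV rows", path, stats.n_skipped_non_snv)
    return catalog, stats


# ---------------------------------------------------------------------------
# BEDPE (SVs)
# ---------------------------------------------------------------------------


def write_sv_bedpe(catalog: SvCatalog, path: str | Path) -> None:
    df = catalog.df
    out = pd.DataFrame(
        {
            "chrom1": df["chrom1"],
            "start1": df["pos1"] - 1,
            "end1": df["pos1"],
            "chrom2": df["chrom2"],
            "start2": df["pos2"] - 1,
            "end2": df["pos2"],
            "name": df["sample_id"],
            "score": ".",
            "strand1": df["strand1"],
            "strand2": df["strand2"],
            "sv_type": df["sv_type"],
            "homology_code": df["homology_code"],
            "n_junctions": df["n_junctions"],
            "foldback": df["foldback"].map({True: "1", False: "0"}),
        }
    )
    out.to_csv(path, sep="\t", index=False, header=True)


def read_sv_bedpe(path: str | Path, layout: GenomeLayout | None = None) -> SvCatalog:
    try:
        raw = pd.read_csv(path, sep="\t", dtype={"foldback": str})
    except Exception as exc:
        raise InputFormatError(f"{path}: unreadable BEDPE: {exc}") from exc
    missing = [c for c in BEDPE_COLUMNS if c not in raw.columns]
    if missing:
        raise InputFormatError(f"{path}: missing BEDPE columns {missing}")
    df = pd.DataFrame(
        {
            "sample_id": raw["name"].astype(str),
            "sv_type": raw["sv_type"],
            "chrom1": raw["chrom1"].astype(str),
            "pos1": raw["start1"].astype(np.int64) + 1,
            "strand1": raw["strand1"],
            "chrom2": raw["chrom2"].astype(str),
            "pos2": raw["start2"].astype(np.int64) + 1,
            "strand2": raw["strand2"],
            "homology_code": raw["homology_code"].astype(np.int64),
            "n_junctions": raw["n_junctions"].astype(np.int64),
            "foldback": raw["foldback"].astype(str).isin(["1", "True", "true"]),
        }
    )
    try:
        return SvCatalog(df, layout)
    except InputFormatError as exc:
        raise InputFormatError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# BED (mask, annotations)
# ---------------------------------------------------------------------------


def write_mask_bed(mask: CoverageMask, path: str | Path) -> None:
    mask.to_frame().to_csv(path, sep="\t", index=False, header=False)


def read_mask_bed(path: str | Path, layout: GenomeLayout | None = None) -> CoverageMask:
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                     names=["chrom", "start", "end"])
    iv: dict[str, list] = {}
    for row in df.itertuples(index=False):
        iv.setdefault(str(row.chrom), []).append((int(row.start), int(row.end)))
    return CoverageMask({c: np.asarray(v) for c, v in iv.items()}, layout)


def write_annotations_bed(annotations: RegionAnnotations, path: str | Path) -> None:
    annotations.df.to_csv(path, sep="\t", index=False, header=False)


def read_annotations_bed(path: str | Path) -> RegionAnnotations:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "label", "gene"],
        dtype={"chrom": str, "label": str},
    )
    df["gene"] = df["gene"].fillna("")
    for ln, label in enumerate(df["label"], 1):
        if label not in ANNOTATION_CLASSES:
            raise InputFormatError(f"{path}:{ln}: unknown annotation class {label!r}")
    return RegionAnnotations(df)


# ---------------------------------------------------------------------------
# TSV (segments, truth, reports)
# ---------------------------------------------------------------------------


def write_segments_tsv(segments: pd.DataFrame, path: str | Path) -> None:
    segments.reindex(columns=SEGMENT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_segments_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SEGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise InputFormatError(f"{path}: missing segment columns {missing}")
    for row in df.itertuples(index=False):
        CopyNumberSegment(str(row.sample_id), str(row.chrom), int(row.start),
                          int(row.end), float(row.copy_ratio))
    return df[SEGMENT_COLUMNS]


# ---------------------------------------------------------------------------
# bundled loading and report writing
# ---------------------------------------------------------------------------


@dataclass
class InputBundle:
    snvs: SnvCatalog
    svs: SvCatalog
    layout: GenomeLayout
    genome: Genome | None
    mask: CoverageMask
    segments: pd.DataFrame
    annotations: RegionAnnotations
    stats: LoadStats


def load_inputs(
    snv_vcf: str | Path,
    sv_bedpe: str | Path,
    fasta: str | Path | None = None,
    chrom_sizes: str | Path | None = None,
    mask_bed: str | Path | None = None,
    segments_tsv: str | Path | None = None,
    annotations_bed: str | Path | None = None,
) -> InputBundle:
    """Load and validate every pipeline input.

    The genome comes from ``fasta`` when given, else the layout from
    ``chrom_sizes``; one of the two is required.  A missing mask defaults
    to fully callable; missing segments/annotations default to empty.
    """
    if fasta is not None:
        genome = read_fasta(fasta)
        layout = genome.layout
    elif chrom_sizes is not None:
        genome = None
        layout = read_chrom_sizes(chrom_sizes)
    else:
        raise InputFormatError("either a FASTA or a chrom-sizes file is required")
    snvs, stats = read_snv_vcf(snv_vcf, layout)
    svs = read_sv_bedpe(sv_bedpe, layout)
    mask = read_mask_bed(mask_bed, layout) if mask_bed else CoverageMask.full(layout)
    segments = read_segments_tsv(segments_tsv) if segments_tsv else pd.DataFrame(
        columns=SEGMENT_COLUMNS
    )
    annotations = read_annotations_bed(annotations_bed) if annotations_bed else RegionAnnotations()
    return InputBundle(
        snvs=snvs, svs=svs, layout=layout, genome=genome, mask=mask,
        segments=segments, annotations=annotations, stats=stats,
    )


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with Path(path).open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_report(
    results: dict[str, pd.DataFrame],
    out_dir: str | Path,
    summary: dict | None = None,
) -> dict[str, Path]:
    """Write one TSV per stage (stable column order) plus a JSON summary.

    Empty results produce a header-only TSV.  Returns the paths written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for stage, df in results.items():
        path = out_dir / f"{stage}.tsv"
        df.to_csv(path, sep="\t", index=False)
        written[stage] = path
    if summary is not None:
        path = out_dir / "run_summary.json"
        path.write_text(json.dumps(summary, indent=2, sort_keys=True, default=str) + "\n")
        written["run_summary"] = path
    return written


def read_report_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
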