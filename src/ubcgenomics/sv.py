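"""SV formation mechanisms, SV-burden genome subtypes, and gene recurrence.

Mechanism calls are derived from junction features: nonhomologous end
joining (NHEJ) leaves 0-2 bp of junction homology or a 1-10 bp untemplated
insertion (homology codes -1..-10); alternative end joining (alt-EJ) uses
3-100 bp of microhomology; fork stalling and template switching /
microhomology-mediated break-induced replication (FoSTeS/MMBIR) produces
multi-junction events; transposable-element insertions (TEI) and
variable-number-tandem-repeat (VNTR) changes are recognized from the call
type or from repeat annotations at the breakends.

Genome subtypes follow burden rules: stable (< 50 rearrangements),
locally rearranged (>= 50 with > 25% on one chromosome), scattered
(50-200 dispersed), unstable (> 200 dispersed).  The rules are evaluated
in that order, so a massively rearranged genome concentrated on one
chromosome is called locally rearranged.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from .types import SvCatalog, SvRecord

MECHANISM_LABELS = ("NHEJ", "alt-EJ", "FoSTeS/MMBIR", "TEI", "VNTR", "unclassified")
SUBTYPES = ("stable", "locally_rearranged", "scattered", "unstable")


class RepeatAnnotations:
    """Transposable-element / VNTR intervals for breakend lookup.

    Built from a frame with columns chrom, start, end (0-based half-open)
    and label in {"TE", "VNTR"}.
    """

    def __init__(self, df: pd.DataFrame | None = None):
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        if df is not None and len(df):
            for row in df.itertuples(index=False):
                key = (str(row.label), str(row.chrom))
                self._trees.setdefault(key, IntervalTree()).addi(int(row.start), int(row.end))

    def hit(self, label: str, chrom: str, pos1: int) -> bool:
        tree = self._trees.get((label, chrom))
        return bool(tree is not None and tree.overlaps(pos1 - 1))


def classify_mechanism(sv: SvRecord, repeats: RepeatAnnotations | None = None) -> str:
    """Label one junction with its inferred formation mechanism.

    Precedence: TEI, then VNTR, then multi-junction FoSTeS/MMBIR, then
    homology-defined NHEJ / alt-EJ, else unclassified.
    """
    if repeats is None:
        repeats = RepeatAnnotations()
    if sv.sv_type == "TEI" or (
        sv.sv_type == "insertion"
        and (repeats.hit("TE", sv.chrom1, sv.pos1) or repeats.hit("TE", sv.chrom2, sv.pos2))
    ):
        return "TEI"
    if sv.sv_type == "VNTR" or (
        repeats.hit("VNTR", sv.chrom1, sv.pos1) or repeats.hit("VNTR", sv.chrom2, sv.pos2)
    ):
        return "VNTR"
    if sv.n_junctions > 2:
        return "FoSTeS/MMBIR"
    h = sv.homology_code
    if 0 <= h <= 2 or -10 <= h <= -1:
        return "NHEJ"
    if 3 <= h <= 100:
        return "alt-EJ"
    return "unclassified"


def classify_mechanisms(
    catalog: SvCatalog, repeats: RepeatAnnotations | None = None
) -> pd.DataFrame:
    """Mechanism call for every junction of a catalog."""
    rows = [
        {
            "sample_id": sv.sample_id,
            "sv_type": sv.sv_type,
            "chrom1": sv.chrom1,
            "pos1": sv.pos1,
            "chrom2": sv.chrom2,
            "pos2": sv.pos2,
            "homology_code": sv.homology_code,
            "n_junctions": sv.n_junctions,
            "mechanism": classify_mechanism(sv, repeats),
        }
        for sv in catalog.records()
    ]
    return pd.DataFrame(
        rows,
        columns=["sample_id", "sv_type", "chrom1", "pos1", "chrom2", "pos2",
                 "homology_code", "n_junctions", "mechanism"],
    )


@dataclass(frozen=True)
class SubtypeCall:
    sample_id: str
    subtype: str
    n_sv: int
    max_chrom_fraction: float


def _max_chrom_fraction(sample_df: pd.DataFrame) -> float:
    """Largest per-chromosome share of a sample's SVs.

    Each SV counts once toward every distinct chromosome it touches (a
    translocation contributes to both of its chromosomes); the denominator
    is the number of SVs.
    """
    n = len(sample_df)
    if n == 0:
        return 0.0
    touched = pd.concat(
        [
            sample_df[["chrom1"]].rename(columns={"chrom1": "chrom"}).assign(i=sample_df.index),
            sample_df[["chrom2"]].rename(columns={"chrom2": "chrom"}).assign(i=sample_df.index),
        ]
    ).drop_duplicates()
    return float(touched.groupby("chrom").size().max() / n)


def classify_subtype(sample_df: pd.DataFrame, sample_id: str | None = None) -> SubtypeCall:
    """SV-burden subtype of one sample's junction table."""
    n = len(sample_df)
    frac = _max_chrom_fraction(sample_df)
    if n < 50:
        subtype = "stable"
    elif frac > 0.25:
        subtype = "locally_rearranged"
    elif n > 200:
        subtype = "unstable"
    else:
        subtype = "scattered"
    if sample_id is None:
        sample_id = str(sample_df["sample_id"].iloc[0]) if n else ""
    return SubtypeCall(sample_id=sample_id, subtype=subtype, n_sv=n, max_chrom_fraction=frac)


def classify_subtypes(catalog: SvCatalog, samples: list[str] | None = None) -> pd.DataFrame:
    if samples is None:
        samples = catalog.samples
    rows = []
    for sample in samples:
        call = classify_subtype(catalog.for_sample(sample), sample)
        rows.append(
            {"sample_id": call.sample_id, "subtype": call.subtype, "n_sv": call.n_sv,
             "max_chrom_fraction": call.max_chrom_fraction}
        )
    return pd.DataFrame(rows, columns=["sample_id", "subtype", "n_sv", "max_chrom_fraction"])


def gene_breakpoint_recurrence(
    catalog: SvCatalog,
    genes: pd.DataFrame,
    n_samples: int,
    recurrent_min_tumors: int = 5,
    significant_fraction: float = 0.10,
) -> pd.DataFrame:
    """Per-gene count of tumors with >= 1 SV breakend inside the gene.

    ``genes`` has columns chrom, start, end, gene (0-based half-open).
    Duplicate gene names with disjoint intervals are unioned.  A gene is
    ``recurrent`` when hit in >= ``recurrent_min_tumors`` tumors and
    ``significant`` when hit in >= ``significant_fraction`` of the cohort.
    """
    genes = genes.copy()
    dup = genes["gene"].duplicated(keep=False)
    if dup.any():
        import warnings

        warnings.warn("duplicate gene names: intervals unioned per name", stacklevel=2)
    trees: dict[str, IntervalTree] = {}
    for row in genes.itertuples(index=False):
        trees.setdefault(str(row.chrom), IntervalTree()).addi(
            int(row.start), int(row.end), str(row.gene)
        )
    hits: dict[str, set[str]] = {str(g): set() for g in genes["gene"]}
    bes = catalog.breakends()
    for row in bes.itertuples(index=False):
        tree = trees.get(str(row.chrom))
        if tree is None:
            continue
        for iv in tree.at(int(row.pos) - 1):
            hits[iv.data].add(str(row.sample_id))
    rows = []
    for gene in sorted(hits):
        n_tumors = len(hits[gene])
        rows.append(
            {
                "gene": gene,
                "n_tumors": n_tumors,
                "fraction": n_tumors / n_samples if n_samples else 0.0,
                "recurrent": n_tumors >= recurrent_min_tumors,
                "significant": n_samples > 0 and n_tumors / n_samples >= significant_fraction,
            }
        )
    return pd.DataFrame(rows, columns=["gene", "n_tumors", "fraction", "recurrent", "significant"])
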