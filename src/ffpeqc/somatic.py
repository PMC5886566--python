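"""Tumor-specific variant derivation and FF/FFPE somatic overlap.

The somatic protocol is deliberately minimal matched-normal subtraction:
a tumor call is tumor-specific when its full allele key
``(chrom, pos, ref, alt)`` is absent from the matched normal — a different
alt at the same site is still tumor-specific.  Subtraction is done per
condition (FF and FFPE separately); the overlap of the two tumor-specific
sets, again on allele keys, measures how reproducible somatic calls are
across preservation methods.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .variant_io import AlleleKey, VariantSet, compute_vaf


@dataclass(frozen=True)
class SomaticComparison:
    tissue: str
    n_ff_somatic: int
    n_ffpe_somatic: int
    n_overlap: int
    pct_of_ff: int    # rounded to nearest integer for reporting
    pct_of_ffpe: int

    def __post_init__(self) -> None:
        if self.n_overlap > min(self.n_ff_somatic, self.n_ffpe_somatic):
            raise ValueError("overlap cannot exceed either somatic set")


def tumor_specific(tumor: VariantSet, normal: VariantSet) -> VariantSet:
    """Tumor records with no alt allele key present in the matched normal.

    A multi-allelic tumor record is kept if at least one of its alt keys is
    absent from the normal.
    """
    normal_keys = normal.allele_key_set()
    out = VariantSet(meta=tumor.meta)
    for rec in tumor:
        if any(k not in normal_keys for k in rec.allele_keys()):
            out.add(rec)
    return out


def overlap_counts(
    ff_somatic: VariantSet, ffpe_somatic: VariantSet
) -> tuple[int, int, int]:
    ff_keys = ff_somatic.allele_key_set()
    ffpe_keys = ffpe_somatic.allele_key_set()
    return len(ff_keys), len(ffpe_keys), len(ff_keys & ffpe_keys)


def condition_overlap(
    ff_somatic: VariantSet, ffpe_somatic: VariantSet, tissue: str = ""
) -> SomaticComparison:
    """Overlap of tumor-specific calls between conditions, on allele keys."""
    n_ff, n_ffpe, n_common = overlap_counts(ff_somatic, ffpe_somatic)
    return somatic_comparison_from_counts(n_ff, n_ffpe, n_common, tissue)


def somatic_comparison_from_counts(
    n_ff: int, n_ffpe: int, n_overlap: int, tissue: str = ""
) -> SomaticComparison:
    """Build the comparison row from bare counts (e.g. a published table)."""
    if n_ff == 0 or n_ffpe == 0:
        raise ValueError("overlap percentage undefined: empty somatic set")
    pct_ff = round(100 * n_overlap / n_ff)
    pct_ffpe = round(100 * n_overlap / n_ffpe)
    return SomaticComparison(
        tissue=tissue, n_ff_somatic=n_ff, n_ffpe_somatic=n_ffpe,
        n_overlap=n_overlap, pct_of_ff=pct_ff, pct_of_ffpe=pct_ffpe,
    )


# ---------------------------------------------------------------------------
# Annotation: generic key join on user-supplied flat tables

ANNOTATION_KEY = ["chrom", "pos", "ref", "alt"]


def aggregate_variants(variant_sets: Sequence[VariantSet]) -> pd.DataFrame:
    """Pool call sets by allele key with per-condition VAF/depth means.

    Returns one row per (chrom, pos, ref, alt) with ``n_samples`` (number of
    samples carrying the key) and mean VAF (percent) and mean depth for the
    FF and FFPE samples carrying it.
    """
    rows = []
    for vs in variant_sets:
        cond = vs.meta.condition
        for rec in vs:
            for i, alt in enumerate(rec.alts):
                vaf = None
                if rec.ad is not None and rec.dp:
                    vaf = 100 * compute_vaf(rec, i)
                rows.append(
                    dict(chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt,
                         condition=cond, vaf=vaf, dp=rec.dp)
                )
    if not rows:
        return pd.DataFrame(
            columns=[*ANNOTATION_KEY, "n_samples",
                     "mean_vaf_ff", "mean_depth_ff", "mean_vaf_ffpe", "mean_depth_ffpe"]
        )
    df = pd.DataFrame(rows)
    out = df.groupby(ANNOTATION_KEY, as_index=False).agg(n_samples=("condition", "size"))
    for cond, tag in (("FF", "ff"), ("FFPE", "ffpe")):
        sub = df[df.condition == cond].groupby(ANNOTATION_KEY, as_index=False).agg(
            **{f"mean_vaf_{tag}": ("vaf", "mean"), f"mean_depth_{tag}": ("dp", "mean")}
        )
        out = out.merge(sub, on=ANNOTATION_KEY, how="left")
    return out


def annotate_variants(
    variant_sets: Sequence[VariantSet],
    tables: Sequence[pd.DataFrame],
    gene_key: str = "gene",
) -> pd.DataFrame:
    """Left-join annotation tables onto the pooled variant table.

    Tables keyed by (chrom, pos, ref, alt) are joined on the allele key;
    tables without positional columns but with a ``gene`` column are joined
    on gene symbol (requires a prior positional table to have supplied one).
    All variants are retained whether or not they match.
    """
    out = aggregate_variants(variant_sets)
    for i, tbl in enumerate(tables):
        if all(c in tbl.columns for c in ANNOTATION_KEY):
            t = tbl.copy()
            t["pos"] = t["pos"].astype(int)
            out = out.merge(t, on=ANNOTATION_KEY, how="left", suffixes=("", f"_t{i}"))
        elif gene_key in tbl.columns and gene_key in out.columns:
            out = out.merge(tbl, on=gene_key, how="left", suffixes=("", f"_t{i}"))
        else:
            raise ValueError(
                f"annotation table {i} has neither {ANNOTATION_KEY} nor a "
                f"joinable {gene_key!r} column (columns: {list(tbl.columns)})"
            )
    return out


def read_annotation_table(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t")
    except Exception as exc:  # surface the offending content
        raise ValueError(f"malformed annotation table {path}: {exc}") from exc


def somatic_table(comparisons: Sequence[SomaticComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(tissue=c.tissue, n_ff_somatic=c.n_ff_somatic,
                 n_ffpe_somatic=c.n_ffpe_somatic, n_overlap=c.n_overlap,
                 pct_of_ff=c.pct_of_ff, pct_of_ffpe=c.pct_of_ffpe)
            for c in comparisons
        ]
    )
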