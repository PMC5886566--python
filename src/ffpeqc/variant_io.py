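"""Reading, filtering and classifying variant call sets.

The whole pipeline operates on :class:`VariantSet` objects: one sample's
calls keyed by ``(chrom, pos, ref)``.  Multi-allelic sites are kept as a
single record carrying the full alt list, because downstream concordance
classification compares the complete call made at a position, not
individual alleles.

Coordinates are 1-based (VCF convention) everywhere inside the package;
0-based half-open BED coordinates are converted at the I/O boundary in
:mod:`ffpeqc.coverage_qc`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd
import pysam

log = logging.getLogger(__name__)

SNV = "SNV"
INDEL = "INDEL"

FF_KITS = frozenset({"FF-Micro", "FF-Blood"})
FFPE_KITS = frozenset({"GeneRead", "Maxwell", "QIAamp"})

#: key used throughout for position identity
PosKey = tuple[str, int, str]
#: key used for allele identity (somatic subtraction, overlap)
AlleleKey = tuple[str, int, str, str]


class VcfFormatError(ValueError):
    """Raised for malformed VCF content, carrying line context when known."""


@dataclass(slots=True)
class VariantRecord:
    """One called variant for one sample.

    ``ad`` is aligned with ``[ref] + alts``; ``genotype`` is the ordered
    pair of allele indices from GT (0 = ref).
    """

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    genotype: tuple[int, int]
    dp: Optional[int] = None
    mq: Optional[float] = None
    ad: Optional[tuple[int, ...]] = None
    vclass: str = ""  # derived; filled on construction

    def __post_init__(self) -> None:
        if not self.ref or "" in self.alts:
            raise ValueError(f"empty allele at {self.chrom}:{self.pos}")
        if self.ad is not None and len(self.ad) != 1 + len(self.alts):
            raise ValueError(
                f"AD length {len(self.ad)} != 1 + {len(self.alts)} alts "
                f"at {self.chrom}:{self.pos}"
            )
        if not self.vclass:
            self.vclass = classify_variant(self)

    @property
    def key(self) -> PosKey:
        return (self.chrom, self.pos, self.ref)

    def allele_keys(self) -> list[AlleleKey]:
        return [(self.chrom, self.pos, self.ref, a) for a in self.alts]


def classify_variant(rec: VariantRecord) -> str:
    """SNV iff ref and every alt are single bases; anything else is INDEL."""
    if not rec.ref or not rec.alts or "" in rec.alts:
        raise ValueError("empty allele string")
    if len(rec.ref) != 1:
        return INDEL
    for a in rec.alts:
        if len(a) != 1:
            return INDEL
    return SNV


def compute_vaf(rec: VariantRecord, alt_index: int = 0) -> float:
    """Variant allele frequency: alt-allele depth over total depth (AD/DP)."""
    if rec.ad is None:
        raise ValueError(f"no AD at {rec.chrom}:{rec.pos}; VAF undefined")
    if not rec.dp:
        raise ValueError(f"DP is zero/missing at {rec.chrom}:{rec.pos}; VAF undefined")
    return rec.ad[alt_index + 1] / rec.dp


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    tissue: str = "liver"
    condition: str = "FF"
    kit: str = "FF-Micro"
    state: str = "normal"

    def __post_init__(self) -> None:
        if self.condition not in ("FF", "FFPE"):
            raise ValueError(f"condition must be FF or FFPE, got {self.condition!r}")
        if self.condition == "FF" and self.kit not in FF_KITS:
            raise ValueError(
                f"FF sample {self.sample_id} must use an FF kit "
                f"({sorted(FF_KITS)}), got {self.kit!r}"
            )
        if self.condition == "FFPE" and self.kit not in FFPE_KITS:
            raise ValueError(
                f"FFPE sample {self.sample_id} must use an FFPE kit "
                f"({sorted(FFPE_KITS)}), got {self.kit!r}"
            )


@dataclass
class FilterTally:
    n_input: int = 0
    n_kept: int = 0
    n_removed: int = 0
    n_unfilterable: int = 0  # missing DP or MQ; dropped, counted separately


def _chrom_sort_key(chrom: str) -> tuple[int, str]:
    body = chrom[3:] if chrom.startswith("chr") else chrom
    return (int(body), "") if body.isdigit() else (10**6, body)


@dataclass
class VariantSet:
    """A sample's call set, unique per (chrom, pos, ref)."""

    meta: SampleMeta
    records: dict[PosKey, VariantRecord] = field(default_factory=dict)
    filter_tally: Optional[FilterTally] = None

    def add(self, rec: VariantRecord) -> None:
        key = (rec.chrom, rec.pos, rec.ref)
        if key in self.records:
            raise ValueError(f"duplicate record at {key}")
        self.records[key] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[VariantRecord]:
        return iter(self.records.values())

    def sorted_records(self) -> list[VariantRecord]:
        return sorted(
            self.records.values(),
            key=lambda r: (_chrom_sort_key(r.chrom), r.pos, r.ref),
        )

    def subset(self, vclass: str) -> "VariantSet":
        return VariantSet(
            meta=self.meta,
            records={k: r for k, r in self.records.items() if r.vclass == vclass},
        )

    def allele_key_set(self) -> set[AlleleKey]:
        keys: set[AlleleKey] = set()
        for rec in self.records.values():
            keys.update(rec.allele_keys())
        return keys


def _normalize_chrom(chrom: str) -> str:
    return chrom if chrom.startswith("chr") else f"chr{chrom}"


def read_vcf(path: str | Path, sample_id: str, meta: Optional[SampleMeta] = None) -> VariantSet:
    """Read one sample's calls from a VCF (v4.x, plain or bgzipped).

    Rows whose genotype is fully missing (./.) or carries no alt allele for
    this sample are skipped.  Multi-allelic rows become a single record with
    the full alt list.  DP is taken from FORMAT/DP with fallback to INFO/DP;
    MQ from INFO/MQ.
    """
    path = str(path)
    try:
        vf = pysam.VariantFile(path)
    except (ValueError, OSError) as exc:
        raise VcfFormatError(f"cannot open VCF {path}: {exc}") from exc
    if sample_id not in vf.header.samples:
        raise ValueError(
            f"sample {sample_id!r} not in {path}; "
            f"available: {list(vf.header.samples)}"
        )
    vs = VariantSet(meta=meta or SampleMeta(sample_id=sample_id))
    n_row = 0
    try:
        for row in vf:
            n_row += 1
            if row.alts is None:
                continue
            call = row.samples[sample_id]
            gt = call.get("GT")
            if gt is None or all(g is None for g in gt):
                continue
            gt = tuple(0 if g is None else int(g) for g in gt)
            if len(gt) == 1:
                gt = (gt[0], gt[0])
            if all(g == 0 for g in gt):
                continue
            dp = call.get("DP")
            if dp is None:
                dp = row.info.get("DP")
            mq = row.info.get("MQ")
            if mq is not None:
                mq = round(float(mq), 4)  # undo float32 widening noise
            ad = call.get("AD")
            if ad is not None and any(a is None for a in ad):
                ad = None
            vs.add(
                VariantRecord(
                    chrom=_normalize_chrom(row.chrom),
                    pos=row.pos,
                    ref=row.ref,
                    alts=tuple(row.alts),
                    genotype=gt,
                    dp=None if dp is None else int(dp),
                    mq=None if mq is None else float(mq),
                    ad=None if ad is None else tuple(int(a) for a in ad),
                )
            )
    except (ValueError, OSError) as exc:
        raise VcfFormatError(f"malformed VCF {path} near record {n_row + 1}: {exc}") from exc
    return vs


def apply_quality_filter(
    vs: VariantSet, min_dp: int = 13, min_mq: float = 43
) -> VariantSet:
    """Keep records with DP >= min_dp and MQ >= min_mq (both inclusive).

    Records missing DP or MQ fail conservatively and are tallied as
    "unfilterable".  Counts are logged and attached as ``filter_tally``.
    """
    tally = FilterTally(n_input=len(vs))
    kept: dict[PosKey, VariantRecord] = {}
    for key, rec in vs.records.items():
        if rec.dp is None or rec.mq is None:
            tally.n_unfilterable += 1
        elif rec.dp >= min_dp and rec.mq >= min_mq:
            kept[key] = rec
            continue
        tally.n_removed += 1
    out = VariantSet(meta=vs.meta, records=kept, filter_tally=tally)
    tally.n_kept = len(out)
    log.info(
        "quality filter (DP>=%s, MQ>=%s) on %s: kept %d / %d (%d removed, %d unfilterable)",
        min_dp, min_mq, vs.meta.sample_id,
        tally.n_kept, tally.n_input, tally.n_removed, tally.n_unfilterable,
    )
    return out


# ---------------------------------------------------------------------------
# I/O: VCF writing, sample sheets, variant tables

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
{contigs}#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def _fmt_float(x: float) -> str:
    return f"{x:g}"


def write_vcf(vs: VariantSet, path: str | Path) -> None:
    """Write a VariantSet as a minimal sorted VCF v4.2."""
    chroms = sorted({r.chrom for r in vs}, key=_chrom_sort_key)
    contigs = "".join(f"##contig=<ID={c}>\n" for c in chroms)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(contigs=contigs, sample=vs.meta.sample_id))
        for rec in vs.sorted_records():
            info = "." if rec.mq is None else f"MQ={_fmt_float(rec.mq)}"
            fmt_keys, fmt_vals = ["GT"], [f"{rec.genotype[0]}/{rec.genotype[1]}"]
            if rec.dp is not None:
                fmt_keys.append("DP")
                fmt_vals.append(str(rec.dp))
            if rec.ad is not None:
                fmt_keys.append("AD")
                fmt_vals.append(",".join(map(str, rec.ad)))
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{','.join(rec.alts)}"
                f"\t.\t.\t{info}\t{':'.join(fmt_keys)}\t{':'.join(fmt_vals)}\n"
            )


def variant_table(vs: VariantSet) -> pd.DataFrame:
    """Flat per-alt table: chrom, pos, ref, alt, class, dp, mq, vaf."""
    rows = []
    for rec in vs.sorted_records():
        for i, alt in enumerate(rec.alts):
            vaf = None
            if rec.ad is not None and rec.dp:
                vaf = compute_vaf(rec, i)
            rows.append(
                dict(chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt,
                     vclass=rec.vclass, dp=rec.dp, mq=rec.mq, vaf=vaf)
            )
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "vclass", "dp", "mq", "vaf"]
    )


SHEET_COLUMNS = ["sample_id", "tissue", "condition", "kit", "state"]


def read_sample_sheet(path: str | Path) -> dict[str, SampleMeta]:
    """TSV with header sample_id/tissue/condition/kit/state -> metadata map."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample sheet {path} missing columns: {missing}")
    out: dict[str, SampleMeta] = {}
    for _, row in df.iterrows():
        meta = SampleMeta(**{c: row[c] for c in SHEET_COLUMNS})
        if meta.sample_id in out:
            raise ValueError(f"duplicate sample_id {meta.sample_id!r} in {path}")
        out[meta.sample_id] = meta
    return out


def write_sample_sheet(metas: Iterable[SampleMeta], path: str | Path) -> None:
    pd.DataFrame(
        [{c: getattr(m, c) for c in SHEET_COLUMNS} for m in metas]
    ).to_csv(path, sep="\t", index=False)
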