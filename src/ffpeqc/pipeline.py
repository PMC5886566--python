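"""End-to-end report assembly over a directory of inputs.

``run_pipeline`` consumes a sample sheet, a pair sheet and the per-sample
VCF / depth / read-placement / flag-count files, applies the quality
filter, and writes one TSV per analysis stage: pair concordance (SNV and
INDEL), per-kit variant-difference summaries, substitution spectra,
somatic overlap (when tumor/normal samples are present) and coverage QC.
A JSON run log records thresholds, modes and filter tallies.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .artifact_spectrum import spectrum_table, substitution_spectrum
from .concordance import kit_difference_stats, kit_table, pair_summary, pair_table
from .coverage_qc import (
    TargetRegions,
    load_depth_track,
    read_bed,
    read_flag_counts,
    summarize_coverage,
)
from .somatic import condition_overlap, somatic_table, tumor_specific
from .variant_io import (
    INDEL,
    SNV,
    VariantSet,
    apply_quality_filter,
    read_sample_sheet,
    read_vcf,
)

log = logging.getLogger(__name__)

MIN_READS_WARN = 80_000_000  # pre-normalization read-count quality gate


@dataclass
class RunConfig:
    input_dir: str
    out_dir: str
    sample_sheet: str = "sample_sheet.tsv"
    pair_sheet: str = "pair_sheet.tsv"
    targets_bed: Optional[str] = "targets.bed"
    flag_counts: Optional[str] = "flagcounts.tsv"
    min_dp: int = 13
    min_mq: float = 43.0
    concordance_mode: str = "genotype"
    cov_threshold: int = 30
    vcf_pattern: str = "{sample_id}.vcf"
    depth_pattern: str = "depth_{sample_id}.tsv"
    reads_pattern: str = "reads_{sample_id}.bed"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls(**data)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage the inputs support; returns the report manifest."""
    in_dir, out_dir = Path(cfg.input_dir), Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    metas = read_sample_sheet(in_dir / cfg.sample_sheet)
    pair_df = pd.read_csv(in_dir / cfg.pair_sheet, sep="\t")
    if pair_df.empty:
        raise ValueError("no pairs defined in pair sheet")

    filtered: dict[str, VariantSet] = {}
    tallies = {}
    for sample_id, meta in metas.items():
        vcf = in_dir / cfg.vcf_pattern.format(sample_id=sample_id)
        if not vcf.exists():
            raise FileNotFoundError(f"stage variant_io: missing VCF {vcf}")
        vs = apply_quality_filter(
            read_vcf(vcf, sample_id, meta), cfg.min_dp, cfg.min_mq
        )
        filtered[sample_id] = vs
        tallies[sample_id] = vars(vs.filter_tally)

    # concordance per pair, both variant classes
    summaries = []
    kit_map = {}
    for row in pair_df.itertuples(index=False):
        kit_map[str(row.pair_id)] = row.kit
        for vclass in (SNV, INDEL):
            summaries.append(
                pair_summary(
                    filtered[row.ff_sample], filtered[row.ffpe_sample],
                    vclass, pair_id=str(row.pair_id), mode=cfg.concordance_mode,
                )
            )
    pair_table(summaries).to_csv(out_dir / "concordance.tsv", sep="\t", index=False)
    kit_table(kit_difference_stats(summaries, kit_map)).to_csv(
        out_dir / "kit_summary.tsv", sep="\t", index=False
    )

    spectra = [substitution_spectrum(vs.subset(SNV)) for vs in filtered.values()]
    spectrum_table(spectra).to_csv(out_dir / "artifact_spectrum.tsv", sep="\t", index=False)

    # somatic subtraction wherever a tissue has tumor+normal per condition
    somatic_rows = []
    by_key = {
        (m.tissue, m.condition, m.state): s
        for s, m in metas.items()
    }
    for tissue in sorted({m.tissue for m in metas.values()}):
        per_cond = {}
        for cond in ("FF", "FFPE"):
            t = by_key.get((tissue, cond, "tumor"))
            n = by_key.get((tissue, cond, "normal"))
            if t and n:
                per_cond[cond] = tumor_specific(
                    filtered[t].subset(SNV), filtered[n].subset(SNV)
                )
        if len(per_cond) == 2:
            somatic_rows.append(condition_overlap(per_cond["FF"], per_cond["FFPE"], tissue))
    if somatic_rows:
        somatic_table(somatic_rows).to_csv(out_dir / "somatic.tsv", sep="\t", index=False)

    # coverage QC where depth tracks exist
    cov_rows = []
    targets_path = in_dir / cfg.targets_bed if cfg.targets_bed else None
    if targets_path and targets_path.exists():
        targets = TargetRegions.from_bed(targets_path)
        flags = {}
        if cfg.flag_counts and (in_dir / cfg.flag_counts).exists():
            flags = read_flag_counts(in_dir / cfg.flag_counts)
            for sample_id, (total, _) in flags.items():
                if total < MIN_READS_WARN:
                    log.warning(
                        "sample %s has %d reads, below the %d pre-normalization gate",
                        sample_id, total, MIN_READS_WARN,
                    )
        for sample_id in metas:
            depth = in_dir / cfg.depth_pattern.format(sample_id=sample_id)
            if not depth.exists():
                continue
            reads_path = in_dir / cfg.reads_pattern.format(sample_id=sample_id)
            reads = read_bed(reads_path) if reads_path.exists() else None
            summary = summarize_coverage(
                sample_id, load_depth_track(depth, targets),
                t=cfg.cov_threshold, flag_counts=flags.get(sample_id),
                read_intervals=reads,
            )
            row = vars(summary).copy()
            row.update(summary.qc_flags())
            cov_rows.append(row)
    if cov_rows:
        pd.DataFrame(cov_rows).to_csv(out_dir / "coverage_qc.tsv", sep="\t", index=False)

    run_log = dict(
        version=__version__,
        min_dp=cfg.min_dp, min_mq=cfg.min_mq,
        concordance_mode=cfg.concordance_mode,
        cov_threshold=cfg.cov_threshold,
        n_samples=len(metas), n_pairs=len(pair_df),
        filter_tallies=tallies,
        outputs=sorted(p.name for p in out_dir.iterdir()),
    )
    (out_dir / "run_log.json").write_text(json.dumps(run_log, indent=1, sort_keys=True))
    return run_log
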