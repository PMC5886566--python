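"""Synthetic matched FF/FFPE data with a truth ledger.

The generator emulates the statistical structure the analysis assumes,
variant-list level (no reads are simulated):

* a shared germline core of SNV + INDEL calls on a two-chromosome 10 Mb
  coordinate space;
* FFPE-specific dropout (calls missing from the FFPE list), a small
  FF-private rate, and FFPE-only C>T / G>A deamination artifacts injected
  at fresh positions;
* low-rate base-call discordance at shared positions (alt swap by default,
  genotype flip optionally);
* depth/MQ annotations drawn around condition-specific means, with FFPE
  coverage attenuated;
* per-base depth tracks, read placements with a controlled off-target
  fraction, and duplicate flag counts.

Every injected quantity is recorded in a :class:`TruthLedger` at injection
time, so pipeline estimates can be checked against exact truth.

All randomness flows through one :class:`numpy.random.Generator` seeded
from ``SimulationConfig.seed``; identical configs give byte-identical
fixture bundles.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .variant_io import (
    SampleMeta,
    VariantRecord,
    VariantSet,
    write_sample_sheet,
    write_vcf,
)

#: synthetic coordinate space: two 5 Mb chromosomes
GENOME: dict[str, int] = {"chr1": 5_000_000, "chr2": 5_000_000}
GENOME_SIZE = sum(GENOME.values())

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for the synthetic cohort.

    Defaults reproduce the regime of a deep whole-exome FF/FFPE comparison:
    ~41k SNVs + ~3.7k INDELs per FF sample, ~3% of FF calls missing from
    FFPE, ~1% FFPE-private deamination artifacts, per-shared-position
    discordance of 1.5e-4 (a handful of discordant SNV calls per pair),
    FF/FFPE median depths 87.6/74.3, duplicate fractions 7.9%/12.2% and
    off-target fractions 21.3%/19.6%.
    """

    n_germline: int = 44_700
    snv_fraction: float = 0.918
    ffpe_dropout: float = 0.029
    ff_private_rate: float = 0.002
    artifact_rate: float = 0.0097        # FFPE-only C>T/G>A per germline variant
    discordance_prob: float = 1.5e-4
    background_cgta: float = 0.362       # C.G>T.A fraction of true SNVs
    het_fraction: float = 2 / 3
    discordance_mode: str = "alt"        # alt | genotype

    n_somatic: int = 1_200
    det_ff: float = 0.36
    det_ffpe: float = 0.38

    depth_mean_ff: float = 87.6
    depth_mean_ffpe: float = 74.3
    mq_mean: float = 60.0
    mq_sd: float = 1.5
    dup_ff: float = 0.079
    dup_ffpe: float = 0.122
    off_target_ff: float = 0.213
    off_target_ffpe: float = 0.196

    n_reads: int = 4_000
    read_length: int = 100
    n_target_intervals: int = 50
    target_interval_length: int = 400
    cov_threshold: int = 30

    kit: str = "GeneRead"
    tissue: str = "colon"
    seed: int = 0

    def __post_init__(self) -> None:
        probs = dict(
            snv_fraction=self.snv_fraction, ffpe_dropout=self.ffpe_dropout,
            ff_private_rate=self.ff_private_rate,
            discordance_prob=self.discordance_prob,
            background_cgta=self.background_cgta, het_fraction=self.het_fraction,
            det_ff=self.det_ff, det_ffpe=self.det_ffpe,
            dup_ff=self.dup_ff, dup_ffpe=self.dup_ffpe,
            off_target_ff=self.off_target_ff, off_target_ffpe=self.off_target_ffpe,
        )
        for name, p in probs.items():
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.depth_mean_ff <= 0 or self.depth_mean_ffpe <= 0:
            raise ValueError("depth means must be positive")
        if self.discordance_mode not in ("alt", "genotype"):
            raise ValueError("discordance_mode must be 'alt' or 'genotype'")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class TruthLedger:
    """Exact injected quantities, recorded at injection time."""

    n_germline: int = 0
    n_dropout: int = 0
    n_ff_private: int = 0
    n_artifacts: int = 0
    n_discordant: int = 0
    n_shared: int = 0                      # germline minus dropouts
    n_somatic: int = 0
    n_det_ff: int = 0
    n_det_ffpe: int = 0
    n_overlap_true: int = 0
    tracks: dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# low-level draws

def _draw_positions(rng: np.random.Generator, n: int) -> np.ndarray:
    """n distinct genome positions (0-based), deterministic given rng state."""
    drawn = np.array([], dtype=np.int64)
    while drawn.size < n:
        extra = rng.integers(0, GENOME_SIZE, size=int(1.2 * (n - drawn.size)) + 16)
        drawn = pd.unique(np.concatenate([drawn, extra]))
    return drawn[:n]


def _locate(pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Global 0-based offsets -> (chrom array, 1-based positions)."""
    size1 = GENOME["chr1"]
    chroms = np.where(pos < size1, "chr1", "chr2")
    local = np.where(pos < size1, pos, pos - size1) + 1
    return chroms, local


def _draw_snv_alleles(
    rng: np.random.Generator, n: int, cgta_fraction: float
) -> tuple[np.ndarray, np.ndarray]:
    """(ref, alt) base pairs with a controlled pooled C>T/G>A fraction."""
    refs = np.empty(n, dtype="U1")
    alts = np.empty(n, dtype="U1")
    is_cgta = rng.random(n) < cgta_fraction
    # deamination classes: C>T or G>A with equal probability
    g_strand = rng.random(n) < 0.5
    refs[is_cgta] = np.where(g_strand[is_cgta], "G", "C")
    alts[is_cgta] = np.where(g_strand[is_cgta], "A", "T")
    # remaining 10 substitution types, uniform
    others = [
        (r, a) for r in "ACGT" for a in "ACGT" if r != a and (r, a) not in (("C", "T"), ("G", "A"))
    ]
    idx = rng.integers(0, len(others), size=n)
    other_refs = np.array([o[0] for o in others])[idx]
    other_alts = np.array([o[1] for o in others])[idx]
    refs[~is_cgta] = other_refs[~is_cgta]
    alts[~is_cgta] = other_alts[~is_cgta]
    return refs, alts


def _draw_indel_alleles(
    rng: np.random.Generator, n: int
) -> tuple[np.ndarray, np.ndarray]:
    anchor = BASES[rng.integers(0, 4, size=n)]
    extra = BASES[rng.integers(0, 4, size=n)]
    is_ins = rng.random(n) < 0.5
    refs = np.where(is_ins, anchor, np.char.add(anchor, extra))
    alts = np.where(is_ins, np.char.add(anchor, extra), anchor)
    return refs, alts


def _swap_alt(rng: np.random.Generator, ref: str, alt: str) -> str:
    """A different legal alt at the same site (discordant re-call)."""
    if len(ref) == 1 and len(alt) == 1:
        options = [b for b in "ACGT" if b != ref and b != alt]
        return options[int(rng.integers(0, len(options)))]
    return alt + "ACGT"[int(rng.integers(0, 4))]  # different indel allele


def _annotate(
    rng: np.random.Generator,
    records: list[tuple[str, int, str, str, tuple[int, int]]],
    depth_mean: float,
    mq_mean: float,
    mq_sd: float,
    meta: SampleMeta,
) -> VariantSet:
    """Attach DP/MQ/AD draws and build a VariantSet."""
    n = len(records)
    dps = np.maximum(rng.poisson(depth_mean, size=n), 1).tolist()
    mqs = np.round(np.maximum(rng.normal(mq_mean, mq_sd, size=n), 0.0), 2).tolist()
    het_ad = rng.binomial(dps, 0.5).tolist()
    out: dict = {}
    het = (0, 1)
    for (chrom, pos, ref, alt, gt, vclass), dp, mq, had in zip(records, dps, mqs, het_ad):
        alt_ad = had if gt == het else dp
        out[(chrom, pos, ref)] = VariantRecord(
            chrom, pos, ref, (alt,), gt, dp, mq, (dp - alt_ad, alt_ad), vclass
        )
    if len(out) != n:  # positions are drawn without replacement upstream
        raise RuntimeError("position collision while building a simulated set")
    return VariantSet(meta=meta, records=out)


# ---------------------------------------------------------------------------
# pair simulation

def _germline_calls(
    cfg: SimulationConfig, rng: np.random.Generator, positions: np.ndarray
) -> list[tuple[str, int, str, str, tuple[int, int]]]:
    n = len(positions)
    chroms, local = _locate(positions)
    is_snv = rng.random(n) < cfg.snv_fraction
    refs = np.empty(n, dtype="U2")
    alts = np.empty(n, dtype="U2")
    s_ref, s_alt = _draw_snv_alleles(rng, n, cfg.background_cgta)
    i_ref, i_alt = _draw_indel_alleles(rng, n)
    refs[is_snv], alts[is_snv] = s_ref[is_snv], s_alt[is_snv]
    refs[~is_snv], alts[~is_snv] = i_ref[~is_snv], i_alt[~is_snv]
    het = rng.random(n) < cfg.het_fraction
    return [
        (c, int(p), r, a, (0, 1) if h else (1, 1), "SNV" if s else "INDEL")
        for c, p, r, a, h, s in zip(chroms, local, refs, alts, het, is_snv)
    ]


def simulate_pair(
    cfg: SimulationConfig, rng: Optional[np.random.Generator] = None,
    pair_tag: str = "P1",
) -> tuple[VariantSet, VariantSet, TruthLedger]:
    """One matched FF/FFPE call-set pair plus the exact truth ledger."""
    rng = rng or cfg.rng()
    ledger = TruthLedger(n_germline=cfg.n_germline)

    n_private = rng.binomial(cfg.n_germline, cfg.ff_private_rate)
    n_artifacts = rng.poisson(cfg.artifact_rate * cfg.n_germline)
    pos = _draw_positions(rng, cfg.n_germline + n_private + n_artifacts)
    core = _germline_calls(cfg, rng, pos[: cfg.n_germline])
    private = _germline_calls(
        cfg, rng, pos[cfg.n_germline: cfg.n_germline + n_private]
    )
    ledger.n_ff_private = n_private

    # FFPE deamination artifacts: C>T or G>A SNVs at fresh positions
    art_chroms, art_local = _locate(pos[cfg.n_germline + n_private:])
    g_strand = rng.random(n_artifacts) < 0.5
    artifacts = [
        (c, int(p), "G" if g else "C", "A" if g else "T", (0, 1), "SNV")
        for c, p, g in zip(art_chroms, art_local, g_strand)
    ]
    ledger.n_artifacts = n_artifacts

    drop = rng.random(cfg.n_germline) < cfg.ffpe_dropout
    ledger.n_dropout = int(drop.sum())
    ledger.n_shared = cfg.n_germline - ledger.n_dropout

    discord = (rng.random(cfg.n_germline) < cfg.discordance_prob) & ~drop
    ledger.n_discordant = int(discord.sum())

    ffpe_calls = []
    for i, call in enumerate(core):
        if drop[i]:
            continue
        if discord[i]:
            chrom, p, ref, alt, gt, vclass = call
            if cfg.discordance_mode == "alt":
                call = (chrom, p, ref, _swap_alt(rng, ref, alt), gt, vclass)
            else:
                call = (chrom, p, ref, alt, (1, 1) if gt == (0, 1) else (0, 1), vclass)
        ffpe_calls.append(call)
    ffpe_calls.extend(artifacts)

    ff_meta = SampleMeta(f"FF_{pair_tag}", cfg.tissue, "FF", "FF-Micro", "normal")
    ffpe_meta = SampleMeta(f"FFPE_{pair_tag}", cfg.tissue, "FFPE", cfg.kit, "normal")
    ff = _annotate(rng, core + private, cfg.depth_mean_ff, cfg.mq_mean, cfg.mq_sd, ff_meta)
    ffpe = _annotate(rng, ffpe_calls, cfg.depth_mean_ffpe, cfg.mq_mean, cfg.mq_sd, ffpe_meta)
    return ff, ffpe, ledger


def simulate_tumor_normal(
    cfg: SimulationConfig, rng: Optional[np.random.Generator] = None,
) -> tuple[VariantSet, VariantSet, VariantSet, VariantSet, TruthLedger]:
    """(tumor_ff, normal_ff, tumor_ffpe, normal_ffpe, ledger).

    Somatic variants exist only in tumor samples and are detected
    independently per condition with det_ff / det_ffpe.  The germline
    background is shared within each condition so matched-normal
    subtraction recovers exactly the detected somatic calls.
    """
    rng = rng or cfg.rng()
    ledger = TruthLedger(n_germline=cfg.n_germline, n_somatic=cfg.n_somatic)

    pos = _draw_positions(rng, cfg.n_germline + cfg.n_somatic)
    germline = _germline_calls(cfg, rng, pos[: cfg.n_germline])
    som_chroms, som_local = _locate(pos[cfg.n_germline:])
    s_ref, s_alt = _draw_snv_alleles(rng, cfg.n_somatic, cfg.background_cgta)
    somatic = [
        (c, int(p), r, a, (0, 1), "SNV")
        for c, p, r, a in zip(som_chroms, som_local, s_ref, s_alt)
    ]

    drop = rng.random(cfg.n_germline) < cfg.ffpe_dropout
    germline_ffpe = [g for g, d in zip(germline, drop) if not d]
    det_ff = rng.random(cfg.n_somatic) < cfg.det_ff
    det_ffpe = rng.random(cfg.n_somatic) < cfg.det_ffpe
    ledger.n_dropout = int(drop.sum())
    ledger.n_det_ff = int(det_ff.sum())
    ledger.n_det_ffpe = int(det_ffpe.sum())
    ledger.n_overlap_true = int((det_ff & det_ffpe).sum())

    ts = cfg.tissue

    def build(name, cond, kit, state, calls, depth):
        meta = SampleMeta(name, ts, cond, kit, state)
        return _annotate(rng, calls, depth, cfg.mq_mean, cfg.mq_sd, meta)

    tumor_ff = build("T_FF", "FF", "FF-Micro", "tumor",
                     germline + [s for s, d in zip(somatic, det_ff) if d],
                     cfg.depth_mean_ff)
    normal_ff = build("N_FF", "FF", "FF-Micro", "normal", germline, cfg.depth_mean_ff)
    tumor_ffpe = build("T_FFPE", "FFPE", cfg.kit, "tumor",
                       germline_ffpe + [s for s, d in zip(somatic, det_ffpe) if d],
                       cfg.depth_mean_ffpe)
    normal_ffpe = build("N_FFPE", "FFPE", cfg.kit, "normal", germline_ffpe,
                        cfg.depth_mean_ffpe)
    return tumor_ff, normal_ff, tumor_ffpe, normal_ffpe, ledger


# ---------------------------------------------------------------------------
# coverage inputs

def make_targets(cfg: SimulationConfig) -> pd.DataFrame:
    """Evenly spaced synthetic capture targets as a BED table."""
    rows = []
    per_chrom = cfg.n_target_intervals // 2
    for chrom, size in GENOME.items():
        step = size // (per_chrom + 1)
        for i in range(per_chrom):
            start = (i + 1) * step
            rows.append((chrom, start, start + cfg.target_interval_length))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def simulate_depth_track(
    cfg: SimulationConfig,
    targets: pd.DataFrame,
    condition: str = "FFPE",
    rng: Optional[np.random.Generator] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, tuple[int, int], dict]:
    """(depth track, read BED, (total, duplicate) counts, track truth).

    Depths are Poisson around the condition mean over every targeted base;
    reads are placed with exactly the realized Binomial off-target count
    fully outside targets (the rest overlap a target by >= 1 base).
    """
    rng = rng or cfg.rng()
    ffpe = condition == "FFPE"
    depth_mean = cfg.depth_mean_ffpe if ffpe else cfg.depth_mean_ff
    off_rate = cfg.off_target_ffpe if ffpe else cfg.off_target_ff
    dup_rate = cfg.dup_ffpe if ffpe else cfg.dup_ff

    base_rows = []
    depth_values = []
    for chrom, start, end in targets[["chrom", "start", "end"]].itertuples(index=False):
        depths = rng.poisson(depth_mean, size=end - start)
        positions = np.arange(start + 1, end + 1)  # 1-based
        base_rows.append(pd.DataFrame({"chrom": chrom, "pos": positions, "depth": depths}))
        depth_values.append(depths)
    depth_df = pd.concat(base_rows, ignore_index=True)
    all_depths = np.concatenate(depth_values)

    # read placement: k_off fully in inter-target gaps, rest overlapping
    n_off = int(rng.binomial(cfg.n_reads, off_rate))
    reads = []
    gaps = _gaps(targets, cfg.read_length)
    gap_caps = np.array([e - s - cfg.read_length + 1 for _, s, e in gaps], dtype=float)
    gap_p = gap_caps / gap_caps.sum()
    for _ in range(n_off):
        gi = int(rng.choice(len(gaps), p=gap_p))
        chrom, gs, ge = gaps[gi]
        start = int(rng.integers(gs, ge - cfg.read_length + 1))
        reads.append((chrom, start, start + cfg.read_length))
    tgt = targets[["chrom", "start", "end"]].to_numpy(object)
    lengths = (targets["end"] - targets["start"]).to_numpy()
    tgt_p = lengths / lengths.sum()
    for _ in range(cfg.n_reads - n_off):
        ti = int(rng.choice(len(tgt), p=tgt_p))
        chrom, s, e = tgt[ti]
        base = int(rng.integers(s, e))
        offset = min(int(rng.integers(0, cfg.read_length)), base)
        reads.append((chrom, base - offset, base - offset + cfg.read_length))
    read_df = pd.DataFrame(reads, columns=["chrom", "start", "end"])

    n_dup = int(round(dup_rate * cfg.n_reads))
    truth = dict(
        n_bases=int(all_depths.size),
        n_ge_threshold=int((all_depths >= cfg.cov_threshold).sum()),
        exceedance_fraction=float((all_depths >= cfg.cov_threshold).mean()),
        n_reads=cfg.n_reads,
        n_off_target=n_off,
        n_duplicates=n_dup,
    )
    return depth_df, read_df, (cfg.n_reads, n_dup), truth


def _gaps(targets: pd.DataFrame, min_len: int) -> list[tuple[str, int, int]]:
    gaps = []
    for chrom, size in GENOME.items():
        sub = targets[targets.chrom == chrom].sort_values("start")
        prev = 0
        for s, e in sub[["start", "end"]].itertuples(index=False):
            if s - prev >= min_len:
                gaps.append((chrom, prev, int(s)))
            prev = int(e)
        if size - prev >= min_len:
            gaps.append((chrom, prev, size))
    return gaps


# ---------------------------------------------------------------------------
# fixture bundles

def write_fixture_bundle(cfg: SimulationConfig, out_dir: str | Path) -> dict:
    """Write a complete, deterministic input bundle; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = cfg.rng()

    ff, ffpe, pair_ledger = simulate_pair(cfg, rng)
    t_ff, n_ff, t_ffpe, n_ffpe, som_ledger = simulate_tumor_normal(cfg, rng)

    targets = make_targets(cfg)
    targets.to_csv(out / "targets.bed", sep="\t", header=False, index=False)

    tracks = {}
    for cond, sample in (("FF", ff.meta.sample_id), ("FFPE", ffpe.meta.sample_id)):
        depth_df, read_df, flags, truth = simulate_depth_track(cfg, targets, cond, rng)
        depth_df.to_csv(out / f"depth_{sample}.tsv", sep="\t", header=False, index=False)
        read_df.to_csv(out / f"reads_{sample}.bed", sep="\t", header=False, index=False)
        tracks[sample] = dict(truth=truth, flags=flags)

    pd.DataFrame(
        [
            dict(sample_id=s, total_reads=tracks[s]["flags"][0],
                 duplicate_reads=tracks[s]["flags"][1])
            for s in tracks
        ]
    ).to_csv(out / "flagcounts.tsv", sep="\t", index=False)

    sets = {vs.meta.sample_id: vs for vs in (ff, ffpe, t_ff, n_ff, t_ffpe, n_ffpe)}
    for sample, vs in sets.items():
        write_vcf(vs, out / f"{sample}.vcf")

    write_sample_sheet([vs.meta for vs in sets.values()], out / "sample_sheet.tsv")
    pd.DataFrame(
        [dict(pair_id="P1", ff_sample=ff.meta.sample_id,
              ffpe_sample=ffpe.meta.sample_id, kit=cfg.kit)]
    ).to_csv(out / "pair_sheet.tsv", sep="\t", index=False)

    ledger = pair_ledger.to_dict()
    ledger.update({k: v for k, v in som_ledger.to_dict().items()
                   if k.startswith(("n_somatic", "n_det", "n_overlap"))})
    ledger["tracks"] = {s: tracks[s]["truth"] for s in tracks}
    (out / "truth.json").write_text(json.dumps(ledger, indent=1, sort_keys=True))

    manifest = dict(
        config=dataclasses.asdict(cfg),
        files=sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
        samples=sorted(sets),
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
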