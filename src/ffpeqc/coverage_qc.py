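"""Exome-capture coverage indicators.

Inputs are the text artifacts a standard alignment pipeline already emits:
a 3-column per-base depth track (chrom, 1-based position, depth), the
capture-kit target BED, a BED of read placements, and a flag-count table of
total/duplicate reads.  All indicators are computed over the full merged
target space — targeted bases absent from the depth track count as depth 0,
so the denominators never shrink when coverage drops out.

A read is on-target when it overlaps any target interval by at least one
base (the usual capture-QC convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd


@dataclass
class TargetRegions:
    """Merged, non-overlapping target intervals (0-based half-open)."""

    starts: dict[str, np.ndarray] = field(default_factory=dict)
    ends: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def from_intervals(cls, intervals: Iterable[tuple[str, int, int]]) -> "TargetRegions":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            if start >= end:
                raise ValueError(f"empty/inverted interval {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((int(start), int(end)))
        tr = cls()
        for chrom, ivs in sorted(by_chrom.items()):
            merged: list[list[int]] = []
            for s, e in sorted(ivs):
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            arr = np.array(merged, dtype=np.int64)
            tr.starts[chrom] = arr[:, 0]
            tr.ends[chrom] = arr[:, 1]
        return tr

    @classmethod
    def from_bed(cls, path: str | Path) -> "TargetRegions":
        df = read_bed(path)
        return cls.from_intervals(df[["chrom", "start", "end"]].itertuples(index=False))

    @property
    def total_bases(self) -> int:
        return int(sum((self.ends[c] - self.starts[c]).sum() for c in self.starts))

    def intervals(self) -> list[tuple[str, int, int]]:
        return [
            (c, int(s), int(e))
            for c in self.starts
            for s, e in zip(self.starts[c], self.ends[c])
        ]

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True iff [start, end) overlaps a target by >= 1 base."""
        if chrom not in self.starts:
            return False
        i = np.searchsorted(self.starts[chrom], end, side="left")
        return i > 0 and self.ends[chrom][i - 1] > start


def read_bed(path: str | Path) -> pd.DataFrame:
    names = ["chrom", "start", "end", "name"]
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except Exception as exc:
        raise ValueError(f"malformed BED {path}: {exc}") from exc
    if df.shape[1] < 3:
        raise ValueError(f"BED {path} needs >= 3 columns, found {df.shape[1]}")
    df = df.iloc[:, : min(4, df.shape[1])]
    df.columns = names[: df.shape[1]]
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


@dataclass
class CoverageProfile:
    """Per-base depth over the target space; unlisted bases are depth 0."""

    targets: TargetRegions
    depths: dict[str, np.ndarray]  # per chrom, concatenated over intervals

    @classmethod
    def zeros(cls, targets: TargetRegions) -> "CoverageProfile":
        return cls(
            targets=targets,
            depths={
                c: np.zeros(int((targets.ends[c] - targets.starts[c]).sum()), dtype=np.int64)
                for c in targets.starts
            },
        )

    def all_depths(self) -> np.ndarray:
        if not self.depths:
            return np.zeros(0, dtype=np.int64)
        return np.concatenate([self.depths[c] for c in sorted(self.depths)])

    def _base_index(self, chrom: str, pos0: np.ndarray) -> np.ndarray:
        """Map 0-based positions to indices into this chrom's depth array.

        Positions outside the targets map to -1.
        """
        starts, ends = self.targets.starts[chrom], self.targets.ends[chrom]
        offsets = np.concatenate([[0], np.cumsum(ends - starts)[:-1]])
        i = np.searchsorted(starts, pos0, side="right") - 1
        ok = (i >= 0) & (pos0 < ends[np.clip(i, 0, None)])
        idx = np.where(ok, offsets[np.clip(i, 0, None)] + pos0 - starts[np.clip(i, 0, None)], -1)
        return idx


def load_depth_track(path: str | Path, targets: TargetRegions) -> CoverageProfile:
    """Read a chrom/pos/depth text track restricted to the target space."""
    try:
        df = pd.read_csv(
            path, sep=r"\s+", header=None, names=["chrom", "pos", "depth"],
            dtype={"chrom": str, "pos": np.int64, "depth": np.int64},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"malformed depth track {path}: {exc}") from exc
    profile = CoverageProfile.zeros(targets)
    for chrom, grp in df.groupby("chrom", sort=False):
        if chrom not in targets.starts:
            continue
        idx = profile._base_index(str(chrom), grp["pos"].to_numpy() - 1)
        keep = idx >= 0
        profile.depths[str(chrom)][idx[keep]] = grp["depth"].to_numpy()[keep]
    return profile


def pct_ge_threshold(profile: CoverageProfile, t: int = 30) -> float:
    """Percent of targeted bases with depth >= t (zero-depth bases included)."""
    depths = profile.all_depths()
    if depths.size == 0:
        raise ValueError("empty target space")
    return float(100 * np.count_nonzero(depths >= t) / depths.size)


def median_coverage(profile: CoverageProfile) -> float:
    """Median depth over all targeted bases (even count: mean of middle two)."""
    depths = profile.all_depths()
    if depths.size == 0:
        raise ValueError("empty target space")
    return float(np.median(depths))


def off_target_fraction(read_intervals: pd.DataFrame, targets: TargetRegions) -> float:
    """Percent of reads with zero overlap with any target interval."""
    n = len(read_intervals)
    if n == 0:
        raise ValueError("no reads")
    n_off = sum(
        not targets.overlaps(str(r.chrom), int(r.start), int(r.end))
        for r in read_intervals.itertuples(index=False)
    )
    return 100 * n_off / n


def duplicate_fraction(total_reads: int, duplicate_reads: int) -> float:
    """Percent of reads flagged as duplicates."""
    if total_reads <= 0:
        raise ValueError("total read count must be positive")
    if duplicate_reads > total_reads:
        raise ValueError("duplicate count exceeds total reads")
    return 100 * duplicate_reads / total_reads


def gene_mean_coverage(
    profile: CoverageProfile, gene_intervals: pd.DataFrame
) -> dict[str, float]:
    """Mean depth per gene over its merged intervals, zeros included.

    ``gene_intervals`` is a named BED table (chrom/start/end/name); bases of
    a gene lying outside the target space count as depth 0.
    """
    if "name" not in gene_intervals.columns:
        raise ValueError("gene BED requires a 4th (name) column")
    out: dict[str, float] = {}
    for gene, grp in gene_intervals.groupby("name", sort=True):
        regions = TargetRegions.from_intervals(
            grp[["chrom", "start", "end"]].itertuples(index=False)
        )
        n_bases = regions.total_bases
        if n_bases == 0:
            raise ValueError(f"gene {gene!r} has an empty interval set")
        total = 0
        for chrom, s, e in regions.intervals():
            if chrom not in profile.depths:
                continue
            pos0 = np.arange(s, e, dtype=np.int64)
            idx = profile._base_index(chrom, pos0)
            total += int(profile.depths[chrom][idx[idx >= 0]].sum())
        out[str(gene)] = total / n_bases
    return out


# ---------------------------------------------------------------------------
# QC gates

@dataclass(frozen=True)
class QcGates:
    """Pass/fail thresholds for whole-exome coverage quality."""

    min_pct_ge_30x: float = 80.0
    min_median_cov: float = 60.0
    max_duplicate_pct: float = 25.0


@dataclass(frozen=True)
class CoverageSummary:
    sample_id: str
    pct_ge_30x: float
    median_cov: float
    duplicate_pct: Optional[float] = None
    off_target_pct: Optional[float] = None

    def qc_flags(self, gates: QcGates = QcGates()) -> dict[str, bool]:
        flags = {
            "pct_ge_30x_pass": self.pct_ge_30x >= gates.min_pct_ge_30x,
            "median_cov_pass": self.median_cov >= gates.min_median_cov,
        }
        if self.duplicate_pct is not None:
            flags["duplicate_pct_pass"] = self.duplicate_pct <= gates.max_duplicate_pct
        return flags


def summarize_coverage(
    sample_id: str,
    profile: CoverageProfile,
    t: int = 30,
    flag_counts: Optional[tuple[int, int]] = None,
    read_intervals: Optional[pd.DataFrame] = None,
) -> CoverageSummary:
    dup = duplicate_fraction(*flag_counts) if flag_counts else None
    off = (
        off_target_fraction(read_intervals, profile.targets)
        if read_intervals is not None
        else None
    )
    return CoverageSummary(
        sample_id=sample_id,
        pct_ge_30x=pct_ge_threshold(profile, t),
        median_cov=median_coverage(profile),
        duplicate_pct=dup,
        off_target_pct=off,
    )


def read_flag_counts(path: str | Path) -> dict[str, tuple[int, int]]:
    """TSV with columns sample_id / total_reads / duplicate_reads."""
    df = pd.read_csv(path, sep="\t")
    need = {"sample_id", "total_reads", "duplicate_reads"}
    if not need.issubset(df.columns):
        raise ValueError(f"flag-count table {path} must have columns {sorted(need)}")
    return {
        str(r.sample_id): (int(r.total_reads), int(r.duplicate_reads))
        for r in df.itertuples(index=False)
    }
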