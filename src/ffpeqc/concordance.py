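"""Matched FF/FFPE pair concordance scoring.

A pair comparison treats the fresh-frozen (FF) call set as the reference.
Common positions are shared ``(chrom, pos, ref)`` keys between the two
filtered call sets of one variant class; at each common position the FFPE
call is concordant if it made the same call as FF, discordant otherwise.

Two readings of "the same call" are supported:

* ``allele``   — identical alt-allele sets;
* ``genotype`` — identical alt-allele sets AND identical unordered
  genotype (default; the stricter, safer reading).

The commonality fraction uses the union of the two call sets as its
denominator: 100 * NPos / (NFF + NFFPE - NPos).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from statistics import median
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .variant_io import VariantRecord, VariantSet

CONCORDANCE_MODES = ("allele", "genotype")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (table convention), not banker's."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PairComparison:
    """One row of the pair concordance table."""

    pair_id: str
    vclass: str
    n_ff: int
    n_ffpe: int
    n_pos: int
    n_co: int
    n_di: int
    p: float            # concordance rate percent, 2 dp
    common_frac: float  # percent of union that is shared

    def __post_init__(self) -> None:
        if self.n_co + self.n_di != self.n_pos:
            raise ValueError("n_co + n_di must equal n_pos")
        if not 0 <= self.n_pos <= min(self.n_ff, self.n_ffpe):
            raise ValueError("n_pos must be within [0, min(n_ff, n_ffpe)]")


def _single_vclass(vs: VariantSet) -> str:
    classes = {rec.vclass for rec in vs}
    if len(classes) > 1:
        raise ValueError(f"mixed variant classes in {vs.meta.sample_id}: {sorted(classes)}")
    return classes.pop() if classes else ""


def common_positions(
    ff: VariantSet, ffpe: VariantSet
) -> list[tuple[VariantRecord, VariantRecord]]:
    """Matched record pairs sharing (chrom, pos, ref); one pair per position."""
    c_ff, c_ffpe = _single_vclass(ff), _single_vclass(ffpe)
    if c_ff and c_ffpe and c_ff != c_ffpe:
        raise ValueError(f"variant class mismatch: {c_ff} vs {c_ffpe}")
    return [
        (rec, ffpe.records[key])
        for key, rec in ff.records.items()
        if key in ffpe.records
    ]


def is_concordant(
    ff_rec: VariantRecord, ffpe_rec: VariantRecord, mode: str = "genotype"
) -> bool:
    if mode not in CONCORDANCE_MODES:
        raise ValueError(f"mode must be one of {CONCORDANCE_MODES}, got {mode!r}")
    if set(ff_rec.alts) != set(ffpe_rec.alts):
        return False
    if mode == "genotype" and sorted(ff_rec.genotype) != sorted(ffpe_rec.genotype):
        return False
    return True


def classify_concordance(
    pairs: Sequence[tuple[VariantRecord, VariantRecord]], mode: str = "genotype"
) -> tuple[int, int]:
    """(n_co, n_di) over matched pairs; FF is the reference call."""
    n_co = sum(is_concordant(a, b, mode) for a, b in pairs)
    return n_co, len(pairs) - n_co


def concordance_rate(n_co: int, n_pos: int) -> float:
    """Percent concordant of common positions, rounded half-up to 2 dp."""
    if n_pos <= 0:
        raise ValueError("concordance rate undefined: no common positions")
    return round_half_up(100 * n_co / n_pos, 2)


def commonality_fraction(n_ff: int, n_ffpe: int, n_pos: int) -> float:
    """Shared positions as percent of the union of both call sets."""
    if n_pos > min(n_ff, n_ffpe):
        raise ValueError("n_pos exceeds a set size")
    union = n_ff + n_ffpe - n_pos
    if union == 0:
        raise ValueError("commonality undefined: both sets empty")
    return 100 * n_pos / union


def pair_summary(
    ff: VariantSet, ffpe: VariantSet, vclass: str,
    pair_id: str = "", mode: str = "genotype",
) -> PairComparison:
    """Full concordance row for one matched FF/FFPE pair of one class."""
    ff_c, ffpe_c = ff.subset(vclass), ffpe.subset(vclass)
    pairs = common_positions(ff_c, ffpe_c)
    n_co, n_di = classify_concordance(pairs, mode)
    n_pos = len(pairs)
    return PairComparison(
        pair_id=pair_id or f"{ff.meta.sample_id}|{ffpe.meta.sample_id}",
        vclass=vclass,
        n_ff=len(ff_c),
        n_ffpe=len(ffpe_c),
        n_pos=n_pos,
        n_co=n_co,
        n_di=n_di,
        p=concordance_rate(n_co, n_pos) if n_pos else float("nan"),
        common_frac=commonality_fraction(len(ff_c), len(ffpe_c), n_pos)
        if (len(ff_c) + len(ffpe_c)) else float("nan"),
    )


@dataclass(frozen=True)
class KitGroupSummary:
    kit: str
    vclass: str
    diffs: tuple[int, ...]             # |n_ff - n_ffpe| per pair
    median_diff: float                 # even-length: mean of middle two
    diff_pct_of_total: tuple[float, ...]  # each diff as percent of n_ff


def kit_difference_stats(
    pair_summaries: Sequence[PairComparison], kit_map: Mapping[str, str]
) -> list[KitGroupSummary]:
    """Per-extraction-kit |NFF - NFFPE| lists and medians."""
    by_kit: dict[tuple[str, str], list[PairComparison]] = {}
    for pc in pair_summaries:
        if pc.pair_id not in kit_map:
            raise ValueError(f"pair {pc.pair_id!r} has no kit assignment")
        by_kit.setdefault((kit_map[pc.pair_id], pc.vclass), []).append(pc)
    out = []
    for (kit, vclass), group in sorted(by_kit.items()):
        diffs = tuple(abs(pc.n_ff - pc.n_ffpe) for pc in group)
        pcts = tuple(100 * d / pc.n_ff for d, pc in zip(diffs, group))
        out.append(
            KitGroupSummary(
                kit=kit, vclass=vclass, diffs=diffs,
                median_diff=float(median(diffs)), diff_pct_of_total=pcts,
            )
        )
    return out


PAIR_TABLE_COLUMNS = ["pair_id", "vclass", "n_ff", "n_ffpe", "n_pos", "n_co", "n_di", "p", "common_frac"]


def pair_table(summaries: Iterable[PairComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [{c: getattr(pc, c) for c in PAIR_TABLE_COLUMNS} for pc in summaries],
        columns=PAIR_TABLE_COLUMNS,
    )


def kit_table(summaries: Iterable[KitGroupSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(kit=s.kit, vclass=s.vclass, n_pairs=len(s.diffs),
                 median_diff=s.median_diff,
                 mean_diff_pct=sum(s.diff_pct_of_total) / len(s.diff_pct_of_total))
            for s in summaries
        ]
    )
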