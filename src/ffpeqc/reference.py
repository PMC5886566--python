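"""Bundled reference count tables from a published 25-pair FF/FFPE
whole-exome comparison, and the arithmetic that recomputes its summary
indicators from those printed counts.

The tables carry, per matched pair and variant class, the FF and FFPE
call counts (NFF, NFFPE), the number of common positions (NPos) and the
concordant/discordant split (Nco, Ndi), plus the pair's extraction kit
(pairs 1-8 QIAamp, 9-18 GeneRead, 19-25 Maxwell).  A companion table holds
the tumor-specific SNV counts per tissue.  Everything derived — the
concordance rate P, the commonality fraction of the union, per-kit medians
of |NFF-NFFPE|, and the overlap percentages — is recomputed here with the
package's own operations; nothing derived is stored.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .concordance import (
    KitGroupSummary,
    PairComparison,
    commonality_fraction,
    concordance_rate,
    kit_difference_stats,
)
from .somatic import SomaticComparison, somatic_comparison_from_counts
from .variant_io import INDEL, SNV


def _load(name: str) -> pd.DataFrame:
    with resources.files("ffpeqc.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def pair_counts(vclass: str = SNV) -> pd.DataFrame:
    """Per-pair count table for one variant class (SNV or INDEL)."""
    if vclass not in (SNV, INDEL):
        raise ValueError(f"vclass must be SNV or INDEL, got {vclass!r}")
    return _load(f"pair_counts_{vclass.lower()}.tsv")


def somatic_counts() -> pd.DataFrame:
    return _load("somatic_counts.tsv")


def pair_comparisons(vclass: str = SNV) -> list[PairComparison]:
    """Rebuild full comparison rows (P, commonality) from the raw counts."""
    rows = []
    for r in pair_counts(vclass).itertuples(index=False):
        rows.append(
            PairComparison(
                pair_id=str(r.pair), vclass=vclass,
                n_ff=r.n_ff, n_ffpe=r.n_ffpe, n_pos=r.n_pos,
                n_co=r.n_co, n_di=r.n_di,
                p=concordance_rate(r.n_co, r.n_pos),
                common_frac=commonality_fraction(r.n_ff, r.n_ffpe, r.n_pos),
            )
        )
    return rows


def kit_medians(vclass: str = SNV) -> dict[str, KitGroupSummary]:
    """Per-kit |NFF-NFFPE| summaries recomputed from the count table."""
    df = pair_counts(vclass)
    kit_map = {str(r.pair): r.kit for r in df.itertuples(index=False)}
    return {s.kit: s for s in kit_difference_stats(pair_comparisons(vclass), kit_map)}


def somatic_comparisons() -> dict[str, SomaticComparison]:
    """Tissue -> overlap percentages recomputed from the somatic counts."""
    return {
        r.tissue: somatic_comparison_from_counts(
            r.n_ff_somatic, r.n_ffpe_somatic, r.n_overlap, tissue=r.tissue
        )
        for r in somatic_counts().itertuples(index=False)
    }
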