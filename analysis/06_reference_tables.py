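"""Recompute the published 25-pair summary indicators from bundled counts.

Everything here is arithmetic over the shipped per-pair count tables:
concordance rate P, commonality of the union, per-kit medians of the
FF-FFPE variant-count difference, and the tumor-specific overlap
percentages.  Writes results/reference_summary.json.
"""

import json
from pathlib import Path

from ffpeqc import reference
from ffpeqc.variant_io import INDEL, SNV

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    out = {}
    for vclass in (SNV, INDEL):
        rows = reference.pair_comparisons(vclass)
        counts = reference.pair_counts(vclass)
        out[vclass] = dict(
            min_concordance_pct=min(pc.p for pc in rows),
            min_commonality_pct=min(round(pc.common_frac) for pc in rows),
            mean_n_ff=counts.n_ff.mean(),
            mean_n_ffpe=counts.n_ffpe.mean(),
            kit_median_diff={k: s.median_diff
                             for k, s in reference.kit_medians(vclass).items()},
        )
    out["somatic"] = {
        tissue: dict(pct_of_ff=c.pct_of_ff, pct_of_ffpe=c.pct_of_ffpe,
                     n_overlap=c.n_overlap)
        for tissue, c in reference.somatic_comparisons().items()
    }
    (ROOT / "results").mkdir(exist_ok=True)
    path = ROOT / "results" / "reference_summary.json"
    path.write_text(json.dumps(out, indent=1))
    print(json.dumps(out, indent=1))
    print(f"written to {path}")


if __name__ == "__main__":
    main()
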