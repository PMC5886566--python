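"""Tumor-specific SNVs per condition and their FF/FFPE overlap.

The pipeline already subtracted matched normals; this driver checks the
overlap against the truth ledger and prints the comparison row.
"""

import json
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    somatic = pd.read_csv(ROOT / "results" / "somatic.tsv", sep="\t")
    truth = json.loads((ROOT / "scratch" / "bundle" / "truth.json").read_text())
    print(somatic.to_string(index=False))
    row = somatic.iloc[0]
    assert row.n_overlap == truth["n_overlap_true"], "overlap disagrees with ledger"
    print(f"overlap {row.n_overlap} == ledger truth {truth['n_overlap_true']}; "
          f"{row.pct_of_ff}% of FF and {row.pct_of_ffpe}% of FFPE somatic calls")


if __name__ == "__main__":
    main()
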