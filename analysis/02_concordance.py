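"""Quality-filter the simulated pair and score FF/FFPE concordance.

Runs the full report pipeline on scratch/bundle/, then checks the measured
discordant-call count against the generator's truth ledger.
"""

import json
from pathlib import Path

import pandas as pd

from ffpeqc.pipeline import RunConfig, run_pipeline

ROOT = Path(__file__).resolve().parents[1]
BUNDLE = ROOT / "scratch" / "bundle"
OUT = ROOT / "results"


def main() -> None:
    run_pipeline(RunConfig(input_dir=str(BUNDLE), out_dir=str(OUT)))
    conc = pd.read_csv(OUT / "concordance.tsv", sep="\t")
    truth = json.loads((BUNDLE / "truth.json").read_text())
    print(conc.to_string(index=False))
    measured_ndi = int(conc.n_di.sum())
    print(f"measured discordant calls: {measured_ndi} "
          f"(truth ledger: {truth['n_discordant']})")
    assert measured_ndi == truth["n_discordant"], "pipeline disagrees with ledger"
    print(f"SNV concordance P = {conc[conc.vclass == 'SNV'].p.iloc[0]}%, "
          f"commonality = {conc[conc.vclass == 'SNV'].common_frac.iloc[0]:.2f}%")


if __name__ == "__main__":
    main()
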