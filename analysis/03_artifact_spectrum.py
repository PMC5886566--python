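"""Substitution spectra: how much extra C.G>T.A load does FFPE carry?

Reads the spectra the pipeline wrote for every simulated sample and prints
the FFPE-minus-FF rate difference next to the injected artifact load.
"""

import json
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    spectra = pd.read_csv(ROOT / "results" / "artifact_spectrum.tsv", sep="\t")
    truth = json.loads((ROOT / "scratch" / "bundle" / "truth.json").read_text())
    pair = spectra.set_index("sample_id").loc[["FF_P1", "FFPE_P1"]]
    print(pair[["C>T", "G>A", "n_snv", "cgta_rate"]].to_string())
    delta = pair.loc["FFPE_P1", "cgta_rate"] - pair.loc["FF_P1", "cgta_rate"]
    injected = truth["n_artifacts"]
    print(f"FFPE - FF C.G>T.A rate difference: {delta:+.4f} "
          f"({injected} artifacts injected on "
          f"{truth['n_germline']} germline calls)")


if __name__ == "__main__":
    main()
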