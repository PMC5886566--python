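"""Generate the synthetic FF/FFPE input bundle the later analyses consume.

Writes a full input set (paired VCFs, tumor/normal VCFs, target BED, depth
tracks, read placements, flag counts, sample/pair sheets, truth ledger)
under scratch/bundle/ and a small manifest under results/.
"""

import json
from pathlib import Path

from ffpeqc.simulate import SimulationConfig, write_fixture_bundle

ROOT = Path(__file__).resolve().parents[1]
BUNDLE = ROOT / "scratch" / "bundle"

# one pair at roughly one-fifth of study scale keeps the whole analysis
# chain fast while preserving every statistical feature of the generator
CONFIG = SimulationConfig(n_germline=9_000, n_somatic=1_200, seed=11)


def main() -> None:
    manifest = write_fixture_bundle(CONFIG, BUNDLE)
    (ROOT / "results").mkdir(exist_ok=True)
    (ROOT / "results" / "simulation_manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))
    truth = json.loads((BUNDLE / "truth.json").read_text())
    print(f"bundle written to {BUNDLE}")
    print(f"  germline variants: {truth['n_germline']}, "
          f"FFPE dropouts: {truth['n_dropout']}, "
          f"artifacts: {truth['n_artifacts']}, "
          f"discordant: {truth['n_discordant']}")
    print(f"  somatic: {truth['n_somatic']} "
          f"(detected FF {truth['n_det_ff']}, FFPE {truth['n_det_ffpe']}, "
          f"true overlap {truth['n_overlap_true']})")


if __name__ == "__main__":
    main()
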