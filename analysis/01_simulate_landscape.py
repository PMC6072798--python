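#!/usr/bin/env python
"""Generate the synthetic study landscapes.

Writes two 300x300 two-date worlds observed through the forward model
(speckled L-band backscatter around the biomass regression):

  * ``default``   — observed-intensity change classes (gains ~1.3 MgC/ha/yr,
                    degradation removing 20-50%, deforestation to <10 MgC/ha)
  * ``separated`` — a validation world whose classes sit well clear of the
                    classification thresholds

Rasters go to scratch/ (large); the truth summaries to results/.
"""

from pathlib import Path

import pandas as pd

from woodychange import SyntheticScenario, write_fixture

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "landscapes"
RESULTS = ROOT / "results"

SCENARIOS = {
    "default": SyntheticScenario(shape=(300, 300), seed=42),
    "separated": SyntheticScenario.separated(shape=(300, 300), seed=42),
}


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for name, scenario in SCENARIOS.items():
        outdir = SCRATCH / name
        paths = write_fixture(scenario, outdir)
        truth = pd.read_csv(paths["truth_summary"])
        truth.insert(0, "landscape", name)
        rows.append(truth)
        wooded = truth.loc[truth["class"] != "nonwooded", "area_ha"].sum()
        print(f"[{name}] fixture -> {outdir}")
        print(f"  analysed area {truth['area_ha'].sum():.0f} ha, wooded {wooded:.0f} ha")
        for _, r in truth.iterrows():
            print(f"  {r['class']:12s} {r['area_ha']:8.1f} ha  dC {r['carbon_change_mgc']:+10.1f} MgC")
    pd.concat(rows).to_csv(RESULTS / "truth_summaries.csv", index=False)
    print(f"truth summaries -> {RESULTS / 'truth_summaries.csv'}")


if __name__ == "__main__":
    main()
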