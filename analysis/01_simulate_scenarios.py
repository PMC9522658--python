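"""Generate the six study scenarios' synthetic datasets.

Writes, per scenario, the raw line-scan profiles, the directly simulated
waveform matrix and the whole-tubule time series under
``results/simulated/<scenario>/``.  These files feed the later stages and
stand in for the intravital recordings.
"""

from pathlib import Path

from lysoscan.io import write_profiles_csv, write_series_csv, write_waveform_csv
from lysoscan.scenarios import DEFAULT_SCENARIOS, save_scenario
from lysoscan.simulate import (simulate_profiles, simulate_tubule_series,
                               simulate_waveform)

SEED = 0
OUT = Path(__file__).resolve().parent.parent / "results" / "simulated"


def main() -> None:
    for name, factory in DEFAULT_SCENARIOS.items():
        scen = factory(seed=SEED)
        outdir = OUT / name
        outdir.mkdir(parents=True, exist_ok=True)
        save_scenario(scen, outdir / "scenario.json")
        write_profiles_csv(simulate_profiles(scen), outdir / "profiles.csv")
        write_waveform_csv(simulate_waveform(scen), outdir / "waveform.csv")
        write_series_csv(simulate_tubule_series(scen),
                         outdir / "tubule_series.csv")
        print(f"{name}: profiles, waveform and tubule series -> {outdir}")


if __name__ == "__main__":
    main()
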