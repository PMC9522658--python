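"""Preprocess the simulated line-scan profiles into binned waveform matrices.

Reads the raw profiles written by 01_simulate_scenarios.py, rescales and
mean-bins them (100 bins on the normalized apical->basolateral axis), runs
the QC pass and writes each waveform with its JSON sidecar under
``results/waveforms/``.
"""

from pathlib import Path

from lysoscan.io import read_profiles, write_waveform_csv
from lysoscan.preprocess import qc_flags, waveform_from_profiles

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    outdir = ROOT / "waveforms"
    outdir.mkdir(parents=True, exist_ok=True)
    for scen_dir in sorted((ROOT / "simulated").iterdir()):
        profiles = read_profiles(scen_dir / "profiles.csv")
        wf, report = waveform_from_profiles(profiles, n_bins=100)
        flags = qc_flags(wf)
        write_waveform_csv(wf, outdir / f"{scen_dir.name}.csv",
                           sidecar={"qc_flags": [vars(f) for f in flags],
                                    **report})
        print(f"{scen_dir.name}: waveform {wf.shape[0]}x{wf.shape[1]}, "
              f"{len(flags)} QC flags")


if __name__ == "__main__":
    main()
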