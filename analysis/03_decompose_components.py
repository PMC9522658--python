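"""SVD-decompose the preprocessed waveforms and select the relevant rank.

For every scenario waveform: full SVD, rank selection (singular-value
amplitude share >= 1% and lag-1 autocorrelation of both singular vectors
>= 0.5), component tables (spatial shapes, singular-value-weighted kinetic
amplitudes, diagnostics) and the denoised reconstruction, all under
``results/components/<scenario>/``.  A summary line per scenario reports the
selected rank.
"""

import json
from pathlib import Path

from lysoscan.decompose import decompose, reconstruct, select_rank
from lysoscan.io import read_waveform_csv, write_components_csv, write_waveform_csv
from lysoscan.preprocess import WaveformMatrix

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    for wf_path in sorted((ROOT / "waveforms").glob("*.csv")):
        wf = read_waveform_csv(wf_path)
        result = decompose(wf)
        k = select_rank(result)
        outdir = ROOT / "components" / wf_path.stem
        write_components_csv(result, outdir)
        denoised = reconstruct(result, k).clip(min=0)
        write_waveform_csv(WaveformMatrix(wf.tubule_id, wf.position_bins,
                                          wf.times, denoised),
                           outdir / "denoised.csv")
        (outdir / "rank.json").write_text(json.dumps(
            {"selected_rank": k}, indent=2))
        top = result.diagnostics.head(4)
        shares = ", ".join(f"{s:.1%}" for s in top["amplitude_share"])
        print(f"{wf_path.stem}: rank {k} (leading amplitude shares: {shares})")


if __name__ == "__main__":
    main()
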