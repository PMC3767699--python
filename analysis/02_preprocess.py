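#!/usr/bin/env python
"""Characterize the preprocessing stages.

Reports the band-pass filter's frequency response at the physiologically
relevant frequencies and demonstrates ICA denoising on one subject with a
planted rank-one global interference: the interference component is
identified by the out-of-band spectral criterion and removing it restores
the correlation with the ground-truth clean data. Writes
results/analysis/filter_response.tsv and ica_demo_components.tsv.
"""

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from netrel.preprocessing import FilterSpec, bandpass_filter, denoise
from netrel.synthetic import (ArtifactSpec, GeneratorConfig,
                              GlobalInterference, generate_dataset,
                              plant_artifacts)

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "analysis"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    fs, spec = 25.0, FilterSpec()

    # --- filter response -----------------------------------------------------
    t = np.arange(int(600 * fs)) / fs
    core = slice(len(t) // 4, 3 * len(t) // 4)
    rows = []
    for label, freq in [("in-band low", 0.02), ("mid-band", 0.04),
                        ("in-band high", 0.07), ("Mayer", 0.1),
                        ("respiratory", 0.3), ("cardiac", 1.0)]:
        y = bandpass_filter(np.sin(2 * np.pi * freq * t), spec, fs)
        gain = (y[core].max() - y[core].min()) / 2.0
        rows.append((label, freq, round(float(gain), 6)))
    resp = pd.DataFrame(rows, columns=["label", "freq_hz", "gain"])
    resp.to_csv(OUT / "filter_response.tsv", sep="\t", index=False)
    print("band-pass gains (0.009-0.08 Hz, 4th-order Butterworth, "
          "forward-backward):")
    print(resp.to_string(index=False))

    # --- ICA denoising demo ---------------------------------------------------
    cfg = GeneratorConfig(n_subjects=1, n_channels=20, duration=300.0, seed=3)
    hbo, _, _ = generate_dataset(cfg)
    artifact = ArtifactSpec(
        global_interference=(GlobalInterference(0, 0, 0.5, 3.0),))
    noisy = plant_artifacts(hbo, artifact, seed=7)
    clean, x = hbo.data[0, 0], noisy.data[0, 0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        denoised, decomp = denoise(x, cfg.fs, seed=11)
    flags = decomp.component_flags
    comp = pd.DataFrame({
        "component": np.arange(decomp.n_components),
        "dominant_freq_hz": np.round(flags.dominant_freq, 4),
        "participation_ratio": np.round(flags.participation_ratio, 2),
        "temporal_flag": flags.temporal,
        "spectral_flag": flags.spectral,
        "spatial_flag": flags.spatial,
        "noise": flags.noise,
    })
    comp.to_csv(OUT / "ica_demo_components.tsv", sep="\t", index=False)

    def mean_corr(a, b):
        return float(np.mean([np.corrcoef(a[c], b[c])[0, 1]
                              for c in range(a.shape[0])]))

    before, after = mean_corr(x, clean), mean_corr(denoised, clean)
    print(f"\nICA demo: planted 0.5 Hz rank-one global interference; "
          f"{int(flags.noise.sum())} of {decomp.n_components} components "
          "flagged as noise")
    print(f"mean channel correlation with clean data: {before:.3f} before, "
          f"{after:.3f} after denoising")
    print(f"wrote {OUT / 'filter_response.tsv'} and "
          f"{OUT / 'ica_demo_components.tsv'}")


if __name__ == "__main__":
    main()
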