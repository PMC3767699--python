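#!/usr/bin/env python
"""Run the full reliability pipeline (band-pass arm, and optionally the
ICA arm).

Uses a scaled-down but faithful analysis configuration — sparsity grid
0.05 to 0.95 in steps of 0.05, 10 degree-preserving nulls with 10 swaps
per edge — so the whole sweep over 18 subjects x 2 sessions x 3 signals
runs in minutes. Outputs land under results/analysis/bandpass/ (and
results/analysis/ica/ with --with-ica): edge ICCs, metric curves, ICC
profiles, AUC ICCs, session tests and the nodal repeated-measures ANOVA.
"""

import argparse
import dataclasses
from pathlib import Path

import numpy as np

from netrel.graphmetrics import NullModelConfig
from netrel.networks import SparsityGrid
from netrel.pipeline import IcaSettings, RunConfig, run_pipeline

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "analysis"

ANALYSIS_GRID = SparsityGrid(tuple(np.round(np.arange(0.05, 1.0, 0.05), 2)))


def analysis_config(ica: bool, out_dir: Path, seed: int) -> RunConfig:
    cfg = RunConfig.from_json(ROOT / "configs" / "default.json")
    cfg.sparsity_grid = ANALYSIS_GRID
    cfg.null = NullModelConfig(n_null=10, swaps_per_edge=10, seed=seed)
    cfg.ica = dataclasses.replace(cfg.ica, enabled=ica)
    cfg.out_dir = str(out_dir)
    cfg.seed = seed
    return cfg


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--with-ica", action="store_true",
                        help="also run the ICA + band-pass arm (slower)")
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    report = run_pipeline(analysis_config(False, OUT / "bandpass", args.seed))
    print(f"band-pass arm done in {report.runtime_s:.0f}s: "
          f"{report.stage_counts['edges']} edges, "
          f"{report.stage_counts['metric_values']} metric values, "
          f"{len(report.warnings)} warnings")
    if args.with_ica:
        report = run_pipeline(analysis_config(True, OUT / "ica", args.seed))
        print(f"ICA arm done in {report.runtime_s:.0f}s "
              f"({len(report.warnings)} warnings)")


if __name__ == "__main__":
    main()
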