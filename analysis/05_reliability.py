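#!/usr/bin/env python
"""Summarize the test-retest reliability results.

Reads the pipeline outputs of 04_graph_metrics.py (band-pass arm; the ICA
arm too when present) and reports: the edge-wise ICC distribution and its
grade histogram per hemoglobin signal, the strength-reliability
correlation (against the group-mean matrices from 03_build_networks.py,
when available), the AUC-based ICCs of the ten global and three nodal
metrics, the between-session paired t-tests and the nodal metric x signal
repeated-measures ANOVA. Writes results/analysis/reliability_summary.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from netrel.networks import read_matrix_tsv
from netrel.reliability import GRADES, strength_reliability_correlation

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "analysis"


def summarize_arm(arm_dir: Path, arm: str) -> list[dict]:
    rows = []
    edge = pd.read_csv(arm_dir / "edge_icc.tsv", sep="\t")
    glob = pd.read_csv(arm_dir / "global_icc.tsv", sep="\t")
    nodal = pd.read_csv(arm_dir / "nodal_icc.tsv", sep="\t")

    print(f"\n=== {arm} arm ===")
    for sig, grp in edge.groupby("signal"):
        mean, sd = grp.icc.mean(), grp.icc.std(ddof=1)
        hist = {g: int((grp.grade == g).sum()) for g in GRADES}
        fair_up = sum(hist[g] for g in ("fair", "good", "excellent"))
        print(f"{sig}: edge ICC {mean:.2f} +- {sd:.2f}; "
              f"{fair_up}/{len(grp)} edges fair-or-better "
              f"({100 * fair_up / len(grp):.0f}%)")
        rows.append({"arm": arm, "signal": sig, "quantity": "edge_icc_mean",
                     "value": round(mean, 4)})
        rows.append({"arm": arm, "signal": sig, "quantity": "edge_icc_sd",
                     "value": round(sd, 4)})
        for g in GRADES:
            rows.append({"arm": arm, "signal": sig,
                         "quantity": f"edge_grade_{g}", "value": hist[g]})

        mean_r_path = OUT / f"group_mean_r_{sig}.tsv"
        if mean_r_path.exists():
            strength = read_matrix_tsv(mean_r_path).upper_values()
            r, p = strength_reliability_correlation(grp.icc.to_numpy(),
                                                    strength)
            print(f"    strength-reliability correlation r = {r:.2f} "
                  f"(p = {p:.2g})")
            rows.append({"arm": arm, "signal": sig,
                         "quantity": "strength_reliability_r",
                         "value": round(r, 4)})

    print("\nAUC-based global-metric ICCs:")
    print(glob.pivot_table(index="metric", columns="signal",
                           values="auc_icc").round(2).to_string())
    for _, row in glob.iterrows():
        rows.append({"arm": arm, "signal": row.signal,
                     "quantity": f"global_auc_icc_{row.metric}",
                     "value": (round(row.auc_icc, 4)
                               if np.isfinite(row.auc_icc) else np.nan)})

    nodal_means = nodal.groupby(["signal", "metric"]).auc_icc.mean()
    print("\nmean nodal AUC ICC by metric/signal:")
    print(nodal_means.unstack().round(2).to_string())
    for (sig, metric), val in nodal_means.items():
        rows.append({"arm": arm, "signal": sig,
                     "quantity": f"nodal_mean_auc_icc_{metric}",
                     "value": round(val, 4)})

    tests = pd.read_csv(arm_dir / "session_tests.tsv", sep="\t")
    n_sig = int((tests.p < 0.05).sum())
    print(f"\nbetween-session paired t-tests on global AUCs: {n_sig} of "
          f"{len(tests)} metric/signal cells differ at p < 0.05")

    anova_path = arm_dir / "anova_summary.tsv"
    if anova_path.exists():
        anova = pd.read_csv(anova_path, sep="\t")
        print("nodal metric x signal repeated-measures ANOVA:")
        print(anova.round(4).to_string(index=False))
    return rows


def main() -> None:
    frames = []
    for arm in ("bandpass", "ica"):
        arm_dir = OUT / arm
        if not (arm_dir / "edge_icc.tsv").exists():
            if arm == "bandpass":
                raise SystemExit("run analysis/04_graph_metrics.py first")
            continue
        frames.extend(summarize_arm(arm_dir, arm))
    summary = pd.DataFrame(frames)
    summary.to_csv(OUT / "reliability_summary.tsv", sep="\t", index=False)
    print(f"\nwrote {OUT / 'reliability_summary.tsv'}")


if __name__ == "__main__":
    main()
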