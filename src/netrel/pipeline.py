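"""End-to-end orchestration: generate/load -> preprocess -> networks ->
graph metrics -> reliability -> report.

A single :class:`RunConfig` (JSON-serializable) drives the whole analysis.
Two preprocessing arms are supported: band-pass filtering only, and ICA
denoising followed by band-pass filtering. All outputs are flat TSV tables
plus a JSON run report, so runs can be diffed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .graphmetrics import GLOBAL_METRICS, NullModelConfig, metric_curves
from .networks import SparsityGrid, correlation_matrix, sparsity_sweep
from .preprocessing import FilterSpec, bandpass_filter, denoise, discard_initial
from .reliability import (auc, edge_reliability, metric_reliability,
                          reliability_anova, session_difference_tests,
                          session_similarity)
from .synthetic import (ArtifactSpec, GeneratorConfig, NoiseSpec,
                        TimeSeriesDataset, generate_dataset, read_dataset)

__all__ = ["RunConfig", "RunReport", "IcaSettings", "validate_config",
           "run_pipeline", "default_config"]

SIGNALS = ("HbO", "HbR", "HbT")

logger = logging.getLogger("netrel")


@dataclass
class IcaSettings:
    enabled: bool = False
    variance_target: float = 0.99
    contrast: str = "skew"
    max_iter: int = 500
    tol: float = 1e-5
    spectral_band: tuple[float, float] = (0.01, 0.1)
    jump_z: float = 6.0
    spike_z: float = 5.0
    min_spike_count: int = 10
    dispersion_fraction: float = 0.7


@dataclass
class RunConfig:
    """Run configuration; ``from_json``/``to_json`` round-trips a flat JSON
    document with nested sections for the generator, filter, ICA and null
    model."""

    mode: str = "synthetic"                    # "synthetic" | "files"
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    data_dir: str | None = None
    signals: tuple[str, ...] = SIGNALS
    discard_seconds: float = 60.0
    ica: IcaSettings = field(default_factory=IcaSettings)
    filter: FilterSpec = field(default_factory=FilterSpec)
    sparsity_grid: SparsityGrid = field(default_factory=SparsityGrid)
    null: NullModelConfig = field(default_factory=NullModelConfig)
    absolute_ranking: bool = False
    out_dir: str = "results/run"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        doc = dict(doc)
        kwargs: dict = {}
        if "generator" in doc:
            gen = dict(doc.pop("generator"))
            if "noise_spec" in gen:
                gen["noise_spec"] = NoiseSpec(**gen["noise_spec"])
            kwargs["generator"] = GeneratorConfig(**gen)
        if "ica" in doc:
            ica = dict(doc.pop("ica"))
            if "spectral_band" in ica:
                ica["spectral_band"] = tuple(ica["spectral_band"])
            kwargs["ica"] = IcaSettings(**ica)
        if "filter" in doc:
            kwargs["filter"] = FilterSpec(**doc.pop("filter"))
        if "sparsity_grid" in doc:
            kwargs["sparsity_grid"] = SparsityGrid(tuple(doc.pop("sparsity_grid")))
        if "null" in doc:
            kwargs["null"] = NullModelConfig(**doc.pop("null"))
        if "signals" in doc:
            kwargs["signals"] = tuple(doc.pop("signals"))
        kwargs.update(doc)
        return cls(**kwargs)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        doc = dataclasses.asdict(self)
        doc["generator"].pop("connectivity_template", None)
        doc["generator"].pop("artifact_spec", None)
        doc["sparsity_grid"] = list(self.sparsity_grid.values)
        doc["signals"] = list(self.signals)
        doc["ica"]["spectral_band"] = list(self.ica.spectral_band)
        return doc


@dataclass
class RunReport:
    config: dict
    version: str
    stage_counts: dict
    warnings: list[dict]
    runtime_s: float

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def default_config() -> RunConfig:
    """Shipped default: the emulated study layout (18 x 2 x 46 at 25 Hz,
    11 min recorded, 0.009-0.08 Hz band, 99-point sparsity grid)."""
    return RunConfig()


def validate_config(config: RunConfig) -> list[str]:
    """Check every invariant; all violations are returned at once."""
    problems: list[str] = []
    if config.mode not in ("synthetic", "files"):
        problems.append(f"unknown mode {config.mode!r}")
    if config.mode == "files":
        if not config.data_dir:
            problems.append("files mode requires data_dir")
        elif not Path(config.data_dir).is_dir():
            problems.append(f"data_dir {config.data_dir!r} does not exist")
    if not config.signals:
        problems.append("signals list is empty")
    unknown = set(config.signals) - set(SIGNALS)
    if unknown:
        problems.append(f"unknown signals {sorted(unknown)}")
    problems.extend(config.generator.validate())
    fs = config.generator.fs
    try:
        config.filter.validate(fs)
    except ValueError as exc:
        problems.append(str(exc))
    if config.discard_seconds < 0:
        problems.append("discard_seconds must be >= 0")
    if config.discard_seconds >= config.generator.duration:
        problems.append("discard_seconds must be shorter than the recording")
    return problems


def _derived_seed(master: int, *key: int) -> int:
    ss = np.random.SeedSequence(master, spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1)[0] % (2**31))


def streamed_edge_correlations(generator: GeneratorConfig,
                               filter_spec: FilterSpec | None = None,
                               discard_seconds: float = 60.0,
                               signal: str = "HbO") -> np.ndarray:
    """Per-subject streaming generate -> discard -> band-pass -> Pearson.

    Returns the (n_subjects, n_sessions, n_channels, n_channels) stack of
    correlation matrices without ever materializing the full cohort's time
    series — the path used for large parameter-recovery studies.
    """
    from .synthetic import generate_subject

    filter_spec = filter_spec or FilterSpec()
    n_ch = generator.n_channels
    stack = np.empty((generator.n_subjects, generator.n_sessions, n_ch, n_ch))
    for i in range(generator.n_subjects):
        sessions = generate_subject(generator, i)[signal]
        for s in range(generator.n_sessions):
            x = sessions[s]
            if discard_seconds > 0:
                x = discard_initial(x, discard_seconds, generator.fs)
            x = bandpass_filter(x, filter_spec, generator.fs)
            stack[i, s] = correlation_matrix(x).values
    return stack


def _load_datasets(config: RunConfig) -> dict[str, TimeSeriesDataset]:
    if config.mode == "synthetic":
        hbo, hbr, hbt = generate_dataset(config.generator)
        all_ds = {"HbO": hbo, "HbR": hbr, "HbT": hbt}
    else:
        all_ds = {sig: read_dataset(config.data_dir, sig)
                  for sig in config.signals}
    return {sig: all_ds[sig] for sig in config.signals}


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages in order and write the output tables.

    Outputs under ``config.out_dir``: edge_icc.tsv, global_icc.tsv,
    nodal_icc.tsv, global_icc_profile.tsv, nodal_icc_profile.tsv,
    session_similarity.tsv, session_tests.tsv, anova_summary.tsv,
    anova_posthoc.tsv, metric_curves.tsv and run_report.json. Idempotent
    given the seed (the report's runtime field aside).
    """
    t0 = time.time()
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid RunConfig: " + "; ".join(problems))

    logging.basicConfig(stream=sys.stderr,
                        level=getattr(logging, config.log_level.upper(), 20),
                        format="[netrel %(levelname)s] %(message)s")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    collected_warnings: list[dict] = []
    counts: dict[str, int] = {}

    logger.info("stage=load mode=%s signals=%s", config.mode,
                ",".join(config.signals))
    datasets = _load_datasets(config)
    fs = next(iter(datasets.values())).fs
    n_sub = next(iter(datasets.values())).n_subjects
    n_ses = next(iter(datasets.values())).n_sessions
    counts["subjects"] = n_sub
    counts["sessions"] = n_ses

    # --- preprocessing -----------------------------------------------------
    logger.info("stage=preprocess discard=%.0fs ica=%s band=%.3f-%.3f Hz",
                config.discard_seconds, config.ica.enabled,
                config.filter.low_cut, config.filter.high_cut)
    processed: dict[str, np.ndarray] = {}
    for sig_i, (sig, ds) in enumerate(datasets.items()):
        data = ds.data
        if config.discard_seconds > 0:
            data = discard_initial(data, config.discard_seconds, fs)
        cleaned = np.empty_like(data)
        for i in range(n_sub):
            for s in range(n_ses):
                x = data[i, s]
                if config.ica.enabled:
                    seed = _derived_seed(config.seed, 1, sig_i, i, s)
                    with warnings.catch_warnings(record=True) as caught:
                        warnings.simplefilter("always")
                        x, decomp = denoise(
                            x, fs, seed=seed,
                            variance_target=config.ica.variance_target,
                            contrast=config.ica.contrast,
                            max_iter=config.ica.max_iter, tol=config.ica.tol,
                            spectral_band=config.ica.spectral_band,
                            jump_z=config.ica.jump_z,
                            spike_z=config.ica.spike_z,
                            min_spike_count=config.ica.min_spike_count,
                            dispersion_fraction=config.ica.dispersion_fraction)
                    for w in caught:
                        collected_warnings.append(
                            {"stage": "ica", "signal": sig, "subject": i,
                             "session": s, "message": str(w.message)})
                x = bandpass_filter(x, config.filter, fs)
                cleaned[i, s] = x
        processed[sig] = cleaned
    counts["samples_retained"] = processed[config.signals[0]].shape[-1]

    # --- network construction ---------------------------------------------
    logger.info("stage=networks grid=%d thresholds", len(config.sparsity_grid))
    r_stacks: dict[str, np.ndarray] = {}
    for sig in config.signals:
        n_ch = processed[sig].shape[2]
        stack = np.empty((n_sub, n_ses, n_ch, n_ch))
        for i in range(n_sub):
            for s in range(n_ses):
                stack[i, s] = correlation_matrix(processed[sig][i, s]).values
        r_stacks[sig] = stack
    counts["edges"] = r_stacks[config.signals[0]].shape[2] * \
        (r_stacks[config.signals[0]].shape[2] - 1) // 2

    # --- edge-wise reliability ---------------------------------------------
    logger.info("stage=edge_reliability")
    edge_frames = []
    similarity_frames = []
    for sig in config.signals:
        df, summary = edge_reliability(r_stacks[sig])
        df.insert(0, "signal", sig)
        edge_frames.append(df)
        counts[f"edge_clamped_{sig}"] = int(df.clamped.sum())
        if n_ses == 2:
            sim = session_similarity(r_stacks[sig])
            sim.insert(0, "signal", sig)
            similarity_frames.append(sim)
    edge_df = pd.concat(edge_frames, ignore_index=True)
    edge_df.to_csv(out / "edge_icc.tsv", sep="\t", index=False,
                   float_format="%.6g")
    if similarity_frames:
        pd.concat(similarity_frames, ignore_index=True).to_csv(
            out / "session_similarity.tsv", sep="\t", index=False,
            float_format="%.6g")

    # --- graph metrics across the sweep ------------------------------------
    logger.info("stage=metrics null=%s n_null=%d", config.null.method,
                config.null.n_null)
    from .networks import ConnectivityMatrix
    curve_frames = []
    for sig_i, sig in enumerate(config.signals):
        for i in range(n_sub):
            for s in range(n_ses):
                cm = ConnectivityMatrix(r_stacks[sig][i, s], subject=i,
                                        session=s, signal=sig)
                nets = sparsity_sweep(cm, config.sparsity_grid,
                                      absolute=config.absolute_ranking)
                null_cfg = dataclasses.replace(
                    config.null,
                    seed=_derived_seed(config.seed, 2, sig_i, i, s))
                curves = metric_curves(nets, null_config=null_cfg, cm=cm)
                curves.insert(0, "session", s + 1)
                curves.insert(0, "subject", i + 1)
                curves.insert(0, "signal", sig)
                curve_frames.append(curves)
    curves_df = pd.concat(curve_frames, ignore_index=True)
    curves_df.to_csv(out / "metric_curves.tsv", sep="\t", index=False,
                     float_format="%.6g")
    counts["metric_values"] = len(curves_df)
    counts["undefined_metric_values"] = int(curves_df.value.isna().sum())

    # --- metric reliability -------------------------------------------------
    logger.info("stage=metric_reliability")
    profiles, auc_iccs = [], []
    for sig in config.signals:
        sub = curves_df[curves_df.signal == sig]
        profile, auc_icc = metric_reliability(sub)
        for frame in (profile, auc_icc):
            frame.insert(0, "signal", sig)
        profiles.append(profile)
        auc_iccs.append(auc_icc)
    profile_df = pd.concat(profiles, ignore_index=True)
    auc_df = pd.concat(auc_iccs, ignore_index=True)

    is_global = auc_df.node == "global"
    auc_df[is_global].drop(columns="node").to_csv(
        out / "global_icc.tsv", sep="\t", index=False, float_format="%.6g")
    auc_df[~is_global].to_csv(out / "nodal_icc.tsv", sep="\t", index=False,
                              float_format="%.6g")
    prof_global = profile_df.node == "global"
    profile_df[prof_global].drop(columns="node").to_csv(
        out / "global_icc_profile.tsv", sep="\t", index=False,
        float_format="%.6g")
    profile_df[~prof_global].to_csv(out / "nodal_icc_profile.tsv", sep="\t",
                                    index=False, float_format="%.6g")
    counts["clamped_metric_iccs"] = int(auc_df.clamped.sum())

    # --- between-session tests on global AUCs -------------------------------
    if n_ses == 2:
        logger.info("stage=session_tests")
        grid = np.asarray(list(config.sparsity_grid), dtype=float)
        rows = []
        glob = curves_df[curves_df.node == "global"]
        for (sig, subj, sess, metric), grp in glob.groupby(
                ["signal", "subject", "session", "metric"], sort=True):
            vals = grp.sort_values("sparsity").value.to_numpy()
            try:
                rows.append((sig, subj, sess, metric, auc(vals, grid)))
            except ValueError:
                collected_warnings.append(
                    {"stage": "auc", "signal": sig, "subject": int(subj),
                     "session": int(sess), "metric": metric,
                     "message": "too few finite points for AUC"})
        auc_table = pd.DataFrame(rows, columns=["signal", "subject",
                                                "session", "metric", "value"])
        tests = session_difference_tests(auc_table)
        tests.to_csv(out / "session_tests.tsv", sep="\t", index=False,
                     float_format="%.6g")

    # --- repeated-measures ANOVA on nodal AUC-ICCs ---------------------------
    nodal = auc_df[~is_global].rename(columns={"auc_icc": "icc"})
    if (len(config.signals) >= 2 and nodal.metric.nunique() >= 2
            and not nodal.icc.isna().any()):
        logger.info("stage=anova")
        anova, posthoc = reliability_anova(
            nodal[["node", "metric", "signal", "icc"]])
        anova.to_csv(out / "anova_summary.tsv", sep="\t", index=False,
                     float_format="%.6g")
        posthoc.to_csv(out / "anova_posthoc.tsv", sep="\t", index=False,
                       float_format="%.6g")
    elif len(config.signals) >= 2:
        collected_warnings.append(
            {"stage": "anova", "message": "ANOVA skipped: incomplete design "
             "or undefined nodal ICCs"})

    report = RunReport(config=config.to_dict(), version=__version__,
                       stage_counts=counts, warnings=collected_warnings,
                       runtime_s=round(time.time() - t0, 3))
    report.to_json(out / "run_report.json")
    logger.info("stage=done runtime=%.1fs warnings=%d", report.runtime_s,
                len(collected_warnings))
    return report
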