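"""Synthetic two-session, multi-subject hemoglobin datasets.

Emulates a resting-state fNIRS study layout — N subjects scanned twice, C
measurement channels, oxy-/deoxy-/total-hemoglobin signals (HbO, HbR, HbT)
sampled at ``fs`` Hz — with a *known, planted* test–retest reliability
structure, so every downstream stage (filtering, ICA denoising, network
construction, graph metrics, ICC analysis) can be validated without any
recorded data.

Reliability planting
--------------------
Each subject owns a band-limited (0.009–0.08 Hz) latent multichannel
"neural" source, drawn once and reused in both sessions; an independent
session-specific source of the same construction is mixed in. Both sources
share one channel-correlation template, so the only thing that
distinguishes subjects and sessions is the finite-sample fluctuation of
each realization's empirical correlations. If the shared source carries a
fraction ``a`` of the variance, a delta-method argument (see
``docs/methods.md``) shows the population edge-wise ICC equals ``a**2``
independently of the template; the generator therefore uses
``a = sqrt(icc_target)``, which makes the ICC of downstream edge
correlations converge to ``icc_target``.

Confounds and artifacts
-----------------------
Physiological sinusoid-with-phase-jitter confounds (cardiac ~1 Hz,
respiratory ~0.3 Hz, Mayer waves ~0.1 Hz), white instrument noise, and —
via :func:`plant_artifacts` — step jumps, slow U-shaped bumps, fast spike
trains and a rank-one global interference are superimposed. HbR is
anti-correlated with HbO (scale -0.4 by default) and HbT = HbO + HbR holds
elementwise by construction.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

NEURAL_BAND = (0.009, 0.08)  # Hz, the band treated as spontaneous neural activity

__all__ = [
    "NoiseSpec",
    "StepArtifact",
    "USpikeArtifact",
    "SpikeTrainArtifact",
    "GlobalInterference",
    "ArtifactSpec",
    "GeneratorConfig",
    "TimeSeriesDataset",
    "default_template",
    "generate_subject",
    "generate_dataset",
    "plant_artifacts",
    "write_dataset",
    "read_dataset",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Amplitudes (in units of the unit-variance neural source) and centre
    frequencies of the physiological and instrument noise terms."""

    cardiac_hz: float = 1.0
    cardiac_amp: float = 0.4
    respiratory_hz: float = 0.3
    respiratory_amp: float = 0.3
    mayer_hz: float = 0.1
    mayer_amp: float = 0.2
    instrument_sigma: float = 0.3
    #: std of the per-sample random-walk phase jitter (radians)
    freq_jitter: float = 0.01

    def highest_frequency(self) -> float:
        return max(self.cardiac_hz, self.respiratory_hz, self.mayer_hz)


@dataclass(frozen=True)
class StepArtifact:
    """Sudden baseline jump on one channel from ``time_s`` onward."""

    subject: int
    session: int
    channel: int
    time_s: float
    amplitude: float


@dataclass(frozen=True)
class USpikeArtifact:
    """Slowly varied U / inverted-U bump (raised cosine) centred at ``time_s``."""

    subject: int
    session: int
    channel: int
    time_s: float
    width_s: float
    amplitude: float


@dataclass(frozen=True)
class SpikeTrainArtifact:
    """Numerous inter-current quick spikes on one channel."""

    subject: int
    session: int
    channel: int
    start_s: float
    duration_s: float
    rate_hz: float
    amplitude: float


@dataclass(frozen=True)
class GlobalInterference:
    """Rank-one, spatially global interference time course.

    The waveform is a *skewed* periodic signal, ``sin(th) - 0.3*cos(2*th)``
    with slow phase jitter: its dominant spectral peak sits at ``freq_hz``
    while its nonzero skewness keeps it identifiable by skew-contrast ICA
    (superficial hemodynamic interference is asymmetric in practice; a pure
    sinusoid would be a degenerate input for that contrast).
    """

    subject: int
    session: int
    freq_hz: float
    amplitude: float


@dataclass(frozen=True)
class ArtifactSpec:
    steps: tuple[StepArtifact, ...] = ()
    u_spikes: tuple[USpikeArtifact, ...] = ()
    spike_trains: tuple[SpikeTrainArtifact, ...] = ()
    global_interference: tuple[GlobalInterference, ...] = ()

    def is_empty(self) -> bool:
        return not (self.steps or self.u_spikes or self.spike_trains
                    or self.global_interference)


def default_template(n_channels: int) -> np.ndarray:
    """Default latent channel-correlation template.

    A dense positive baseline plus a distance-decay term,
    ``0.35 + 0.55 * 0.8**|i-j|`` off the diagonal. Positive semi-definite by
    construction (sum of an all-ones rank-one matrix, an AR(1)-type Markov
    correlation matrix and a diagonal ridge), unit diagonal, and spread-out
    edge strengths so strength–reliability analyses have variance to work
    with.
    """
    idx = np.arange(n_channels)
    decay = 0.8 ** np.abs(idx[:, None] - idx[None, :])
    template = 0.35 * np.ones((n_channels, n_channels)) + 0.55 * decay
    np.fill_diagonal(template, 1.0)
    return template


@dataclass
class GeneratorConfig:
    """Study-condition description for the synthetic generator.

    Defaults emulate the emulated study: 18 subjects x 2 sessions x 46
    channels at 25 Hz, 11 min recorded (the first minute is discarded
    downstream, leaving 15,000 samples).
    """

    n_subjects: int = 18
    n_sessions: int = 2
    n_channels: int = 46
    fs: float = 25.0
    duration: float = 660.0
    icc_target: float = 0.7
    connectivity_template: np.ndarray | None = None
    noise_spec: NoiseSpec = field(default_factory=NoiseSpec)
    artifact_spec: ArtifactSpec | None = None
    hbr_scale: float = -0.4
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))

    def template(self) -> np.ndarray:
        if self.connectivity_template is None:
            return default_template(self.n_channels)
        return np.asarray(self.connectivity_template, dtype=float)

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        problems: list[str] = []
        if self.n_channels < 2:
            problems.append("n_channels must be >= 2")
        if self.n_subjects < 1:
            problems.append("n_subjects must be >= 1")
        if self.n_sessions < 1:
            problems.append("n_sessions must be >= 1")
        if not 0.0 <= self.icc_target <= 1.0:
            problems.append("icc_target must lie in [0, 1]")
        if self.fs <= 2.0 * self.noise_spec.highest_frequency():
            problems.append("fs must exceed twice the highest noise frequency")
        if self.duration <= 0:
            problems.append("duration must be positive")
        tpl = self.template()
        if tpl.shape != (self.n_channels, self.n_channels):
            problems.append("connectivity_template shape must be n_channels x n_channels")
        else:
            if not np.allclose(tpl, tpl.T, atol=1e-10):
                problems.append("connectivity_template must be symmetric")
            if not np.allclose(np.diag(tpl), 1.0, atol=1e-10):
                problems.append("connectivity_template must have a unit diagonal")
        return problems

    def require_valid(self) -> None:
        problems = self.validate()
        if problems:
            raise ValueError("invalid GeneratorConfig: " + "; ".join(problems))


@dataclass
class TimeSeriesDataset:
    """Subjects x sessions x channels x samples hemoglobin signals."""

    data: np.ndarray
    signal: str
    fs: float
    channel_ids: list[str]

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_sessions(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]

    @property
    def n_samples(self) -> int:
        return self.data.shape[3]

    def copy(self) -> "TimeSeriesDataset":
        return TimeSeriesDataset(self.data.copy(), self.signal, self.fs,
                                 list(self.channel_ids))


def _subject_rng(seed: int, subject: int, stream: int = 0) -> np.random.Generator:
    """Deterministic per-subject substream, independent of n_subjects."""
    ss = np.random.SeedSequence(seed, spawn_key=(stream, subject))
    return np.random.default_rng(ss)


def _bandlimited_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                       fs: float, band: tuple[float, float] = NEURAL_BAND) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited (by FFT masking) to ``band``."""
    white = rng.standard_normal((n_channels, n_samples))
    spectrum = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    spectrum[:, ~mask] = 0.0
    out = np.fft.irfft(spectrum, n=n_samples, axis=1)
    sd = out.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def _physiological_confound(rng: np.random.Generator, n_channels: int,
                            n_samples: int, fs: float, freq: float, amp: float,
                            jitter: float) -> np.ndarray:
    """Global sinusoid with slow phase jitter, channel-specific loading/lag."""
    if amp == 0.0:
        return np.zeros((n_channels, n_samples))
    t = np.arange(n_samples) / fs
    phase = 2.0 * np.pi * freq * t + np.cumsum(rng.normal(0.0, jitter, n_samples))
    loading = amp * (0.5 + rng.uniform(0.0, 1.0, n_channels))
    lag = rng.uniform(0.0, 0.5, n_channels)
    return loading[:, None] * np.sin(phase[None, :] + lag[:, None])


def generate_subject(config: GeneratorConfig, subject: int) -> dict[str, np.ndarray]:
    """Generate one subject's sessions for all three signals.

    Returns a dict mapping signal name to an (n_sessions, n_channels,
    n_samples) array. Deterministic in (config.seed, subject) and
    independent of ``n_subjects``, so datasets can be streamed
    subject-by-subject without materializing the full cohort.
    """
    config.require_valid()
    n_c, n_t, fs = config.n_channels, config.n_samples, config.fs
    chol = np.linalg.cholesky(config.template())
    spec = config.noise_spec

    # variance share of the shared source; edge-wise ICC converges to share^2
    share = float(np.sqrt(config.icc_target))

    rng_shared = _subject_rng(config.seed, subject, stream=0)
    shared = chol @ _bandlimited_noise(rng_shared, n_c, n_t, fs)

    sessions_hbo = np.empty((config.n_sessions, n_c, n_t))
    sessions_hbr = np.empty_like(sessions_hbo)
    for s in range(config.n_sessions):
        rng = _subject_rng(config.seed, subject, stream=1 + s)
        session_src = chol @ _bandlimited_noise(rng, n_c, n_t, fs)
        neural = np.sqrt(share) * shared + np.sqrt(1.0 - share) * session_src

        def confounds(scale: float, rng=rng) -> np.ndarray:
            out = np.zeros((n_c, n_t))
            for f, a in ((spec.cardiac_hz, spec.cardiac_amp),
                         (spec.respiratory_hz, spec.respiratory_amp),
                         (spec.mayer_hz, spec.mayer_amp)):
                out += _physiological_confound(rng, n_c, n_t, fs, f,
                                               a * scale, spec.freq_jitter)
            out += rng.normal(0.0, spec.instrument_sigma * scale, (n_c, n_t))
            return out

        sessions_hbo[s] = neural + confounds(1.0)
        sessions_hbr[s] = config.hbr_scale * neural + confounds(abs(config.hbr_scale))

    return {"HbO": sessions_hbo, "HbR": sessions_hbr,
            "HbT": sessions_hbo + sessions_hbr}


def generate_dataset(config: GeneratorConfig) -> tuple[TimeSeriesDataset,
                                                       TimeSeriesDataset,
                                                       TimeSeriesDataset]:
    """Generate the full cohort; returns (HbO, HbR, HbT) datasets.

    HbT equals HbO + HbR elementwise. Fully reproducible from
    ``config.seed``. When ``config.artifact_spec`` is set the artifacts are
    planted into every signal (the clean arrays are not retained here; call
    :func:`plant_artifacts` explicitly to keep an oracle copy).
    """
    config.require_valid()
    shape = (config.n_subjects, config.n_sessions, config.n_channels,
             config.n_samples)
    arrays = {sig: np.empty(shape) for sig in ("HbO", "HbR", "HbT")}
    for i in range(config.n_subjects):
        per_subject = generate_subject(config, i)
        for sig in arrays:
            arrays[sig][i] = per_subject[sig]
    channel_ids = [f"CH{c + 1:02d}" for c in range(config.n_channels)]
    datasets = tuple(
        TimeSeriesDataset(arrays[sig], sig, config.fs, channel_ids)
        for sig in ("HbO", "HbR", "HbT")
    )
    if config.artifact_spec is not None and not config.artifact_spec.is_empty():
        datasets = tuple(plant_artifacts(ds, config.artifact_spec,
                                         seed=config.seed) for ds in datasets)
    return datasets  # type: ignore[return-value]


def _check_onset(time_s: float, duration_s: float, what: str) -> None:
    if not 0.0 <= time_s < duration_s:
        raise ValueError(f"{what} onset {time_s} s outside recording "
                         f"(0–{duration_s} s)")


def plant_artifacts(dataset: TimeSeriesDataset, artifact_spec: ArtifactSpec,
                    seed: int = 0) -> TimeSeriesDataset:
    """Return a copy of ``dataset`` with the specified artifacts added.

    The input is left untouched and serves as the ground-truth clean copy
    for oracle comparisons. Amplitudes are interpreted in the dataset's own
    units. Raises ``ValueError`` for onsets outside the recording or
    non-finite amplitudes.
    """
    out = dataset.copy()
    data = out.data
    fs = dataset.fs
    n_t = dataset.n_samples
    duration = n_t / fs
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(999,)))

    for a in (artifact_spec.steps + artifact_spec.u_spikes
              + artifact_spec.spike_trains + artifact_spec.global_interference):
        if not np.isfinite(a.amplitude):
            raise ValueError(f"non-finite artifact amplitude in {a}")

    for st in artifact_spec.steps:
        _check_onset(st.time_s, duration, "step")
        onset = int(round(st.time_s * fs))
        data[st.subject, st.session, st.channel, onset:] += st.amplitude

    for u in artifact_spec.u_spikes:
        _check_onset(u.time_s, duration, "U-spike")
        t = np.arange(n_t) / fs
        inside = np.abs(t - u.time_s) < u.width_s / 2.0
        bump = np.zeros(n_t)
        bump[inside] = 0.5 * (1.0 + np.cos(2.0 * np.pi * (t[inside] - u.time_s)
                                           / u.width_s))
        data[u.subject, u.session, u.channel] += u.amplitude * bump

    for tr in artifact_spec.spike_trains:
        _check_onset(tr.start_s, duration, "spike train")
        n_spikes = max(1, int(round(tr.rate_hz * tr.duration_s)))
        times = tr.start_s + rng.uniform(0.0, tr.duration_s, n_spikes)
        times = times[times < duration]
        width = max(1, int(round(0.08 * fs)))  # ~2 samples at 25 Hz
        for t0 in times:
            onset = int(round(t0 * fs))
            stop = min(n_t, onset + width)
            data[tr.subject, tr.session, tr.channel, onset:stop] += tr.amplitude

    for g in artifact_spec.global_interference:
        t = np.arange(n_t) / fs
        phase = (2.0 * np.pi * g.freq_hz * t
                 + np.cumsum(rng.normal(0.0, 0.005, n_t)))
        waveform = np.sin(phase) - 0.3 * np.cos(2.0 * phase)
        waveform -= waveform.mean()
        loading = rng.uniform(0.5, 1.5, dataset.n_channels)  # spatially global
        data[g.subject, g.session] += g.amplitude * np.outer(loading, waveform)

    return out


# ---------------------------------------------------------------------------
# dataset I/O: one TSV per subject/session/signal plus a JSON manifest
# ---------------------------------------------------------------------------

def _tsv_name(signal: str, subject: int, session: int) -> str:
    return f"sub-{subject + 1:02d}_ses-{session + 1}_{signal}.tsv"


def write_dataset(dataset: TimeSeriesDataset, outdir: str | Path,
                  extra_manifest: dict | None = None) -> Path:
    """Write one TSV per subject/session (rows = channels, columns = sample
    indices, first column = channel id) plus ``manifest_<signal>.json``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = "channel\t" + "\t".join(str(i) for i in range(dataset.n_samples))
    for i in range(dataset.n_subjects):
        for s in range(dataset.n_sessions):
            path = outdir / _tsv_name(dataset.signal, i, s)
            with open(path, "w", encoding="utf-8", newline="\n") as fh:
                fh.write(header + "\n")
                for c, cid in enumerate(dataset.channel_ids):
                    row = "\t".join(f"{v:.8g}" for v in dataset.data[i, s, c])
                    fh.write(f"{cid}\t{row}\n")
    manifest = {
        "signal": dataset.signal,
        "fs": dataset.fs,
        "n_subjects": dataset.n_subjects,
        "n_sessions": dataset.n_sessions,
        "channel_ids": dataset.channel_ids,
        "n_samples": dataset.n_samples,
    }
    if extra_manifest:
        manifest.update(extra_manifest)
    with open(outdir / f"manifest_{dataset.signal}.json", "w",
              encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return outdir


def read_dataset(indir: str | Path, signal: str) -> TimeSeriesDataset:
    """Read a dataset written by :func:`write_dataset`."""
    indir = Path(indir)
    with open(indir / f"manifest_{signal}.json", encoding="utf-8") as fh:
        manifest = json.load(fh)
    n_sub = manifest["n_subjects"]
    n_ses = manifest["n_sessions"]
    channel_ids = manifest["channel_ids"]
    n_t = manifest["n_samples"]
    data = np.empty((n_sub, n_ses, len(channel_ids), n_t))
    for i in range(n_sub):
        for s in range(n_ses):
            path = indir / _tsv_name(signal, i, s)
            raw = np.loadtxt(path, delimiter="\t", skiprows=1,
                             usecols=range(1, n_t + 1), ndmin=2)
            data[i, s] = raw
    return TimeSeriesDataset(data, signal, manifest["fs"], channel_ids)


def write_dataset_hdf5(datasets: dict[str, TimeSeriesDataset],
                       path: str | Path) -> Path:
    """Optional HDF5 container mirroring the TSV layout."""
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as fh:
        for sig, ds in datasets.items():
            grp = fh.create_group(sig)
            grp.create_dataset("data", data=ds.data)
            grp.attrs["fs"] = ds.fs
            grp.attrs["channel_ids"] = [c.encode() for c in ds.channel_ids]
    return path


def read_dataset_hdf5(path: str | Path, signal: str) -> TimeSeriesDataset:
    import h5py

    with h5py.File(path, "r") as fh:
        grp = fh[signal]
        data = grp["data"][()]
        fs = float(grp.attrs["fs"])
        channel_ids = [c.decode() if isinstance(c, bytes) else str(c)
                       for c in grp.attrs["channel_ids"]]
    return TimeSeriesDataset(data, signal, fs, channel_ids)


def config_manifest(config: GeneratorConfig) -> dict:
    """Ground-truth parameters for the manifest (template omitted)."""
    d = dataclasses.asdict(config)
    d.pop("connectivity_template", None)
    d.pop("artifact_spec", None)
    return d
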