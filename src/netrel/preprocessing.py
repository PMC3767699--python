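"""Hemoglobin time-series conversion and cleaning.

Covers the preprocessing arm of the pipeline: optional modified
Beer-Lambert-law (MBLL) conversion of dual-wavelength optical-density
changes to concentration changes, discarding of the unstable initial
segment, zero-phase band-pass filtering of the spontaneous-activity band,
and ICA-based artifact removal with three noise-component criteria
(temporal anomalies, out-of-band dominant frequency, spatially dispersive
mixing pattern).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "FilterSpec",
    "PCAResult",
    "ICADecomposition",
    "ComponentFlags",
    "mbll_convert",
    "discard_initial",
    "bandpass_filter",
    "pca_reduce",
    "ica_decompose",
    "classify_noise_components",
    "reconstruct_without",
    "denoise",
    "DEFAULT_EXTINCTION",
]

# Molar extinction coefficients (cm^-1 mM^-1) for HbO/HbR at 690 and 830 nm,
# from the standard compiled tabulations. Rows: wavelength; columns: HbO, HbR.
DEFAULT_EXTINCTION = np.array([
    [0.2764, 2.0520],   # 690 nm
    [0.9740, 0.6930],   # 830 nm
])


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass specification; defaults select the 0.009–0.08 Hz band of
    spontaneous hemodynamic fluctuations."""

    low_cut: float = 0.009
    high_cut: float = 0.08
    order: int = 4
    kind: str = "butter"

    def validate(self, fs: float) -> None:
        if not 0.0 < self.low_cut < self.high_cut:
            raise ValueError("require 0 < low_cut < high_cut")
        if self.high_cut >= fs / 2.0:
            raise ValueError(f"high_cut {self.high_cut} Hz >= Nyquist {fs / 2} Hz")
        if self.kind != "butter":
            raise ValueError(f"unsupported filter kind {self.kind!r}")


def mbll_convert(delta_od_690: np.ndarray, delta_od_830: np.ndarray,
                 source_detector_distance: float = 3.2,
                 dpf_690: float = 6.0, dpf_830: float = 6.0,
                 extinction_table: np.ndarray = DEFAULT_EXTINCTION,
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Invert the modified Beer-Lambert law for two wavelengths.

    ``delta_od = distance * dpf * (eps_HbO * dHbO + eps_HbR * dHbR)`` per
    wavelength; the 2x2 system is solved per channel/sample. Returns
    (dHbO, dHbR, dHbT) with dHbT = dHbO + dHbR. Distances in cm, extinction
    in cm^-1 mM^-1, concentrations in mM.
    """
    od690 = np.asarray(delta_od_690, dtype=float)
    od830 = np.asarray(delta_od_830, dtype=float)
    if od690.shape != od830.shape:
        raise ValueError("optical-density arrays must share a shape")
    if source_detector_distance <= 0:
        raise ValueError("source-detector distance must be positive")
    ext = np.asarray(extinction_table, dtype=float)
    system = ext * source_detector_distance * np.array([[dpf_690], [dpf_830]])
    det = np.linalg.det(system)
    if abs(det) < 1e-12:
        raise ValueError("singular extinction system; wavelengths degenerate")
    inv = np.linalg.inv(system)
    stacked = np.stack([od690, od830])               # (2, ...)
    conc = np.tensordot(inv, stacked, axes=([1], [0]))  # (2, ...)
    hbo, hbr = conc[0], conc[1]
    return hbo, hbr, hbo + hbr


def discard_initial(ts: np.ndarray, seconds: float, fs: float) -> np.ndarray:
    """Drop the first ``seconds`` of signal (last axis is time)."""
    ts = np.asarray(ts)
    start = int(round(seconds * fs))
    if start >= ts.shape[-1]:
        raise ValueError(f"discard of {seconds} s >= duration "
                         f"({ts.shape[-1] / fs} s)")
    return ts[..., start:]


def bandpass_filter(ts: np.ndarray, spec: FilterSpec, fs: float) -> np.ndarray:
    """Zero-phase (forward–backward) Butterworth band-pass along time.

    Second-order sections keep the filter numerically stable at the very low
    normalized cutoffs involved (0.009 Hz at fs = 25 Hz).
    """
    spec.validate(fs)
    sos = sps.butter(spec.order, [spec.low_cut, spec.high_cut],
                     btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(ts, dtype=float), axis=-1)


@dataclass
class PCAResult:
    n_components: int
    scores: np.ndarray        # components x samples
    loadings: np.ndarray      # channels x components
    eigenvalues: np.ndarray   # all eigenvalues, descending
    mean: np.ndarray          # per-channel mean
    variance_retained: float


def pca_reduce(data: np.ndarray, variance_target: float = 0.99) -> PCAResult:
    """Smallest-m principal subspace whose eigenvalue share *exceeds*
    ``variance_target``; always at least one component."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2:
        raise ValueError("need a channels x samples matrix with >= 2 channels")
    if not np.all(np.isfinite(data)):
        raise ValueError("data contains non-finite values")
    mean = data.mean(axis=1, keepdims=True)
    centered = data - mean
    cov = centered @ centered.T / data.shape[1]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.clip(evals[order], 0.0, None), evecs[:, order]
    total = evals.sum()
    if total <= 0:
        raise ValueError("all-zero data; PCA undefined")
    cum = np.cumsum(evals) / total
    m = int(np.searchsorted(cum, variance_target, side="right")) + 1
    m = min(m, len(evals))
    loadings = evecs[:, :m]
    scores = loadings.T @ centered
    return PCAResult(m, scores, loadings, evals, mean[:, 0], float(cum[m - 1]))


@dataclass
class ComponentFlags:
    """Per-component noise flags with per-criterion sub-flags."""

    temporal: np.ndarray       # criterion (i): jumps / spike trains
    spectral: np.ndarray       # criterion (ii): dominant frequency out of band
    spatial: np.ndarray        # criterion (iii): globally dispersive mixing
    dominant_freq: np.ndarray
    participation_ratio: np.ndarray

    @property
    def noise(self) -> np.ndarray:
        return self.temporal | self.spectral | self.spatial

    def __len__(self) -> int:
        return len(self.temporal)


@dataclass
class ICADecomposition:
    """Deflation-mode ICA of one channels x samples recording.

    ``mixing @ sources + mean[:, None]`` reconstructs the PCA-retained part
    of the data; the number of components equals the number of retained
    principal components.
    """

    sources: np.ndarray            # components x samples
    mixing: np.ndarray             # channels x components
    mean: np.ndarray               # per-channel mean
    pca_variance_retained: float
    converged: np.ndarray          # per-component convergence flags
    component_flags: ComponentFlags | None = None

    @property
    def n_components(self) -> int:
        return self.sources.shape[0]


def _deflation_fastica(z: np.ndarray, rng: np.random.Generator,
                       contrast: str, max_iter: int, tol: float,
                       ) -> tuple[np.ndarray, np.ndarray]:
    """FastICA deflation on whitened data ``z`` (components x samples).

    ``contrast='skew'`` uses g(u)=u^2 (sensitive to asymmetric sources, the
    dominant character of hemodynamic artifacts); 'cube' uses g(u)=u^3.
    Returns (W, converged) with W orthogonal (rows = unmixing vectors).
    Non-converged rows are kept as-is and flagged.
    """
    m = z.shape[0]
    w_all = np.zeros((m, m))
    converged = np.zeros(m, dtype=bool)
    for p in range(m):
        w = rng.standard_normal(m)
        w -= w_all[:p].T @ (w_all[:p] @ w)
        w /= np.linalg.norm(w)
        for _ in range(max_iter):
            wx = w @ z
            if contrast == "skew":
                w_new = (z * wx**2).mean(axis=1)
            elif contrast == "cube":
                w_new = (z * wx**3).mean(axis=1) - 3.0 * w
            else:
                raise ValueError(f"unknown contrast {contrast!r}")
            w_new -= w_all[:p].T @ (w_all[:p] @ w_new)
            norm = np.linalg.norm(w_new)
            if norm < 1e-12:       # contrast degenerate in this direction
                break
            w_new /= norm
            if abs(abs(w_new @ w) - 1.0) < tol:
                w = w_new
                converged[p] = True
                break
            w = w_new
        w_all[p] = w
    return w_all, converged


def ica_decompose(data: np.ndarray, n_components: int | None = None,
                  seed: int = 0, variance_target: float = 0.99,
                  contrast: str = "skew", max_iter: int = 500,
                  tol: float = 1e-5) -> ICADecomposition:
    """PCA-whiten then deflation-mode ICA.

    If ``n_components`` is None it is set to the smallest PCA dimension
    retaining more than ``variance_target`` of the variance. Components that
    fail to converge within ``max_iter`` iterations are returned as-is with
    a warning (``converged`` records per-component status).
    """
    data = np.asarray(data, dtype=float)
    pca = pca_reduce(data, variance_target)
    if n_components is None:
        n_components = pca.n_components
    if n_components > data.shape[0]:
        raise ValueError("n_components exceeds channel count")
    n_components = min(n_components, int(np.sum(pca.eigenvalues > 1e-12)))
    mean = pca.mean
    centered = data - mean[:, None]
    cov = centered @ centered.T / data.shape[1]
    full_evals, full_evecs = np.linalg.eigh(cov)
    order = np.argsort(full_evals)[::-1][:n_components]
    evals = np.clip(full_evals[order], 1e-30, None)
    evecs = full_evecs[:, order]
    z = (evecs / np.sqrt(evals)).T @ centered   # whitened, comps x samples
    rng = np.random.default_rng(seed)
    w, converged = _deflation_fastica(z, rng, contrast, max_iter, tol)
    if not converged.all():
        warnings.warn(f"FastICA: {int((~converged).sum())} of {n_components} "
                      "components did not converge; partial result returned",
                      RuntimeWarning, stacklevel=2)
    sources = w @ z
    mixing = (evecs * np.sqrt(evals)) @ w.T     # channels x components
    retained = float(evals.sum() / np.clip(full_evals.sum(), 1e-30, None))
    return ICADecomposition(sources, mixing, mean, retained, converged)


def _dominant_frequency(source: np.ndarray, fs: float) -> float:
    nperseg = min(len(source), 4096)
    freqs, power = sps.welch(source, fs=fs, nperseg=nperseg,
                             noverlap=nperseg // 2)
    power = power.copy()
    power[freqs == 0.0] = 0.0   # ignore residual DC
    return float(freqs[np.argmax(power)])


def _robust_z(x: np.ndarray) -> np.ndarray:
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    scale = 1.4826 * mad if mad > 0 else (x.std() or 1.0)
    return (x - med) / scale


def classify_noise_components(decomp: ICADecomposition, fs: float,
                              spectral_band: tuple[float, float] = (0.01, 0.1),
                              jump_z: float = 6.0, spike_z: float = 5.0,
                              min_spike_count: int = 10,
                              dispersion_fraction: float = 0.7,
                              ) -> ComponentFlags:
    """Flag noise components by any of three criteria.

    (i) temporal anomaly — the maximum robust z-score of the first
    differences exceeds ``jump_z`` (sudden jumps, fast or slow spikes), or
    at least ``min_spike_count`` samples exceed ``spike_z`` robust SD;
    (ii) the dominant Welch-spectrum frequency lies outside
    ``spectral_band``; (iii) the mixing column is globally dispersive —
    its participation ratio exceeds ``dispersion_fraction`` of the channel
    count. An empty decomposition yields empty flags.
    """
    m = decomp.n_components
    temporal = np.zeros(m, dtype=bool)
    spectral = np.zeros(m, dtype=bool)
    spatial = np.zeros(m, dtype=bool)
    dominant = np.zeros(m)
    pr = np.zeros(m)
    n_channels = decomp.mixing.shape[0]
    for j in range(m):
        src = decomp.sources[j]
        if src.std() == 0:
            continue
        dz = _robust_z(np.diff(src))
        spikes = int(np.sum(np.abs(_robust_z(src)) > spike_z))
        temporal[j] = bool(np.max(np.abs(dz)) > jump_z
                           or spikes >= min_spike_count)
        dominant[j] = _dominant_frequency(src, fs)
        spectral[j] = not (spectral_band[0] <= dominant[j] <= spectral_band[1])
        col = decomp.mixing[:, j]
        denom = np.sum(col**4)
        pr[j] = (np.sum(col**2) ** 2 / denom) if denom > 0 else 0.0
        spatial[j] = bool(pr[j] > dispersion_fraction * n_channels)
    return ComponentFlags(temporal, spectral, spatial, dominant, pr)


def reconstruct_without(decomp: ICADecomposition,
                        flags: np.ndarray | ComponentFlags) -> np.ndarray:
    """Rebuild channel data with flagged mixing columns zeroed.

    With no flags this reproduces the PCA-retained data (plus the channel
    means). Flagging every component returns the channel means with a
    warning.
    """
    noise = flags.noise if isinstance(flags, ComponentFlags) else np.asarray(flags, bool)
    if len(noise) != decomp.n_components:
        raise ValueError("flag vector length must equal component count")
    if noise.all():
        warnings.warn("all components flagged as noise; returning channel means",
                      RuntimeWarning, stacklevel=2)
    mixing = decomp.mixing.copy()
    mixing[:, noise] = 0.0
    return mixing @ decomp.sources + decomp.mean[:, None]


def denoise(data: np.ndarray, fs: float, seed: int = 0,
            variance_target: float = 0.99, contrast: str = "skew",
            max_iter: int = 500, tol: float = 1e-5,
            spectral_band: tuple[float, float] = (0.01, 0.1),
            jump_z: float = 6.0, spike_z: float = 5.0,
            min_spike_count: int = 10, dispersion_fraction: float = 0.7,
            ) -> tuple[np.ndarray, ICADecomposition]:
    """PCA -> ICA -> classify -> reconstruct convenience wrapper.

    Returns the denoised channels x samples array (same shape as the input)
    and the decomposition with ``component_flags`` populated.
    """
    decomp = ica_decompose(data, seed=seed, variance_target=variance_target,
                           contrast=contrast, max_iter=max_iter, tol=tol)
    flags = classify_noise_components(
        decomp, fs, spectral_band=spectral_band, jump_z=jump_z,
        spike_z=spike_z, min_spike_count=min_spike_count,
        dispersion_fraction=dispersion_fraction)
    decomp.component_flags = flags
    if flags.noise.all():
        # keep the least-suspicious component rather than erasing the data
        keep = int(np.argmin(flags.temporal.astype(int)
                             + flags.spectral.astype(int)
                             + flags.spatial.astype(int)))
        noise = flags.noise.copy()
        noise[keep] = False
        cleaned = reconstruct_without(decomp, noise)
    else:
        cleaned = reconstruct_without(decomp, flags)
    return cleaned, decomp
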