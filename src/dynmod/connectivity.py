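"""Windowed wavelet-coherence networks from region×time panels.

The connectivity stage turns a z-scored region×time BOLD panel into an
ordered stack of symmetric coherence matrices (one per sliding window):

1. each region's series is decomposed with the maximal-overlap discrete
   wavelet transform (MODWT, Haar family); scale ``j`` isolates the band
   ``[1/(2^{j+1} tr), 1/(2^j tr)]`` Hz — scale 1 at tr = 2 s is
   0.125–0.25 Hz;
2. the coefficient series are divided into half-overlapping windows
   (default 32 volumes = 64 s, step 16);
3. within each window, magnitude-squared coherence is estimated for every
   region pair by Welch's averaged-periodogram method and averaged over
   the in-band frequencies;
4. coherences below the 95th percentile of a shuffled-window null are set
   to zero, yielding sparse multislice networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal as sp_signal

__all__ = [
    "TimeSeriesPanel",
    "WindowSpec",
    "MultilayerNetwork",
    "modwt_band_coefficients",
    "scale_passband",
    "window_slices",
    "band_coherence",
    "coherence_null_threshold",
    "build_multilayer",
    "node_strength",
    "enforce_uniform_sparsity",
]

#: Welch settings inside a 32-sample window: 16-sample hann segments,
#: 50% overlap — standard averaged-periodogram practice at this length.
WELCH_NPERSEG = 16
WELCH_OVERLAP = 0.5


@dataclass
class TimeSeriesPanel:
    """Per-subject region×time signal matrix with sampling interval.

    ``data`` is re-normalized on construction so every row has mean 0 and
    unit standard deviation (population convention, ddof=0).
    """

    data: np.ndarray
    tr: float
    subject: str = ""
    region_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("panel data must be a 2-D region×time matrix")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("panel contains missing or non-finite values")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        sd = self.data.std(axis=1, keepdims=True)
        if np.any(sd == 0):
            bad = np.flatnonzero(sd.ravel() == 0)
            raise ValueError(f"constant region series (zero variance): rows {bad.tolist()}")
        self.data = (self.data - self.data.mean(axis=1, keepdims=True)) / sd
        if not self.region_ids:
            self.region_ids = [f"r{i:03d}" for i in range(self.data.shape[0])]
        if len(self.region_ids) != self.data.shape[0]:
            raise ValueError("region_ids length mismatch")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry in volumes (default 32-volume, 50% overlap)."""

    length: int = 32
    step: int = 16

    def __post_init__(self) -> None:
        if not (0 < self.step <= self.length):
            raise ValueError("require 0 < step <= length")

    def seconds(self, tr: float) -> float:
        return self.length * tr


@dataclass
class MultilayerNetwork:
    """Ordered stack of symmetric nonnegative N×N coherence matrices."""

    layers: np.ndarray  # L×N×N
    window: WindowSpec
    band: tuple[float, float]
    threshold: float = 0.0
    subject: str = ""

    def __post_init__(self) -> None:
        self.layers = np.asarray(self.layers, dtype=float)
        if self.layers.ndim != 3 or self.layers.shape[1] != self.layers.shape[2]:
            raise ValueError("layers must be an L×N×N stack")
        if not np.allclose(self.layers, self.layers.transpose(0, 2, 1)):
            raise ValueError("layers must be symmetric")
        if self.layers.min() < 0 or self.layers.max() > 1 + 1e-12:
            raise ValueError("coherence entries must lie in [0, 1]")
        for l in range(self.layers.shape[0]):
            np.fill_diagonal(self.layers[l], 0.0)

    @property
    def n_layers(self) -> int:
        return self.layers.shape[0]

    @property
    def n_regions(self) -> int:
        return self.layers.shape[1]

    @property
    def sparsity(self) -> float:
        """Fraction of zero off-diagonal (upper-triangle) entries."""
        n = self.n_regions
        iu = np.triu_indices(n, k=1)
        vals = self.layers[:, iu[0], iu[1]]
        return float(np.mean(vals == 0))


def scale_passband(scale: int, tr: float) -> tuple[float, float]:
    """Nominal frequency band of MODWT detail ``scale``: [1/2^{j+1}, 1/2^j] / tr Hz."""
    if scale < 1:
        raise ValueError("scale must be >= 1")
    return (1.0 / (2 ** (scale + 1) * tr), 1.0 / (2**scale * tr))


def _modwt_filters(wavelet: str) -> tuple[np.ndarray, np.ndarray]:
    wav = pywt.Wavelet(wavelet)
    g = np.asarray(wav.dec_lo, dtype=float) / np.sqrt(2.0)
    h = np.asarray(wav.dec_hi, dtype=float) / np.sqrt(2.0)
    return g, h


def _circular_filter(v: np.ndarray, filt: np.ndarray, stride: int) -> np.ndarray:
    """out[t] = sum_l filt[l] * v[(t - stride*l) mod T], vectorized over leading axes."""
    out = np.zeros_like(v)
    for l, c in enumerate(filt):
        out += c * np.roll(v, stride * l, axis=-1)
    return out


def modwt_band_coefficients(series: np.ndarray, scale: int, wavelet: str = "haar") -> np.ndarray:
    """Undecimated (maximal-overlap) wavelet detail coefficients at ``scale``.

    Uses the MODWT pyramid with periodic boundary handling; the returned
    coefficient series has the same length as the input. Accepts a 1-D
    series or a 2-D region×time matrix (transformed row-wise). The
    transform is energy-preserving: summed detail energies across scales
    plus the final smooth equal the input energy.
    """
    x = np.asarray(series, dtype=float)
    if scale < 1:
        raise ValueError("scale must be >= 1")
    g, h = _modwt_filters(wavelet)
    support = (len(h) - 1) * (2**scale - 1) + 1
    if x.shape[-1] < max(2**scale, support):
        raise ValueError(
            f"series of length {x.shape[-1]} shorter than scale-{scale} filter support"
        )
    v = x
    for j in range(1, scale + 1):
        stride = 2 ** (j - 1)
        w = _circular_filter(v, h, stride)
        v = _circular_filter(v, g, stride)
    return w


def modwt_decompose(series: np.ndarray, level: int, wavelet: str = "haar"):
    """Full MODWT: detail coefficients for scales 1..level plus final smooth."""
    x = np.asarray(series, dtype=float)
    g, h = _modwt_filters(wavelet)
    details = []
    v = x
    for j in range(1, level + 1):
        stride = 2 ** (j - 1)
        details.append(_circular_filter(v, h, stride))
        v = _circular_filter(v, g, stride)
    return details, v


def window_slices(n_volumes: int, spec: WindowSpec) -> list[range]:
    """Half-open [start, start+length) windows fully inside the series."""
    if n_volumes < spec.length:
        raise ValueError(
            f"series of {n_volumes} volumes shorter than window length {spec.length}"
        )
    n_win = (n_volumes - spec.length) // spec.step + 1
    return [range(i * spec.step, i * spec.step + spec.length) for i in range(n_win)]


def _band_mask(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    mask = (freqs >= band[0] - 1e-12) & (freqs <= band[1] + 1e-12)
    if not mask.any():
        raise ValueError(f"no discrete frequencies inside band {band}")
    return mask


def band_coherence(
    x: np.ndarray,
    y: np.ndarray,
    band: tuple[float, float],
    tr: float,
    nperseg: int = WELCH_NPERSEG,
) -> float:
    """Welch magnitude-squared coherence of two windows, averaged over ``band``.

    Hann-tapered ``nperseg``-sample segments with 50% overlap; per-segment
    mean removal. Symmetric in (x, y) and bounded in [0, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D windows")
    if x.size < 8:
        raise ValueError("window too short for spectral estimation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate window: zero variance")
    noverlap = int(nperseg * WELCH_OVERLAP)
    freqs, cxy = sp_signal.coherence(
        x, y, fs=1.0 / tr, window="hann", nperseg=nperseg, noverlap=noverlap
    )
    return float(np.mean(cxy[_band_mask(freqs, band)]))


def _welch_csd_batch(windows: np.ndarray, tr: float, nperseg: int = WELCH_NPERSEG):
    """Segment FFTs for a batch of windows (…, T): returns freqs, X (…, S, F).

    Mirrors scipy's Welch conventions (hann taper, constant detrend per
    segment, 50% overlap) so pairwise coherences assembled from these
    FFTs match :func:`band_coherence` to floating-point accuracy.
    """
    w = np.asarray(windows, dtype=float)
    T = w.shape[-1]
    step = nperseg - int(nperseg * WELCH_OVERLAP)
    if T < nperseg:
        raise ValueError("window shorter than Welch segment length")
    starts = np.arange(0, T - nperseg + 1, step)
    taper = sp_signal.get_window("hann", nperseg)
    segs = np.stack([w[..., s : s + nperseg] for s in starts], axis=-2)
    segs = segs - segs.mean(axis=-1, keepdims=True)
    segs = segs * taper
    X = np.fft.rfft(segs, axis=-1)
    freqs = np.fft.rfftfreq(nperseg, d=tr)
    return freqs, X


def _coherence_matrix(
    coeff_window: np.ndarray, band: tuple[float, float], tr: float
) -> np.ndarray:
    """All-pairs band-averaged magnitude-squared coherence for one window.

    ``coeff_window`` is N×T (regions × in-window coefficient samples).
    """
    if np.any(np.ptp(coeff_window, axis=1) == 0):
        bad = np.flatnonzero(np.ptp(coeff_window, axis=1) == 0)
        raise ValueError(f"degenerate window: zero variance in regions {bad.tolist()}")
    freqs, X = _welch_csd_batch(coeff_window, tr)  # N×S×F
    mask = _band_mask(freqs, band)
    Xb = X[..., mask]  # N×S×Fb
    # cross-spectra averaged over segments: P[i,j,f] = mean_s X_i X_j*
    P = np.einsum("isf,jsf->ijf", Xb, np.conj(Xb)) / Xb.shape[1]
    auto = np.real(np.einsum("iif->if", P))
    msc = np.abs(P) ** 2 / (auto[:, None, :] * auto[None, :, :])
    C = msc.mean(axis=2)
    C = 0.5 * (C + C.T)
    np.fill_diagonal(C, 0.0)
    return np.clip(C, 0.0, 1.0)


def coherence_null_threshold(
    panel: TimeSeriesPanel,
    spec: WindowSpec = WindowSpec(),
    scale: int = 1,
    n_iter: int = 10_000,
    percentile: float = 95.0,
    seed: int | np.random.Generator = 0,
    wavelet: str = "haar",
) -> float:
    """Percentile of a shuffled-window coherence null.

    Each iteration picks two regions and two window start times at random,
    permutes the coefficient samples independently inside each window
    (destroying auto- and cross-correlation while preserving marginals),
    and computes the band coherence of the shuffled pair.
    """
    if n_iter < 100:
        raise ValueError("null too small: n_iter must be >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    coeffs = modwt_band_coefficients(panel.data, scale, wavelet)
    band = scale_passband(scale, panel.tr)
    T, w = panel.n_volumes, spec.length
    if T < w:
        raise ValueError("series too short for one window")
    n_reg = panel.n_regions
    regs = np.empty((n_iter, 2), dtype=int)
    for i in range(n_iter):
        regs[i] = rng.choice(n_reg, size=2, replace=False)
    starts = rng.integers(0, T - w + 1, size=(n_iter, 2))
    xw = np.empty((n_iter, w))
    yw = np.empty((n_iter, w))
    for i in range(n_iter):
        xw[i] = coeffs[regs[i, 0], starts[i, 0] : starts[i, 0] + w]
        yw[i] = coeffs[regs[i, 1], starts[i, 1] : starts[i, 1] + w]
    # independent within-window sample permutations
    xw = rng.permuted(xw, axis=1)
    yw = rng.permuted(yw, axis=1)
    freqs, Xf = _welch_csd_batch(xw, panel.tr)
    _, Yf = _welch_csd_batch(yw, panel.tr)
    mask = _band_mask(freqs, band)
    Xb, Yb = Xf[..., mask], Yf[..., mask]
    Pxy = np.mean(Xb * np.conj(Yb), axis=1)
    Pxx = np.mean(np.abs(Xb) ** 2, axis=1)
    Pyy = np.mean(np.abs(Yb) ** 2, axis=1)
    msc = np.abs(Pxy) ** 2 / (Pxx * Pyy)
    null = msc.mean(axis=1)
    return float(np.percentile(null, percentile))


def build_multilayer(
    panel: TimeSeriesPanel,
    spec: WindowSpec = WindowSpec(),
    scale: int = 1,
    threshold: float = 0.0,
    wavelet: str = "haar",
) -> MultilayerNetwork:
    """Thresholded multislice coherence network from a panel.

    Decomposes the full series once, windows the coefficient series, and
    computes all-pairs band coherence per window; entries strictly below
    ``threshold`` are zeroed.
    """
    coeffs = modwt_band_coefficients(panel.data, scale, wavelet)
    band = scale_passband(scale, panel.tr)
    slices = window_slices(panel.n_volumes, spec)
    layers = np.empty((len(slices), panel.n_regions, panel.n_regions))
    for l, sl in enumerate(slices):
        try:
            layers[l] = _coherence_matrix(coeffs[:, sl.start : sl.stop], band, panel.tr)
        except ValueError as exc:
            raise ValueError(f"window {l} (volumes {sl.start}-{sl.stop}): {exc}") from exc
    layers[layers < threshold] = 0.0
    return MultilayerNetwork(
        layers=layers, window=spec, band=band, threshold=threshold, subject=panel.subject
    )


def node_strength(net: MultilayerNetwork) -> tuple[np.ndarray, float]:
    """Per-region mean strength (sum of incident edge weights per layer,
    averaged over layers) and the subject scalar (mean over regions too)."""
    per_layer = net.layers.sum(axis=2)  # L×N
    per_region = per_layer.mean(axis=0)
    return per_region, float(per_region.mean())


def enforce_uniform_sparsity(net: MultilayerNetwork, density: float) -> MultilayerNetwork:
    """Keep the top ``ceil(density * N(N-1)/2)`` edges per layer, zero the rest.

    Ties broken by stable edge index order (earlier upper-triangle index
    wins). ``density=1`` is the identity.
    """
    if not (0 < density <= 1):
        raise ValueError("density must be in (0, 1]")
    n = net.n_regions
    iu = np.triu_indices(n, k=1)
    n_keep = int(np.ceil(density * n * (n - 1) / 2))
    new_layers = np.zeros_like(net.layers)
    for l in range(net.n_layers):
        w = net.layers[l][iu]
        order = np.argsort(-w, kind="stable")
        keep = order[:n_keep]
        mat = np.zeros((n, n))
        mat[iu[0][keep], iu[1][keep]] = w[keep]
        new_layers[l] = mat + mat.T
    return MultilayerNetwork(
        layers=new_layers,
        window=net.window,
        band=net.band,
        threshold=net.threshold,
        subject=net.subject,
    )
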