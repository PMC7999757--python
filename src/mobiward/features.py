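"""The 160-dimension feature bank for one arm+leg window pair.

Per site (arm, leg) and axis (x, y, z) a block of 26 features is computed
from the total and dynamic acceleration of one 256-sample window:

==========================  =====================================================
index in block              feature
==========================  =====================================================
0                           mean of total acceleration
1                           RMS of dynamic acceleration
2                           autocorrelation main peak (r(0), unnormalized)
3                           autocorrelation second-peak height (normalized)
4                           autocorrelation second-peak lag, s
5-10                        heights of the first six spectral peaks
11-16                       positions of the first six spectral peaks, Hz
17-21                       total power in five adjacent frequency bands
22                          median of total acceleration
23                          SD of dynamic acceleration
24                          MAD of total acceleration
25                          MAD of dynamic acceleration
==========================  =====================================================

plus, per site, the mean per-sample Euclidean magnitude of total and of
dynamic acceleration. That is 2 x 3 x 26 + 2 x 2 = 160 features. The layout
is frozen in :func:`feature_names` so that selection masks remain portable.

Spectral and autocorrelation features are computed on the dynamic signal:
on the total signal the gravity (DC) line would dominate every spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np
from scipy import signal as sps

from .types import CANONICAL_RATE_HZ, SITES, WINDOW_SAMPLES, ValidationError, WindowPair

AXES = ("x", "y", "z")

_AXIS_FEATURES = (
    ["total_mean", "dyn_rms", "ac_main_peak", "ac_peak2_height", "ac_peak2_lag_s"]
    + [f"spec_peak{i}_height" for i in range(1, 7)]
    + [f"spec_peak{i}_hz" for i in range(1, 7)]
    + [f"band_power_{i}" for i in range(1, 6)]
    + ["total_median", "dyn_sd", "total_mad", "dyn_mad"]
)
_MAG_FEATURES = ["mag_total_mean", "mag_dyn_mean"]

N_AXIS_FEATURES = len(_AXIS_FEATURES)  # 26
N_FEATURES = 2 * 3 * N_AXIS_FEATURES + 2 * len(_MAG_FEATURES)  # 160


@dataclass
class SpectralSpec:
    """Configuration of the spectral features.

    ``band_edges_hz`` defines five adjacent bands covering 0.5-25 Hz by
    default; the periodogram is single-taper (Hamming by default). The top
    edge must stay below Nyquist.
    """

    band_edges_hz: Tuple[float, ...] = (0.5, 5.0, 10.0, 15.0, 20.0, 25.0)
    n_peaks: int = 6
    taper: str = "hamming"

    def validate(self, rate_hz: float) -> None:
        edges = np.asarray(self.band_edges_hz, dtype=float)
        if edges.ndim != 1 or len(edges) != 6 or np.any(np.diff(edges) <= 0):
            raise ValidationError("band_edges_hz must be 6 ascending values")
        if edges[-1] >= rate_hz / 2:
            raise ValidationError(f"top band edge {edges[-1]} Hz must be < Nyquist ({rate_hz / 2} Hz)")
        if self.taper not in ("rectangular", "hamming"):
            raise ValidationError(f"unknown taper {self.taper!r}")


def feature_names() -> List[str]:
    """The canonical 160 feature names, in extraction order."""
    names = []
    for site in SITES:
        for axis in AXES:
            names.extend(f"{site}_{axis}_{feat}" for feat in _AXIS_FEATURES)
    for site in SITES:
        names.extend(f"{site}_{feat}" for feat in _MAG_FEATURES)
    return names


FEATURE_NAMES = feature_names()
assert len(FEATURE_NAMES) == N_FEATURES


def site_mask(sites) -> np.ndarray:
    """Boolean mask over the 160 features keeping only the given site(s)."""
    if isinstance(sites, str):
        sites = (sites,)
    unknown = set(sites) - set(SITES)
    if unknown:
        raise ValidationError(f"unknown sensor site(s) {sorted(unknown)}")
    return np.array([any(n.startswith(f"{s}_") for s in sites) for n in FEATURE_NAMES])


def autocorr_second_peak(x: np.ndarray, rate_hz: float = CANONICAL_RATE_HZ) -> Tuple[float, float]:
    """Height and lag of the dominant non-zero-lag autocorrelation peak.

    The biased autocorrelation r(k) = (1/n) sum_t x_t x_{t+k} is normalized
    by r(0); the search starts at the first lag where the normalized
    autocorrelation is no longer positive (past the main lobe) and returns
    the highest local maximum found — for a cyclical movement this is the
    stride/cadence period. Returns ``(0.0, 0.0)`` when no such peak exists
    or the signal has no power.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    r = np.correlate(x, x, mode="full")[n - 1 :] / n
    if r[0] <= 0:
        return 0.0, 0.0
    rho = r / r[0]
    nonpos = np.flatnonzero(rho <= 0)
    if nonpos.size == 0:
        return 0.0, 0.0
    k0 = int(nonpos[0])
    seg = rho[k0:]
    if seg.size < 3:
        return 0.0, 0.0
    interior = np.flatnonzero((seg[1:-1] >= seg[:-2]) & (seg[1:-1] > seg[2:])) + 1
    if interior.size == 0:
        return 0.0, 0.0
    best = interior[np.argmax(seg[interior])]
    k = k0 + int(best)
    return float(rho[k]), k / rate_hz


def _periodogram(dynamic: np.ndarray, spec: SpectralSpec, rate_hz: float):
    window = "hamming" if spec.taper == "hamming" else "boxcar"
    f, p = sps.periodogram(dynamic, fs=rate_hz, window=window, detrend=False)
    return f, p


def _spectral_peaks(f: np.ndarray, p: np.ndarray, n_peaks: int) -> Tuple[np.ndarray, np.ndarray]:
    # local maxima of the magnitude spectrum, by decreasing height; padded
    # with (0, 0) when fewer exist
    idx, _ = sps.find_peaks(p)
    heights = np.zeros(n_peaks)
    positions = np.zeros(n_peaks)
    if idx.size:
        order = idx[np.argsort(p[idx])[::-1]][:n_peaks]
        heights[: order.size] = p[order]
        positions[: order.size] = f[order]
    return heights, positions


def _band_powers(f: np.ndarray, p: np.ndarray, edges) -> np.ndarray:
    df = f[1] - f[0]
    out = np.empty(len(edges) - 1)
    for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
        mask = (f >= lo) & (f < hi)
        out[i] = float(np.sum(p[mask]) * df)
    return out


def _mad(x: np.ndarray) -> float:
    """Median absolute deviation about the median, unscaled."""
    return float(np.median(np.abs(x - np.median(x))))


def axis_features(
    total: np.ndarray,
    dynamic: np.ndarray,
    spec: SpectralSpec,
    rate_hz: float = CANONICAL_RATE_HZ,
) -> np.ndarray:
    """The 26-value feature block for one axis of one site."""
    total = np.asarray(total, dtype=float)
    dynamic = np.asarray(dynamic, dtype=float)
    if total.shape != (WINDOW_SAMPLES,) or dynamic.shape != (WINDOW_SAMPLES,):
        raise ValidationError(f"axis signals must have length {WINDOW_SAMPLES}")
    if not (np.all(np.isfinite(total)) and np.all(np.isfinite(dynamic))):
        raise ValidationError("non-finite values in axis signals")
    spec.validate(rate_hz)

    n = dynamic.size
    r0 = float(np.dot(dynamic, dynamic) / n)
    peak2_h, peak2_lag = autocorr_second_peak(dynamic, rate_hz)
    f, p = _periodogram(dynamic, spec, rate_hz)
    heights, positions = _spectral_peaks(f, p, spec.n_peaks)
    bands = _band_powers(f, p, spec.band_edges_hz)

    return np.concatenate(
        [
            [
                float(np.mean(total)),
                float(np.sqrt(np.mean(dynamic ** 2))),
                r0,
                peak2_h,
                peak2_lag,
            ],
            heights,
            positions,
            bands,
            [
                float(np.median(total)),
                float(np.std(dynamic, ddof=0)),
                _mad(total),
                _mad(dynamic),
            ],
        ]
    )


def magnitude_features(total: np.ndarray, dynamic: np.ndarray) -> np.ndarray:
    """Mean per-sample Euclidean magnitude of total and dynamic acceleration."""
    total = np.asarray(total, dtype=float)
    dynamic = np.asarray(dynamic, dtype=float)
    if total.shape != (WINDOW_SAMPLES, 3) or dynamic.shape != (WINDOW_SAMPLES, 3):
        raise ValidationError(f"magnitude inputs must be ({WINDOW_SAMPLES}, 3)")
    return np.array(
        [
            float(np.mean(np.linalg.norm(total, axis=1))),
            float(np.mean(np.linalg.norm(dynamic, axis=1))),
        ]
    )


def extract(
    pair: WindowPair,
    spec: SpectralSpec | None = None,
    rate_hz: float = CANONICAL_RATE_HZ,
) -> np.ndarray:
    """The full ordered 160-value feature vector of one window pair."""
    spec = spec or SpectralSpec()
    if not pair.has_dynamic:
        raise ValidationError(
            "window pair lacks dynamic acceleration; run split_acceleration before segmenting"
        )
    blocks = []
    for total, dynamic in ((pair.arm_total, pair.arm_dynamic), (pair.leg_total, pair.leg_dynamic)):
        for j in range(3):
            blocks.append(axis_features(total[:, j], dynamic[:, j], spec, rate_hz))
    for total, dynamic in ((pair.arm_total, pair.arm_dynamic), (pair.leg_total, pair.leg_dynamic)):
        blocks.append(magnitude_features(total, dynamic))
    vec = np.concatenate(blocks)
    assert vec.shape == (N_FEATURES,)
    return vec


def extract_many(pairs, spec: SpectralSpec | None = None, rate_hz: float = CANONICAL_RATE_HZ) -> np.ndarray:
    """Feature matrix (n_windows x 160) for a sequence of window pairs."""
    spec = spec or SpectralSpec()
    if not pairs:
        return np.empty((0, N_FEATURES))
    return np.vstack([extract(p, spec, rate_hz) for p in pairs])
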