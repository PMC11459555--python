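"""Windowing and per-window feature extraction for surface-EMG templates.

A discrete gesture template (channels x time) is cut into overlapping or
non-overlapping windows; each window is summarised by one or more amplitude /
complexity features per channel, producing an ordered ``FeatureSequence``
(windows x (channels * features)) that downstream classifiers consume.

Feature definitions are the classic myoelectric-control time-domain set
(Hudgins' features, waveform length, mean power) plus the low-sampling-rate
set (L-scale, maximum fractal length, mean square root, Willison amplitude).
Column order is channels-major, features-minor and is fixed so that trained
models are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

__all__ = [
    "WindowingConfig",
    "FeatureSequence",
    "FEATURE_IDS",
    "FEATURE_SETS",
    "extract_windows",
    "compute_feature",
    "compute_feature_set",
]

#: individual feature identifiers, in canonical order
FEATURE_IDS = (
    "RMS", "MAV", "WL", "MNP", "WENG", "ZC", "SSC", "LS", "MFL", "MSR", "WAMP",
)

#: named feature sets: Hudgins' time domain and Low Sampling 4,
#: plus single-feature sets for each individual feature
FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "HTD": ("MAV", "ZC", "SSC", "WL"),
    "LS4": ("LS", "MFL", "MSR", "WAMP"),
    **{f: (f,) for f in FEATURE_IDS},
}

# features needing at least two samples (first differences)
_DIFF_FEATURES = frozenset({"WL", "SSC", "MFL", "WAMP"})


@dataclass(frozen=True)
class WindowingConfig:
    """Sliding-window parameters, in samples (200 Hz: 1 sample = 5 ms)."""

    window_length: int
    increment: int

    def __post_init__(self) -> None:
        if self.window_length < 1 or self.increment < 1:
            raise ValueError(
                f"window_length and increment must be >= 1, got "
                f"L={self.window_length}, I={self.increment}"
            )

    def n_windows(self, n_samples: int) -> int:
        """Number of full windows that fit in a template of ``n_samples``."""
        if n_samples < self.window_length:
            raise ValueError(
                f"template of {n_samples} samples shorter than window "
                f"({self.window_length} samples)"
            )
        return (n_samples - self.window_length) // self.increment + 1


@dataclass
class FeatureSequence:
    """Ordered windows x (channels * features) matrix with its provenance.

    ``values[w, c * n_features + f]`` is feature ``feature_ids[f]`` of channel
    ``c`` in window ``w`` (channels-major, features-minor).
    """

    values: np.ndarray
    windowing: WindowingConfig
    feature_ids: tuple[str, ...]
    source: object | None = field(default=None, repr=False)

    def __len__(self) -> int:  # number of windows
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def to_csv(self, path) -> None:
        import pandas as pd

        n_ch = self.values.shape[1] // self.n_features
        cols = [
            f"ch{c + 1}_{f}"
            for c in range(n_ch)
            for f in self.feature_ids
        ]
        pd.DataFrame(self.values, columns=cols).to_csv(path, index=False)


def extract_windows(samples: np.ndarray, cfg: WindowingConfig) -> np.ndarray:
    """Cut a channels x T template into (n_windows, channels, L) windows.

    Windows start at 0, I, 2I, ...; a window [s, s+L) is emitted iff
    s + L <= T, so the count is floor((T - L) / I) + 1.
    """
    samples = np.asarray(samples)
    if samples.ndim != 2:
        raise ValueError("expected a channels x time matrix")
    T = samples.shape[1]
    n = cfg.n_windows(T)  # raises if T < L
    starts = np.arange(n) * cfg.increment
    return np.stack(
        [samples[:, s : s + cfg.window_length] for s in starts], axis=0
    )


def _weng(x: np.ndarray) -> float:
    """Total squared-coefficient energy of a db4 wavelet decomposition.

    Uses a 4-level decomposition, reduced to the maximum feasible level for
    short windows; a window too short for even one level falls back to the
    raw signal energy (the 0-level decomposition).
    """
    wavelet = pywt.Wavelet("db4")
    level = min(4, pywt.dwt_max_level(len(x), wavelet.dec_len))
    if level < 1:
        return float(np.sum(np.square(x, dtype=float)))
    coeffs = pywt.wavedec(x.astype(float), wavelet, level=level)
    return float(sum(np.sum(c * c) for c in coeffs))


def _ls(x: np.ndarray) -> float:
    """Second sample L-moment (L-scale): mean over pairs of |x_(j) - x_(i)|/2.

    Computed from order statistics: sum_k x_(k) (2k - L + 1) / (L (L - 1)).
    """
    L = len(x)
    if L < 2:
        return 0.0
    xs = np.sort(x.astype(float))
    k = np.arange(L)
    return float(np.dot(xs, 2 * k - L + 1) / (L * (L - 1)))


def compute_feature(
    window: np.ndarray,
    feature_id: str,
    eps: float = 0.0,
    eps_wamp: float = 5.0,
) -> np.ndarray:
    """One feature of one window, per channel.

    Parameters
    ----------
    window : channels x L array (integer EMG samples or floats).
    feature_id : one of ``FEATURE_IDS``.
    eps : dead-band for zero crossings and slope-sign changes.
    eps_wamp : Willison-amplitude threshold, in raw amplitude units.

    Returns
    -------
    length-``channels`` float vector.
    """
    w = np.asarray(window, dtype=float)
    if w.ndim == 1:
        w = w[None, :]
    L = w.shape[1]
    if feature_id in _DIFF_FEATURES and L < 2:
        raise ValueError(f"{feature_id} needs a window of at least 2 samples")

    if feature_id == "RMS":
        return np.sqrt(np.mean(w * w, axis=1))
    if feature_id == "MAV":
        return np.mean(np.abs(w), axis=1)
    if feature_id == "WL":
        return np.sum(np.abs(np.diff(w, axis=1)), axis=1)
    if feature_id == "MNP":
        # mean of the two-sided periodogram power values; by Parseval this
        # equals the mean squared amplitude
        spec = np.abs(np.fft.fft(w, axis=1)) ** 2 / L
        return np.mean(spec, axis=1)
    if feature_id == "WENG":
        return np.array([_weng(ch) for ch in w])
    if feature_id == "ZC":
        a, b = w[:, :-1], w[:, 1:]
        return np.sum(
            (a * b < 0) & (np.abs(a) > eps) & (np.abs(b) > eps), axis=1
        ).astype(float)
    if feature_id == "SSC":
        if L < 3:
            return np.zeros(w.shape[0])
        d1 = w[:, 1:-1] - w[:, :-2]
        d2 = w[:, 1:-1] - w[:, 2:]
        return np.sum(d1 * d2 > eps, axis=1).astype(float)
    if feature_id == "LS":
        return np.array([_ls(ch) for ch in w])
    if feature_id == "MFL":
        ss = np.sum(np.diff(w, axis=1) ** 2, axis=1)
        # floor keeps the log finite on (degenerate) constant windows
        return np.log10(np.sqrt(np.maximum(ss, 1e-12)))
    if feature_id == "MSR":
        return np.mean(np.sqrt(np.abs(w)), axis=1)
    if feature_id == "WAMP":
        return np.sum(np.abs(np.diff(w, axis=1)) > eps_wamp, axis=1).astype(
            float
        )
    raise ValueError(f"unknown feature id {feature_id!r}")


def compute_feature_set(
    windows: np.ndarray,
    set_id: str,
    cfg: WindowingConfig | None = None,
    source: object | None = None,
    eps: float = 0.0,
    eps_wamp: float = 5.0,
) -> FeatureSequence:
    """Featurize a (n_windows, channels, L) window stack into a sequence.

    ``set_id`` names either a feature set ("HTD", "LS4") or a single feature.
    Output columns are channels-major, features-minor.
    """
    windows = np.asarray(windows)
    if windows.ndim != 3 or windows.shape[0] == 0:
        raise ValueError("expected a nonempty (n_windows, channels, L) stack")
    try:
        feats = FEATURE_SETS[set_id]
    except KeyError:
        raise ValueError(f"unknown feature set {set_id!r}") from None
    n_win, n_ch, _ = windows.shape
    out = np.empty((n_win, n_ch * len(feats)))
    for wi in range(n_win):
        per_feat = [
            compute_feature(windows[wi], f, eps=eps, eps_wamp=eps_wamp)
            for f in feats
        ]  # each: (n_ch,)
        # channels-major, features-minor
        out[wi] = np.stack(per_feat, axis=1).reshape(-1)
    if cfg is None:
        cfg = WindowingConfig(windows.shape[2], windows.shape[2])
    return FeatureSequence(out, cfg, feats, source=source)


def featurize_template(
    samples: np.ndarray,
    cfg: WindowingConfig,
    set_id: str = "RMS",
    source: object | None = None,
) -> FeatureSequence:
    """Window then featurize a channels x T template in one call."""
    return compute_feature_set(
        extract_windows(samples, cfg), set_id, cfg=cfg, source=source
    )
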