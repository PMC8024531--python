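"""Feature extraction for raw EEG segments and non-negative scaling.

Three representations feed the subspace learner: wavelet-packet subband
energies (WPD), short-time Fourier band powers (STFT), and kernel-PCA
scores.  WPD and KPCA features can be negative, while the factorization
requires non-negative input, so a pooled min-max scaler maps every feature
to [0, 1] using statistics from both domains (both are available when the
shared subspace is learned).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pywt
from scipy.signal import get_window
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import KernelPCA

from .io import FeatureMatrix, SignalSegment

__all__ = [
    "FeatureConfig",
    "NonnegativeMinMaxScaler",
    "wpd_features",
    "stft_features",
    "kpca_fit_transform",
    "scale_nonneg",
    "extract_features",
]


@dataclass
class FeatureConfig:
    """Configuration of the three extractors.

    Defaults are deliberate but arbitrary design choices; none are dictated
    by the method itself.  ``wpd_level=3`` gives 8 subband energies,
    ``stft_n_bands=8`` gives 8 band powers over 0..fs/2, and KPCA keeps 10
    components of an RBF kernel with ``gamma = 1/d`` when unset.
    """

    method: str = "wpd"
    wpd_wavelet: str = "db4"
    wpd_level: int = 3
    stft_window_length: int = 256
    stft_overlap: float = 0.5
    stft_n_bands: int = 8
    kpca_kernel: str = "rbf"
    kpca_gamma: float | None = None
    kpca_n_components: int = 10

    def __post_init__(self) -> None:
        if self.method not in ("wpd", "stft", "kpca"):
            raise ValueError(f"unknown feature method {self.method!r}")
        if self.wpd_level < 1:
            raise ValueError("wpd_level must be >= 1")
        if not (0 <= self.stft_overlap < 1):
            raise ValueError("stft_overlap must be in [0, 1)")
        if self.stft_n_bands < 1 or self.stft_window_length < 1:
            raise ValueError("STFT window and band counts must be positive")
        if self.kpca_n_components < 1:
            raise ValueError("kpca_n_components must be >= 1")
        if self.kpca_gamma is not None and self.kpca_gamma <= 0:
            raise ValueError("kpca_gamma must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


def wpd_features(
    seg: SignalSegment | np.ndarray, wavelet: str = "db4", level: int = 3
) -> np.ndarray:
    """Terminal-subband energies of a wavelet packet decomposition.

    The signal is decomposed ``level`` times with the given (orthogonal)
    wavelet in periodization mode; the energy (sum of squared coefficients)
    of each of the ``2**level`` terminal nodes, in frequency order, is the
    feature vector.  Band k nominally covers ``[k, k+1] * fs/2 / 2**level``.

    The signal is truncated to the largest multiple of ``2**level`` samples
    (e.g. 4096 of a 4097-sample Bonn segment) so the periodized transform
    is exactly orthonormal; the energies then sum to the analyzed signal's
    energy (Parseval).
    """
    x = seg.samples if isinstance(seg, SignalSegment) else np.asarray(seg, float)
    if x.size < 2**level:
        raise ValueError(
            f"segment of length {x.size} too short for level {level} "
            f"(needs >= {2 ** level} samples)"
        )
    n_keep = (x.size >> level) << level
    x = x[:n_keep]
    try:
        pywt.Wavelet(wavelet)
    except ValueError as exc:
        raise ValueError(f"unknown wavelet {wavelet!r}") from exc
    wp = pywt.WaveletPacket(x, wavelet=wavelet, mode="periodization")
    nodes = wp.get_level(level, order="freq")
    return np.array([float(np.sum(node.data**2)) for node in nodes])


def stft_features(
    seg: SignalSegment | np.ndarray,
    window_length: int = 256,
    overlap: float = 0.5,
    n_bands: int = 8,
) -> np.ndarray:
    """Time-averaged band power from a short-time Fourier transform.

    A periodic Hamming window slides over the signal with the given overlap
    (frames that would run past the end are dropped, no padding); the
    squared magnitude spectrum is averaged over frames and the one-sided
    frequency axis 0..fs/2 is split into ``n_bands`` equal-width bands whose
    powers are summed.  All entries are >= 0; a pure DC signal puts all its
    power in the band containing 0 Hz.
    """
    x = seg.samples if isinstance(seg, SignalSegment) else np.asarray(seg, float)
    if not (0 <= overlap < 1):
        raise ValueError("overlap must be in [0, 1)")
    if window_length > x.size:
        raise ValueError(
            f"window_length {window_length} exceeds segment length {x.size}"
        )
    hop = max(1, int(round(window_length * (1 - overlap))))
    window = get_window("hamming", window_length, fftbins=True)
    starts = range(0, x.size - window_length + 1, hop)
    spectra = [
        np.abs(np.fft.rfft(x[s : s + window_length] * window)) ** 2
        for s in starts
    ]
    mean_power = np.mean(spectra, axis=0)
    # rfft bin i sits at frequency i*fs/window_length; band edges are
    # j*fs/2/n_bands.  Assign each bin to a band by its frequency.
    n_bins = mean_power.size
    bin_frac = np.arange(n_bins) / (n_bins - 1)  # 0 .. 1 == 0 .. fs/2
    band_idx = np.minimum((bin_frac * n_bands).astype(int), n_bands - 1)
    return np.array(
        [float(mean_power[band_idx == b].sum()) for b in range(n_bands)]
    )


def kpca_fit_transform(
    train: FeatureMatrix | np.ndarray,
    others: list[FeatureMatrix | np.ndarray] | None = None,
    kernel: str = "rbf",
    gamma: float | None = None,
    n_components: int = 10,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Fit kernel PCA on *train* and project train plus *others* with it.

    The kernel matrix is centered in feature space and eigendecomposed; the
    top ``n_components`` eigenvectors define the projection.  Because the
    centered kernel matrix has rank at most ``n_samples - 1``,
    ``n_components`` must stay below the training sample count.
    """
    X = train.values if isinstance(train, FeatureMatrix) else np.asarray(train)
    others = others or []
    if gamma is not None and gamma <= 0:
        raise ValueError("gamma must be positive")
    if n_components >= X.shape[0]:
        raise ValueError(
            f"n_components={n_components} must be < n_samples={X.shape[0]} "
            "(centered kernel matrix has rank <= n_samples - 1)"
        )
    kpca = KernelPCA(n_components=n_components, kernel=kernel, gamma=gamma)
    train_scores = kpca.fit_transform(X)
    other_scores = [
        kpca.transform(
            o.values if isinstance(o, FeatureMatrix) else np.asarray(o)
        )
        for o in others
    ]
    return train_scores, other_scores


class NonnegativeMinMaxScaler(TransformerMixin, BaseEstimator):
    """Per-feature min-max scaler to [0, 1], fitted on pooled domains.

    Maps each feature affinely so that the pooled minimum goes to 0 and the
    pooled maximum to 1; constant features map to 0.  Besides enforcing the
    non-negativity the factorization requires, this equalizes feature
    scales, which the multiplicative updates are sensitive to.

    Attributes
    ----------
    data_min_, data_range_ : ndarray of shape (n_features,)
        Pooled per-feature minimum and (max - min) range.
    """

    def __init__(self, clip: bool = True):
        self.clip = clip

    def fit(self, X, y=None, extra: list[np.ndarray] | None = None):
        """Compute pooled statistics over X and any *extra* matrices."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        pooled = (
            X
            if not extra
            else np.vstack([X] + [np.atleast_2d(np.asarray(e)) for e in extra])
        )
        if pooled.size == 0:
            raise ValueError("cannot fit scaler on empty input")
        self.data_min_ = pooled.min(axis=0)
        self.data_range_ = pooled.max(axis=0) - self.data_min_
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count mismatch with fitted scaler")
        with np.errstate(invalid="ignore", divide="ignore"):
            out = (X - self.data_min_) / self.data_range_
        out[:, self.data_range_ == 0] = 0.0
        if self.clip:
            out = np.clip(out, 0.0, 1.0)
        return out


def scale_nonneg(
    reference: FeatureMatrix, others: list[FeatureMatrix] | None = None
) -> tuple[FeatureMatrix, list[FeatureMatrix], NonnegativeMinMaxScaler]:
    """Min-max scale reference and others to [0,1] using pooled statistics.

    Returns scaled copies (labels and names preserved) plus the fitted
    scaler so the identical map can be applied to later data.
    """
    others = others or []
    scaler = NonnegativeMinMaxScaler().fit(
        reference.values, extra=[o.values for o in others]
    )

    def _apply(fm: FeatureMatrix) -> FeatureMatrix:
        return FeatureMatrix(
            values=scaler.transform(fm.values),
            labels=fm.labels,
            feature_names=fm.feature_names,
        )

    return _apply(reference), [_apply(o) for o in others], scaler


def extract_features(
    segments: list[SignalSegment], config: FeatureConfig
) -> FeatureMatrix:
    """Apply the configured per-segment extractor (WPD or STFT) to a batch.

    KPCA operates on feature matrices, not raw segments; build a base
    representation first and use :func:`kpca_fit_transform` for that path.
    """
    if config.method == "wpd":
        vectors = [
            wpd_features(s, config.wpd_wavelet, config.wpd_level)
            for s in segments
        ]
        names = [f"wpd_band{i}" for i in range(2**config.wpd_level)]
    elif config.method == "stft":
        vectors = [
            stft_features(
                s,
                config.stft_window_length,
                config.stft_overlap,
                config.stft_n_bands,
            )
            for s in segments
        ]
        names = [f"stft_band{i}" for i in range(config.stft_n_bands)]
    else:
        raise ValueError(
            "extract_features handles 'wpd' and 'stft'; use "
            "kpca_fit_transform for KPCA"
        )
    labels = [s.label for s in segments]
    has_labels = all(l is not None for l in labels)
    return FeatureMatrix(
        values=np.vstack(vectors),
        labels=np.asarray(labels) if has_labels else None,
        feature_names=names,
    )
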