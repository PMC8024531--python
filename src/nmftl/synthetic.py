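"""Synthetic two-domain data with a planted shared subspace, and EEG-like
signals, so the whole pipeline is testable without any download.

The feature generator plants a common non-negative basis H* (r_true x d):
each domain draws per-sample coefficient rows around class centers, the
target domain's centers additionally shifted to create a controlled domain
gap, and emits X = W H* + noise clipped at zero.  The signal generator
emits Bonn-shaped single-channel segments: a background class of
low-amplitude alpha/beta-band sinusoids in noise, and an "ictal-like" class
with an added dominant rhythmic component — a caricature of seizure EEG,
not a physiological simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import FeatureMatrix, SignalSegment

__all__ = [
    "DomainPairSpec",
    "SyntheticEEGSpec",
    "gen_domain_pair",
    "gen_eeg_segments",
]


@dataclass
class DomainPairSpec:
    """Study conditions for the two-domain feature generator.

    Defaults mirror the scale of the motivating EEG experiments: a handful
    of spectral features (d=12), source domain three times the size of the
    target (150 vs 50), two classes separated by 2 coefficient units, a
    moderate target shift of 1 unit, and additive noise of 0.3 sd.
    """

    d: int = 12
    r_true: int = 4
    n_s: int = 150
    n_t: int = 50
    n_classes: int = 2
    class_separation: float = 2.0
    domain_shift: float = 1.0
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.d, self.r_true, self.n_s, self.n_t, self.n_classes) < 1:
            raise ValueError("all counts must be positive")
        if self.r_true > self.d:
            raise ValueError("r_true must not exceed d")
        if self.noise_sd < 0 or self.domain_shift < 0:
            raise ValueError("noise_sd and domain_shift must be >= 0")


@dataclass
class SyntheticEEGSpec:
    """Study conditions for the EEG-like signal generator."""

    n_segments: int = 20
    segment_length: int = 4097
    sampling_rate: float = 173.61
    ictal_amplitude_factor: float = 3.0
    ictal_dominant_freq: float = 3.5
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_segments < 1 or self.segment_length < 2:
            raise ValueError("counts must be positive")
        if self.ictal_amplitude_factor < 1:
            raise ValueError("ictal_amplitude_factor must be >= 1")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")


@dataclass
class DomainPairTruth:
    """Ground truth planted by :func:`gen_domain_pair`."""

    H: np.ndarray  # r_true x d shared basis
    source_centers: np.ndarray  # n_classes x r_true
    target_centers: np.ndarray  # n_classes x r_true
    Ws: np.ndarray
    Wt: np.ndarray


def gen_domain_pair(
    spec: DomainPairSpec,
) -> tuple[FeatureMatrix, FeatureMatrix, DomainPairTruth]:
    """Generate source and target feature matrices sharing a planted basis.

    Construction (all draws from one seeded generator, so the output is a
    pure function of the spec):

    1. ``H* = |N(0,1)|`` of shape r_true x d.
    2. Class centers in coefficient space: class c sits at
       ``|N(0,1)| + c * class_separation`` per coordinate; target centers
       get an extra ``domain_shift`` added to a random half of their
       coordinates.
    3. Coefficient rows ``w = |center + N(0,1)|`` (absolute value, so the
       coefficient distribution has no atom at zero).
    4. ``X = W H* + N(0, noise_sd)``, negatives clipped to 0 (the
       factorization needs non-negative input).
    """
    rng = np.random.default_rng(spec.seed)
    H = np.abs(rng.standard_normal((spec.r_true, spec.d)))
    base = np.abs(rng.standard_normal((spec.n_classes, spec.r_true)))
    offsets = np.arange(spec.n_classes)[:, None] * spec.class_separation
    source_centers = base + offsets
    shift_mask = rng.random((spec.n_classes, spec.r_true)) < 0.5
    target_centers = source_centers + spec.domain_shift * shift_mask

    def _domain(
        n: int, centers: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        labels = rng.integers(0, spec.n_classes, size=n)
        W = np.abs(centers[labels] + rng.standard_normal((n, spec.r_true)))
        X = W @ H + spec.noise_sd * rng.standard_normal((n, spec.d))
        return np.clip(X, 0.0, None), labels, W

    Xs, ys, Ws = _domain(spec.n_s, source_centers)
    Xt, yt, Wt = _domain(spec.n_t, target_centers)
    names = [f"f{i}" for i in range(spec.d)]
    source = FeatureMatrix(values=Xs, labels=ys, feature_names=names)
    target = FeatureMatrix(values=Xt, labels=yt, feature_names=names)
    truth = DomainPairTruth(
        H=H,
        source_centers=source_centers,
        target_centers=target_centers,
        Ws=Ws,
        Wt=Wt,
    )
    return source, target, truth


#: Background rhythm frequencies (Hz): alpha and low-beta range.
_BACKGROUND_FREQS = (8.0, 11.0, 15.0, 22.0)


def gen_eeg_segments(spec: SyntheticEEGSpec) -> list[SignalSegment]:
    """Generate labeled EEG-like segments, half background and half ictal-like.

    Background segments are sums of low-amplitude alpha/beta sinusoids with
    random phases plus Gaussian noise.  Ictal-like segments add a dominant
    low-frequency rhythm (default 3.5 Hz, the spike-and-wave range) scaled
    by ``ictal_amplitude_factor``, so their variance exceeds background
    variance by construction.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.segment_length) / spec.sampling_rate
    segments: list[SignalSegment] = []
    for label in ("background", "ictal"):
        for _ in range(spec.n_segments):
            x = np.zeros_like(t)
            for f in _BACKGROUND_FREQS:
                amp = rng.uniform(0.5, 1.0)
                x += amp * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
            if label == "ictal":
                x += spec.ictal_amplitude_factor * np.sin(
                    2 * np.pi * spec.ictal_dominant_freq * t
                    + rng.uniform(0, 2 * np.pi)
                )
            x += spec.noise_sd * rng.standard_normal(t.size)
            segments.append(
                SignalSegment(
                    samples=x, sampling_rate=spec.sampling_rate, label=label
                )
            )
    return segments
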