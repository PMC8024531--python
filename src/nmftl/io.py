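"""Readers and writers for the two plain-text formats the toolkit touches.

Bonn-style EEG segments are ASCII files with one amplitude sample per line
(single channel, canonically 4097 samples at 173.61 Hz).  Feature matrices
travel as comma-separated text with a mandatory header row and an optional
label column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: Canonical Bonn corpus sampling rate in Hz.
BONN_SAMPLING_RATE = 173.61


@dataclass
class SignalSegment:
    """One single-channel EEG recording.

    Parameters
    ----------
    samples : ndarray
        Amplitude values, arbitrary units.
    sampling_rate : float
        Samples per second; defaults to the Bonn corpus rate of 173.61 Hz.
    label : str or None
        Optional class tag (e.g. one of the Bonn groups A-E).
    source_path : str or None
        Provenance of the segment, if read from disk.
    """

    samples: np.ndarray
    sampling_rate: float = BONN_SAMPLING_RATE
    label: str | None = None
    source_path: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a nonempty 1-D array")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def duration(self) -> float:
        """Segment length in seconds."""
        return self.samples.size / self.sampling_rate

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class FeatureMatrix:
    """A samples-by-features matrix with optional labels.

    This is the unit of data both domains share: rows are samples, columns
    are features, and source and target domains must agree on the columns.
    """

    values: np.ndarray
    labels: np.ndarray | None = None
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise ValueError("feature matrix must be at least 1x1")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (self.values.shape[0],):
                raise ValueError(
                    f"labels length {self.labels.shape} does not match "
                    f"{self.values.shape[0]} samples"
                )
        if self.feature_names is not None:
            self.feature_names = list(self.feature_names)
            if len(self.feature_names) != self.values.shape[1]:
                raise ValueError("feature_names length must equal n_features")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


class BonnParseError(ValueError):
    """A Bonn segment file contained a line that does not parse as a number."""


def read_bonn_segment(
    path: str | Path,
    sampling_rate: float = BONN_SAMPLING_RATE,
    label: str | None = None,
) -> SignalSegment:
    """Read a Bonn-format EEG segment (one numeric sample per line).

    Blank lines and lines starting with ``#`` are skipped, tolerating
    packaging variants of the corpus.  A canonical file has 4097 lines,
    i.e. 23.6 s at 173.61 Hz.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    BonnParseError
        If a nonblank line is not a single number; the message names the
        offending (1-based) line number.
    """
    path = Path(path)
    samples: list[float] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            try:
                samples.append(float(stripped))
            except ValueError as exc:
                raise BonnParseError(
                    f"{path}: line {lineno}: {stripped!r} is not a number"
                ) from exc
    if not samples:
        raise BonnParseError(f"{path}: no samples found")
    return SignalSegment(
        samples=np.array(samples),
        sampling_rate=sampling_rate,
        label=label,
        source_path=str(path),
    )


def write_bonn_segment(segment: SignalSegment, path: str | Path) -> None:
    """Write a segment in Bonn format (one sample per line)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for value in segment.samples:
            fh.write(f"{value:g}\n")


def read_feature_csv(
    path: str | Path, label_column: str | None = None
) -> FeatureMatrix:
    """Read a delimited feature matrix (header row mandatory).

    Parameters
    ----------
    path : path
        CSV file: comma separator, ``.`` decimal point, UTF-8.
    label_column : str, optional
        Column holding class labels; the remaining columns must be numeric.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, encoding="utf-8")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed delimited text: {exc}") from exc
    labels = None
    if label_column is not None:
        if label_column not in frame.columns:
            raise ValueError(f"{path}: no column named {label_column!r}")
        labels = frame[label_column].to_numpy()
        frame = frame.drop(columns=[label_column])
    try:
        values = frame.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric feature cell: {exc}") from exc
    return FeatureMatrix(
        values=values, labels=labels, feature_names=list(frame.columns)
    )


def write_feature_csv(
    fm: FeatureMatrix, path: str | Path, label_column: str = "label"
) -> None:
    """Write a FeatureMatrix as CSV; round-trips through read_feature_csv."""
    names = fm.feature_names or [f"f{i}" for i in range(fm.n_features)]
    frame = pd.DataFrame(fm.values, columns=names)
    if fm.labels is not None:
        frame[label_column] = fm.labels
    frame.to_csv(path, index=False, encoding="utf-8", float_format="%.17g")


def read_bonn_directory(
    directory: str | Path,
    sampling_rate: float = BONN_SAMPLING_RATE,
    label: str | None = None,
    pattern: str = "*.txt",
) -> list[SignalSegment]:
    """Read every Bonn segment file matching *pattern* in a directory."""
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"not a directory: {directory}")
    return [
        read_bonn_segment(p, sampling_rate=sampling_rate, label=label)
        for p in sorted(directory.glob(pattern))
    ]


def stack_segments(
    feature_vectors: Sequence[np.ndarray],
    labels: Sequence[str] | None = None,
    feature_names: list[str] | None = None,
) -> FeatureMatrix:
    """Stack per-segment feature vectors into a FeatureMatrix."""
    values = np.vstack([np.asarray(v, dtype=float) for v in feature_vectors])
    return FeatureMatrix(
        values=values,
        labels=None if labels is None else np.asarray(labels),
        feature_names=feature_names,
    )
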