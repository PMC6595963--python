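"""Static and sliding-window Pearson functional connectivity.

A subject's data is a T x 90 matrix of region-averaged BOLD samples at a
fixed repetition time (TR).  Static functional connectivity is one Pearson
correlation matrix over the full scan; dynamic functional connectivity is a
sequence of matrices over rectangular sliding windows (default width 25 TR,
step 1 TR, i.e. 50 s windows advanced by 2 s at TR = 2 s).

Windows are indexed in volumes, half-open ``[start, start + length)``,
0-based internally.  The window count is ``floor((T - length)/step) + 1``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Union

import numpy as np


class ConnectivityError(ValueError):
    """Raised on invalid time series or window geometry."""


@dataclass
class SubjectTimeSeries:
    """One subject's T x n_regions BOLD matrix (arbitrary units)."""

    subject_id: str
    data: np.ndarray
    tr_seconds: float = 2.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ConnectivityError(
                f"subject {self.subject_id}: time series must be 2-D, "
                f"got shape {self.data.shape}"
            )
        if self.data.shape[0] < 2:
            raise ConnectivityError(
                f"subject {self.subject_id}: need at least 2 timepoints"
            )
        if not np.all(np.isfinite(self.data)):
            raise ConnectivityError(
                f"subject {self.subject_id}: non-finite values in time series"
            )

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


@dataclass
class FCMatrix:
    """A symmetric correlation matrix with unit diagonal.

    ``window_start``/``window_length`` are volume indices, or the strings
    ``"static"``/``"full"`` for a full-scan matrix.
    """

    values: np.ndarray
    window_start: Union[int, str] = "static"
    window_length: Union[int, str] = "full"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ConnectivityError(f"FC matrix must be square, got {v.shape}")
        self.values = v

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass
class WindowedFCSeries:
    """Stack of per-window correlation matrices from one subject."""

    values: np.ndarray  # (n_windows, n, n)
    window_length: int = 25
    step: int = 1
    starts: np.ndarray = field(default=None)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ConnectivityError("windowed FC stack must be 3-D")
        if self.starts is None:
            self.starts = np.arange(self.values.shape[0]) * self.step
        self.starts = np.asarray(self.starts, dtype=int)

    def __len__(self) -> int:
        return self.values.shape[0]

    def __getitem__(self, k: int) -> FCMatrix:
        return FCMatrix(self.values[k], int(self.starts[k]), self.window_length)

    def __iter__(self) -> Iterator[FCMatrix]:
        return (self[k] for k in range(len(self)))


def _check_constant(seg: np.ndarray, subject_id: str, start, length) -> None:
    rng = seg.max(axis=0) - seg.min(axis=0)
    bad = np.flatnonzero(rng == 0)
    if bad.size:
        raise ConnectivityError(
            f"subject {subject_id}: region {bad[0] + 1} is constant within "
            f"window [{start}, {start}+{length}); correlation undefined"
        )


def _pearson(seg: np.ndarray) -> np.ndarray:
    c = np.corrcoef(seg, rowvar=False)
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return c


def pearson_fc(
    ts: SubjectTimeSeries, start: int = 0, length: int | None = None
) -> FCMatrix:
    """Pearson correlation matrix over volumes ``[start, start + length)``.

    ``length=None`` uses the full series and labels the result "static".
    A constant region within the window is an error (its correlation with
    anything is undefined).
    """
    T = ts.n_volumes
    full = length is None
    if full:
        start, length = 0, T
    start, length = int(start), int(length)
    if start < 0 or length < 3 or start + length > T:
        raise ConnectivityError(
            f"invalid window [{start}, {start}+{length}) for T={T} "
            "(need start >= 0, length >= 3, start+length <= T)"
        )
    seg = ts.data[start : start + length]
    _check_constant(seg, ts.subject_id, "static" if full else start, length)
    return FCMatrix(
        _pearson(seg),
        "static" if full else start,
        "full" if full else length,
    )


def sliding_windows(
    ts: SubjectTimeSeries, window_length: int = 25, step: int = 1
) -> WindowedFCSeries:
    """All sliding-window correlation matrices of a subject's series.

    Window k covers volumes ``[k*step, k*step + window_length)``; there are
    ``floor((T - window_length)/step) + 1`` windows.
    """
    T = ts.n_volumes
    window_length, step = int(window_length), int(step)
    if window_length > T:
        raise ConnectivityError(
            f"subject {ts.subject_id}: window length {window_length} exceeds "
            f"series length {T}"
        )
    if step < 1:
        raise ConnectivityError("step must be >= 1")
    if window_length < 3:
        raise ConnectivityError("window length must be >= 3")
    n_windows = (T - window_length) // step + 1
    n = ts.n_regions
    out = np.empty((n_windows, n, n), dtype=float)
    for k in range(n_windows):
        s = k * step
        seg = ts.data[s : s + window_length]
        _check_constant(seg, ts.subject_id, s, window_length)
        out[k] = _pearson(seg)
    return WindowedFCSeries(out, window_length, step)


def n_windows(T: int, window_length: int = 25, step: int = 1) -> int:
    """Window count for a series of T volumes: floor((T - W)/s) + 1."""
    if window_length > T:
        raise ConnectivityError(f"window length {window_length} exceeds T={T}")
    return (T - window_length) // step + 1


def variance_stabilize(fc: Union[FCMatrix, np.ndarray]) -> np.ndarray:
    """Fisher r-to-z transform, ``z = atanh(r)``, applied off-diagonal.

    Monotone, so it never changes the ranking of edges; it is applied before
    proportional (sparsity) thresholding.  Off-diagonal values at exactly
    +/-1 are clipped to +/-(1 - 1e-7) with a warning.  The diagonal is set
    to 0 and is excluded from all downstream edge operations.
    """
    values = fc.values if isinstance(fc, FCMatrix) else np.asarray(fc, dtype=float)
    r = values.copy()
    diag = np.eye(r.shape[-1], dtype=bool)
    off = ~diag
    if r.ndim == 3:
        off = np.broadcast_to(off, r.shape)
        diag = np.broadcast_to(diag, r.shape)
    clip = 1.0 - 1e-7
    n_clipped = int(np.count_nonzero(off & (np.abs(r) >= 1.0)))
    if n_clipped:
        warnings.warn(
            f"{n_clipped} off-diagonal correlation(s) at +/-1 clipped to "
            f"+/-{clip} before variance stabilization",
            RuntimeWarning,
            stacklevel=2,
        )
    z = np.arctanh(np.clip(r, -clip, clip))
    z[diag] = 0.0
    return z
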