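"""Binary graph construction, degree centrality, hub calling, hub probability.

A correlation matrix is binarized either with an *absolute* threshold (edge
kept when the signed correlation strictly exceeds a fixed value, e.g.
r > 0.25; strong negative correlations are not edges) or a *proportional*
threshold (a fixed fraction of the strongest off-diagonal edges kept,
"sparsity").  Degree D_i is the neighbor count of region i; per graph the
degrees are normalized to Z-scores over the 90 regions, and a region is a
hub when Z_i > 1, i.e. its degree lies strictly more than one standard
deviation above the across-region mean.  Hub probability (centrality
frequency) of a region is the fraction of sliding windows in which it is a
hub.

Numerical conventions, all strict and deterministic:

* thresholding and hub calling use strict ``>``; boundary values excluded;
* the Z-score uses the population (divide-by-N) standard deviation across
  regions, switchable via ``ddof``;
* the proportional edge budget for sparsity s on n nodes is
  ``round_half_up(s * n*(n-1)/2)``; ties at the cutoff are broken by the
  smaller lexicographic (i, j) pair so runs are bit-reproducible;
* if the degree standard deviation of a graph is zero, all Z are 0 and no
  hubs are called.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np

from .connectivity import FCMatrix, SubjectTimeSeries, WindowedFCSeries, \
    pearson_fc, sliding_windows, variance_stabilize


class GraphError(ValueError):
    """Raised on invalid thresholding specifications or graphs."""


@dataclass(frozen=True)
class ThresholdSpec:
    """How to binarize a correlation matrix.

    mode
        ``"absolute"`` (value is a correlation threshold, e.g. 0.25) or
        ``"proportional"`` (value is a sparsity, the kept edge fraction).
    weight_space
        ``"raw_r"`` ranks/thresholds raw correlations;
        ``"variance_stabilized"`` applies the Fisher z transform first.
        The two give identical proportional graphs (the map is monotone);
        in absolute mode the threshold is interpreted in the chosen space.
    """

    mode: str
    value: float
    weight_space: str = "raw_r"

    def __post_init__(self):
        if self.mode not in ("absolute", "proportional"):
            raise GraphError(f"unknown threshold mode {self.mode!r}")
        if self.weight_space not in ("raw_r", "variance_stabilized"):
            raise GraphError(f"unknown weight space {self.weight_space!r}")
        if self.mode == "proportional" and not 0.0 < self.value <= 1.0:
            raise GraphError(
                f"proportional threshold (sparsity) must be in (0, 1], "
                f"got {self.value}"
            )
        if (self.mode == "absolute" and self.weight_space == "raw_r"
                and not -1.0 < self.value < 1.0):
            raise GraphError(
                f"absolute correlation threshold must be in (-1, 1), "
                f"got {self.value}"
            )

    @property
    def label(self) -> str:
        kind = "r" if self.mode == "absolute" else "sparsity"
        return f"{self.mode}_{kind}{self.value:g}"


@dataclass
class BinaryGraph:
    """Symmetric binary adjacency matrix with zero diagonal."""

    adjacency: np.ndarray
    spec: ThresholdSpec
    window: Union[int, str, None] = None

    def __post_init__(self):
        a = np.asarray(self.adjacency, dtype=bool)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise GraphError(f"adjacency must be square, got {a.shape}")
        if np.any(np.diagonal(a)):
            raise GraphError("adjacency diagonal must be zero")
        if not np.array_equal(a, a.T):
            raise GraphError("adjacency must be symmetric")
        self.adjacency = a

    @property
    def n_regions(self) -> int:
        return self.adjacency.shape[0]


@dataclass
class DegreeProfile:
    """Per-region degree D_i and Z-scored degree Z_i of one graph."""

    degree: np.ndarray
    zscore: np.ndarray


@dataclass
class HubProbabilityProfile:
    """Per-region fraction of windows in which the region is a hub."""

    prob: np.ndarray
    n_windows: int
    spec: ThresholdSpec

    @property
    def hub_window_counts(self) -> np.ndarray:
        return np.rint(self.prob * self.n_windows).astype(int)


def edge_budget(sparsity: float, n_regions: int) -> int:
    """Number of kept edges for a sparsity: round-half-up of s * n(n-1)/2."""
    n_pairs = n_regions * (n_regions - 1) // 2
    m = int(math.floor(sparsity * n_pairs + 0.5))
    if m > n_pairs:
        raise GraphError(
            f"sparsity {sparsity} asks for {m} edges but only {n_pairs} pairs exist"
        )
    return m


def _weights(values: np.ndarray, spec: ThresholdSpec) -> np.ndarray:
    if spec.weight_space == "variance_stabilized":
        return variance_stabilize(values)
    return values


def binarize_stack(values: np.ndarray, spec: ThresholdSpec) -> np.ndarray:
    """Binarize a (n_windows, n, n) stack of FC matrices; returns bool stack."""
    values = np.asarray(values, dtype=float)
    squeeze = values.ndim == 2
    if squeeze:
        values = values[None]
    nw, n, _ = values.shape
    w = _weights(values, spec)
    if spec.mode == "absolute":
        adj = w > spec.value
        diag = np.eye(n, dtype=bool)
        adj &= ~diag[None]
        adj &= adj.transpose(0, 2, 1)  # exact symmetry despite fp noise
    else:
        m = edge_budget(spec.value, n)
        iu, ju = np.triu_indices(n, k=1)  # row-major == lexicographic pairs
        flat = w[:, iu, ju]
        # stable sort on descending weight keeps the lexicographically
        # smallest pair first among ties
        order = np.argsort(-flat, axis=1, kind="stable")[:, :m]
        adj = np.zeros((nw, n, n), dtype=bool)
        rows = np.repeat(np.arange(nw), m)
        sel = order.ravel()
        adj[rows, iu[sel], ju[sel]] = True
        adj |= adj.transpose(0, 2, 1)
    return adj[0] if squeeze else adj


def binarize(fc: FCMatrix, spec: ThresholdSpec) -> BinaryGraph:
    """Binarize one FC matrix under an absolute or proportional threshold."""
    adj = binarize_stack(fc.values, spec)
    return BinaryGraph(adj, spec, fc.window_start)


def degree(graph: Union[BinaryGraph, np.ndarray]) -> np.ndarray:
    """Degree centrality D_i: neighbor count of each region (i != j)."""
    adj = graph.adjacency if isinstance(graph, BinaryGraph) else np.asarray(graph)
    return adj.sum(axis=-1).astype(int)


def zscore_degree(D: np.ndarray, ddof: int = 0) -> np.ndarray:
    """Z_i = (D_i - mean D) / sd(D) across regions of one graph.

    ``ddof=0`` (population sd) by default.  A graph whose degrees are all
    equal has sd 0; its Z-scores are defined as all-zero, so it contains no
    hubs.  Works on a single degree vector or a (n_windows, n) stack.
    """
    D = np.asarray(D, dtype=float)
    if D.shape[-1] < 2:
        raise GraphError("need at least 2 regions to Z-score degrees")
    mean = D.mean(axis=-1, keepdims=True)
    sd = D.std(axis=-1, ddof=ddof, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (D - mean) / sd
    return np.where(sd == 0, 0.0, z)


def call_hubs(Z: np.ndarray) -> np.ndarray:
    """Hub indicator: degree strictly more than one SD above the mean (Z > 1)."""
    return np.asarray(Z) > 1.0


def hub_probability(
    windowed: WindowedFCSeries, spec: ThresholdSpec, ddof: int = 0
) -> HubProbabilityProfile:
    """Fraction of windows in which each region is a hub.

    Per window: binarize -> degree -> Z-score -> hub call; then average the
    hub indicator over windows.  Invariant to window order.
    """
    if len(windowed) < 1:
        raise GraphError("need at least one window")
    adj = binarize_stack(windowed.values, spec)
    D = degree(adj)
    Z = zscore_degree(D, ddof=ddof)
    hubs = call_hubs(Z)
    return HubProbabilityProfile(hubs.mean(axis=0), len(windowed), spec)


def window_hub_calls(
    windowed: WindowedFCSeries, spec: ThresholdSpec, ddof: int = 0
) -> np.ndarray:
    """(n_windows, n_regions) boolean hub-call matrix, for audit output."""
    adj = binarize_stack(windowed.values, spec)
    return call_hubs(zscore_degree(degree(adj), ddof=ddof))


def static_centrality(
    ts: SubjectTimeSeries, spec: ThresholdSpec, ddof: int = 0
) -> DegreeProfile:
    """Full-scan degree profile: static FC -> binarize -> degree -> Z-score.

    The Z-scored degree is the per-region measure of the static analysis.
    """
    fc = pearson_fc(ts)
    adj = binarize_stack(fc.values, spec)
    D = degree(adj)
    return DegreeProfile(D, zscore_degree(D, ddof=ddof))


def dynamic_hub_probability(
    ts: SubjectTimeSeries,
    spec: ThresholdSpec,
    window_length: int = 25,
    step: int = 1,
    ddof: int = 0,
) -> HubProbabilityProfile:
    """Convenience composition: sliding windows -> hub probability."""
    return hub_probability(sliding_windows(ts, window_length, step), spec, ddof=ddof)
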