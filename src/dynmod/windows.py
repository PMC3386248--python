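"""Sliding-window construction of signed, weighted connectivity graphs.

A window of ``L`` volumes (L odd, so each graph can be centered on a single
volume) is advanced through a subject's ROI series with a fixed stride
(default 1 volume).  Within each window the N x N matrix of pairwise Pearson
correlations is taken as a fully connected, signed, weighted graph — no
thresholding or binarization is applied at any point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .synthetic_bold import RoiTimeSeries

__all__ = [
    "WindowConfig",
    "ConnectivityMatrix",
    "DynamicConnectivity",
    "window_count",
    "correlation_graph",
    "dynamic_graphs",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window geometry: odd window length and stride, in volumes."""

    length_volumes: int
    stride_volumes: int = 1

    def __post_init__(self) -> None:
        if self.length_volumes < 1 or self.length_volumes % 2 == 0:
            raise ValueError(f"window length must be an odd positive integer, got {self.length_volumes}")
        if self.stride_volumes < 1:
            raise ValueError(f"stride must be a positive integer, got {self.stride_volumes}")


@dataclass
class ConnectivityMatrix:
    """Symmetric signed Pearson-weight graph for one window.

    The diagonal is stored as 1 but is excluded from all modularity, strength
    and degree computations downstream.
    """

    weights: np.ndarray
    window_index: int = 0
    center_volume: int = 0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = self.weights.shape[0]
        if self.weights.ndim != 2 or self.weights.shape != (n, n):
            raise ValueError("weights must be a square matrix")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights contain non-finite values")
        if not np.allclose(self.weights, self.weights.T, atol=1e-12):
            raise ValueError("weights must be symmetric")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass
class DynamicConnectivity:
    """Ordered sequence of windowed connectivity graphs for one subject."""

    graphs: list
    config: WindowConfig
    subject_id: str = ""

    @property
    def n_windows(self) -> int:
        return len(self.graphs)


def window_count(T: int, config: WindowConfig) -> int:
    """Number of windows of length ``L`` and the configured stride fitting in ``T`` volumes.

    For T=100, L=11, stride=1 this is 90 — one graph per centered volume.
    """
    L = config.length_volumes
    if L > T:
        raise ValueError(f"window length {L} exceeds series length {T}")
    return (T - L) // config.stride_volumes + 1


def _pearson(block: np.ndarray, strict: bool, context: str) -> np.ndarray:
    """Pearson correlation of the columns of ``block`` with zero-variance handling."""
    x = block - block.mean(axis=0)
    ss = np.einsum("ij,ij->j", x, x)
    zero = ss <= 0.0
    if np.any(zero):
        names = np.where(zero)[0].tolist()
        if strict:
            raise ValueError(f"zero-variance region(s) {names} in {context}")
        logger.warning("zero-variance region(s) %s in %s; their weights set to 0", names, context)
        ss = np.where(zero, 1.0, ss)
    denom = np.sqrt(ss)
    corr = (x.T @ x) / np.outer(denom, denom)
    if np.any(zero):
        corr[zero, :] = 0.0
        corr[:, zero] = 0.0
    np.clip(corr, -1.0, 1.0, out=corr)
    np.fill_diagonal(corr, 1.0)
    return corr


def correlation_graph(
    ts: RoiTimeSeries,
    start_volume: int,
    config: WindowConfig,
    window_index: int = 0,
    strict: bool = True,
) -> ConnectivityMatrix:
    """Pearson graph over volumes ``[start, start+L)`` (0-based, half-open).

    ``center_volume`` is ``start + (L-1)//2``.  A zero-variance region raises
    in strict mode; in lenient mode its weights are set to 0 with a logged
    warning.
    """
    L = config.length_volumes
    T = ts.n_volumes
    if start_volume < 0 or start_volume + L > T:
        raise ValueError(f"window [{start_volume}, {start_volume + L}) does not fit in {T} volumes")
    block = ts.data[start_volume : start_volume + L]
    corr = _pearson(block, strict, f"window starting at volume {start_volume}")
    return ConnectivityMatrix(
        weights=corr,
        window_index=window_index,
        center_volume=start_volume + (L - 1) // 2,
    )


def dynamic_graphs(ts: RoiTimeSeries, config: WindowConfig, strict: bool = True) -> DynamicConnectivity:
    """All sliding-window graphs for one subject, windows advancing by the stride."""
    n = window_count(ts.n_volumes, config)
    graphs = [
        correlation_graph(ts, w * config.stride_volumes, config, window_index=w, strict=strict)
        for w in range(n)
    ]
    return DynamicConnectivity(graphs=graphs, config=config, subject_id=ts.subject_id)
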