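"""Eigenvalue reduction of recurrence matrices.

The matrix is repeatedly sharpened (2-D cross-correlation with a 3x3 kernel
followed by ReLU) and max-pooled until its side length is at most a target
size; the modulus of the largest-magnitude eigenvalue of the final matrix is
the feature.  With the default schedule (valid convolution, pool 5, stride 1)
a 98x98 plot shrinks by 6 per iteration: 98 -> 92 -> 86 -> 80 -> 74 -> 68.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import correlate2d

from .exceptions import ConfigurationError, InputError
from .recurrence import FRPMatrix

__all__ = [
    "SHARPEN_KERNEL",
    "EigenConfig",
    "ReducedMatrix",
    "relu_convolve",
    "max_pool",
    "reduce_matrix",
    "largest_recurrence_eigenvalue",
]

SHARPEN_KERNEL = np.array([[0.0, -1.0, 0.0],
                           [-1.0, 5.0, -1.0],
                           [0.0, -1.0, 0.0]])


@dataclass(frozen=True)
class EigenConfig:
    """Reduction schedule: kernel, pooling size/stride, target side length."""

    kernel: np.ndarray = field(default_factory=lambda: SHARPEN_KERNEL.copy())
    pool_size: int = 5
    stride: int = 1
    final_size: int = 70
    boundary: str = "valid"

    def __post_init__(self) -> None:
        k = np.asarray(self.kernel, dtype=np.float64)
        object.__setattr__(self, "kernel", k)
        if k.ndim != 2 or k.shape[0] != k.shape[1]:
            raise ConfigurationError("kernel must be a square 2-D array")
        if self.pool_size < 2:
            raise ConfigurationError("pool_size must be >= 2")
        if self.stride < 1:
            raise ConfigurationError("stride must be >= 1")
        if self.final_size < 2:
            raise ConfigurationError("final_size must be >= 2")
        if self.boundary not in ("valid", "same"):
            raise ConfigurationError("boundary must be 'valid' or 'same'")


@dataclass
class ReducedMatrix:
    """Final reduced matrix plus the side lengths traversed."""

    cR: np.ndarray
    history: list[int]


def relu_convolve(M: np.ndarray, kernel: np.ndarray = SHARPEN_KERNEL,
                  boundary: str = "valid") -> np.ndarray:
    """2-D cross-correlation with ``kernel`` followed by elementwise ReLU."""
    M = np.asarray(M, dtype=np.float64)
    kernel = np.asarray(kernel, dtype=np.float64)
    if M.ndim != 2:
        raise InputError("input must be a 2-D matrix")
    if M.shape[0] < kernel.shape[0] or M.shape[1] < kernel.shape[1]:
        raise InputError(f"matrix {M.shape} smaller than kernel {kernel.shape}")
    if boundary not in ("valid", "same"):
        raise InputError("boundary must be 'valid' or 'same'")
    out = correlate2d(M, kernel, mode=boundary)
    return np.maximum(out, 0.0)


def _pool_starts(n: int, size: int, stride: int) -> list[int]:
    """Window start offsets: full windows every ``stride``, plus one truncated
    trailing window when the stride does not land a full window on the edge."""
    starts = list(range(0, n - size + 1, stride))
    last = starts[-1] if starts else 0
    if not starts or last + size < n:
        nxt = last + stride if starts else 0
        if nxt < n:
            starts.append(nxt)
    return starts


def max_pool(M: np.ndarray, pool_size: int = 5, stride: int = 1) -> np.ndarray:
    """Max pooling with ``pool_size`` x ``pool_size`` windows advancing by
    ``stride``; a truncated trailing window covers any leftover edge."""
    M = np.asarray(M, dtype=np.float64)
    if M.ndim != 2:
        raise InputError("input must be a 2-D matrix")
    if pool_size > min(M.shape):
        raise InputError(f"pool_size {pool_size} exceeds matrix side {min(M.shape)}")
    rows = _pool_starts(M.shape[0], pool_size, stride)
    cols = _pool_starts(M.shape[1], pool_size, stride)
    out = np.empty((len(rows), len(cols)), dtype=np.float64)
    for a, i in enumerate(rows):
        for b, j in enumerate(cols):
            out[a, b] = M[i:i + pool_size, j:j + pool_size].max()
    return out


def reduce_matrix(R: FRPMatrix | np.ndarray, config: EigenConfig | None = None) -> ReducedMatrix:
    """Iterate convolution + ReLU + max pooling while the side exceeds
    ``final_size``; each iteration must strictly shrink the matrix."""
    if config is None:
        config = EigenConfig()
    M = R.R if isinstance(R, FRPMatrix) else np.asarray(R, dtype=np.float64)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise InputError("recurrence matrix must be square")
    history = [M.shape[0]]
    while M.shape[0] > config.final_size:
        M = relu_convolve(M, config.kernel, config.boundary)
        M = max_pool(M, config.pool_size, config.stride)
        if M.shape[0] >= history[-1]:
            raise ConfigurationError(
                f"reduction schedule does not shrink the matrix "
                f"({history[-1]} -> {M.shape[0]}); adjust stride/boundary"
            )
        history.append(M.shape[0])
    return ReducedMatrix(cR=M, history=history)


def largest_recurrence_eigenvalue(R: FRPMatrix | np.ndarray,
                                  config: EigenConfig | None = None) -> float:
    """Modulus of the largest-magnitude eigenvalue of the reduced matrix."""
    reduced = reduce_matrix(R, config)
    return float(np.abs(np.linalg.eigvals(reduced.cR)).max())
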