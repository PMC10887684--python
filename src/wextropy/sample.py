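"""Validated container for positive lifetime samples."""

from __future__ import annotations

import numpy as np

from .exceptions import DomainError

__all__ = ["LifetimeSample"]


class LifetimeSample:
    """A univariate sample of strictly positive lifetimes.

    Values are stored in input order; :attr:`sorted_values` exposes the
    order statistics ``X_{1:n} <= ... <= X_{n:n}``.

    Parameters
    ----------
    values : array_like
        Finite, strictly positive observations (arbitrary time units).
    """

    def __init__(self, values) -> None:
        arr = np.atleast_1d(np.asarray(values, dtype=float))
        if arr.ndim != 1:
            raise DomainError("lifetime sample must be one-dimensional")
        if arr.size == 0:
            raise DomainError("lifetime sample must be non-empty")
        if not np.all(np.isfinite(arr)):
            raise DomainError("lifetime sample contains non-finite values")
        if np.any(arr <= 0):
            raise DomainError("lifetime sample contains non-positive values")
        self._values = arr.copy()
        self._values.setflags(write=False)
        self._sorted: np.ndarray | None = None

    @property
    def values(self) -> np.ndarray:
        """Observations in input order (read-only view)."""
        return self._values

    @property
    def n(self) -> int:
        """Sample size."""
        return self._values.size

    @property
    def sorted_values(self) -> np.ndarray:
        """Order statistics, non-decreasing (read-only, cached)."""
        if self._sorted is None:
            s = np.sort(self._values)
            s.setflags(write=False)
            self._sorted = s
        return self._sorted

    def __len__(self) -> int:
        return self.n

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"LifetimeSample(n={self.n}, min={self._values.min():.4g}, max={self._values.max():.4g})"


def as_sample(data) -> LifetimeSample:
    """Coerce an array or LifetimeSample into a LifetimeSample."""
    if isinstance(data, LifetimeSample):
        return data
    return LifetimeSample(data)
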