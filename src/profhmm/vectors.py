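"""Buffer-backed numeric vectors.

A :class:`NumericVector` owns a one-dimensional float array and hands
out zero-copy views: ``numpy.asarray(vec)`` and ``memoryview(vec.data)``
both alias the owner's storage, so mutations through a view are seen by
the owner and vice versa.
"""

from __future__ import annotations

from typing import Iterable, Iterator

import numpy as np

__all__ = ["NumericVector"]


class NumericVector:
    """A one-dimensional float vector exposing contiguous shared memory."""

    __slots__ = ("_values",)

    def __init__(self, values: Iterable[float], dtype=np.float64) -> None:
        arr = np.ascontiguousarray(values, dtype=dtype)
        if arr.ndim != 1:
            raise ValueError("NumericVector is one-dimensional")
        self._values = arr

    # -- zero-copy access ----------------------------------------------

    @property
    def values(self) -> np.ndarray:
        """The owned array itself (not a copy)."""
        return self._values

    @property
    def data(self) -> memoryview:
        """A writable contiguous memory view over the storage."""
        return self._values.data

    def __array__(self, dtype=None, copy=None):
        if dtype is None or dtype == self._values.dtype:
            return self._values
        return self._values.astype(dtype)

    # -- sequence protocol ---------------------------------------------

    def __len__(self) -> int:
        return int(self._values.shape[0])

    def __getitem__(self, idx):
        return self._values[idx]

    def __setitem__(self, idx, value) -> None:
        self._values[idx] = value

    def __iter__(self) -> Iterator[float]:
        return iter(self._values)

    def __repr__(self) -> str:
        return f"NumericVector({self._values.tolist()!r})"

    def __eq__(self, other) -> bool:
        if isinstance(other, NumericVector):
            return bool(np.array_equal(self._values, other._values))
        return NotImplemented
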