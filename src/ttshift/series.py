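"""The :class:`Series` container for regularly sampled time series.

A series is stored as a ``(n_features, n_time)`` float array. Univariate
series (the common case) have a single feature row and expose their values
as a flat vector through :meth:`Series.as_1d`. Multivariate series carry
feature identifiers so that statistics that match features across two
tables (e.g. the median per-feature correlation) can align them by ID.

Missing values are encoded as NaN. They are tolerated in a container (so
that gap filling can be applied) but rejected by the test engines.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import InsufficientDataError


@dataclass(frozen=True)
class Series:
    """A regularly sampled time series, univariate or feature-by-time.

    Parameters
    ----------
    values
        Array of shape ``(n,)`` or ``(n_features, n)``. Copied and cast to
        float64.
    label
        Free-text name used in reports and file headers.
    feature_ids
        Optional tuple of feature identifiers, one per row. Defaults to
        ``("f0", "f1", ...)`` for multivariate input and ``None`` for
        univariate input.
    """

    values: np.ndarray
    label: str = ""
    feature_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim == 1:
            arr = arr[np.newaxis, :]
        if arr.ndim != 2:
            raise ValueError("Series values must be 1-D or 2-D (features x time)")
        if arr.shape[1] < 1:
            raise InsufficientDataError("Series must contain at least one time point")
        object.__setattr__(self, "values", arr)
        if self.feature_ids is not None:
            ids = tuple(str(i) for i in self.feature_ids)
            if len(ids) != arr.shape[0]:
                raise ValueError(
                    f"{len(ids)} feature ids for {arr.shape[0]} feature rows"
                )
            object.__setattr__(self, "feature_ids", ids)
        elif arr.shape[0] > 1:
            object.__setattr__(
                self, "feature_ids", tuple(f"f{i}" for i in range(arr.shape[0]))
            )

    # -- basic geometry -------------------------------------------------
    @property
    def n(self) -> int:
        """Number of time points."""
        return self.values.shape[1]

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def is_univariate(self) -> bool:
        return self.values.shape[0] == 1

    def __len__(self) -> int:
        return self.n

    def as_1d(self) -> np.ndarray:
        """Return the values of a univariate series as a flat vector."""
        if not self.is_univariate:
            raise ValueError(f"Series {self.label!r} is multivariate")
        return self.values[0]

    # -- slicing and checks ---------------------------------------------
    def window(self, start: int, stop: int) -> "Series":
        """Sub-series over time indices ``start:stop`` (python slice bounds)."""
        if not (0 <= start < stop <= self.n):
            raise InsufficientDataError(
                f"window [{start}:{stop}] outside series of length {self.n}"
            )
        return replace(self, values=self.values[:, start:stop])

    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def require_complete(self) -> None:
        if self.has_missing():
            raise ValueError(
                f"Series {self.label!r} has missing values; apply gap_fill first"
            )

    def with_values(self, values: np.ndarray) -> "Series":
        return replace(self, values=values)
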