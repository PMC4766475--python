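"""Normalized N-dimensional return-map geometry for RR-interval series.

An RR record is a sequence of M beat-to-beat intervals.  The analysis embeds
it in an N-dimensional Poincare map and measures, for every window of N
consecutive beats, the vector distance from the (globally normalized) window
to the *identity line* ``{1, ..., 1} * t`` -- the locus of zero beat-to-beat
variability.  Two filtration levels are applied:

1.  *Circadian filtration*: the whole record is divided by its mean, so that
    the normalized series ``x`` has mean exactly 1 and the analysis becomes
    independent of the subject's average heart rate.
2.  *Local filtration*: the N-th order forward moving average ``<x>_i`` of
    each window is subtracted componentwise, yielding the globally normalized
    deviation vector ``Delta_i`` with components

        Delta_{i,k} = x_{i+k} - <x>_i,    k = 0..N-1.

    Dividing additionally by the local average gives the locally normalized
    field ``delta_{i,k} = Delta_{i,k} / <x>_i``.

Every Delta (and delta) row sums to zero by construction -- the *closure*
property -- so the field lives on a fixed (N-1)-dimensional hyperplane and
its true informative dimension is N-1.  ``truncate_for_graph`` drops the
redundant last component for plotting and angle computations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "RRSeries",
    "NormalizedSeries",
    "MovingAverageSeries",
    "DeltaField",
    "normalize_global",
    "moving_average",
    "delta_field",
    "truncate_for_graph",
]

#: post-hoc closure assertion tolerance (the formula closes analytically;
#: this catches implementation drift, not rounding of well-formed input)
CLOSURE_TOL = 1e-12

#: intervals with a median above this are taken to be milliseconds
_MS_DETECTION_MEDIAN = 10.0


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class RRSeries:
    """A raw beat-to-beat interval sequence, stored canonically in seconds.

    Parameters
    ----------
    intervals : array of float
        Strictly positive RR intervals in seconds.
    source_id : str
        Free-form provenance label (file name, record id, ...).
    unit_declared : {"seconds", "milliseconds", None}
        The unit the intervals were *supplied* in.  Use
        :meth:`RRSeries.from_values` to apply unit resolution; the stored
        array is always seconds.
    """

    intervals: np.ndarray
    source_id: str = ""
    unit_declared: str | None = "seconds"

    def __post_init__(self) -> None:
        arr = _as_float_array(self.intervals, "intervals")
        if arr.size == 0:
            raise ValueError("RR series is empty")
        bad = np.flatnonzero(arr <= 0)
        if bad.size:
            i = int(bad[0])
            raise ValueError(
                f"non-positive RR interval {arr[i]!r} at index {i + 1} (1-based)"
            )
        if arr.size < 2:
            raise ValueError("RR series must contain at least 2 intervals")
        object.__setattr__(self, "intervals", arr)

    @classmethod
    def from_values(
        cls,
        values,
        unit: str | None = None,
        source_id: str = "",
    ) -> "RRSeries":
        """Build an :class:`RRSeries`, resolving the unit to seconds.

        A declared ``unit`` ("seconds" or "milliseconds") is authoritative.
        With ``unit=None`` the unit is detected: a median interval above
        10 is read as milliseconds (human RR intervals are ~0.3-2 s).
        """
        arr = _as_float_array(values, "values")
        if unit is None:
            unit = "milliseconds" if np.median(arr) > _MS_DETECTION_MEDIAN else "seconds"
        if unit == "milliseconds":
            arr = arr / 1000.0
        elif unit != "seconds":
            raise ValueError(f"unknown unit {unit!r}")
        return cls(intervals=arr, source_id=source_id, unit_declared=unit)

    @property
    def M(self) -> int:
        """Number of beats (intervals) in the record."""
        return int(self.intervals.size)

    def capped(self, m_cap: int | None) -> "RRSeries":
        """First ``m_cap`` beats (the whole record if shorter or ``None``)."""
        if m_cap is None or m_cap >= self.M:
            return self
        if m_cap < 2:
            raise ValueError("m_cap must be at least 2")
        return RRSeries(
            intervals=self.intervals[:m_cap],
            source_id=self.source_id,
            unit_declared=self.unit_declared,
        )


@dataclass(frozen=True)
class NormalizedSeries:
    """Record divided by its global mean: dimensionless, mean exactly 1."""

    x: np.ndarray
    global_mean: float

    @property
    def M(self) -> int:
        return int(self.x.size)


@dataclass(frozen=True)
class MovingAverageSeries:
    """Forward moving averages ``<x>_i`` of a normalized series, order N."""

    avg: np.ndarray
    order: int

    @property
    def n_windows(self) -> int:
        return int(self.avg.size)


@dataclass(frozen=True)
class DeltaField:
    """(M - N + 1) x N matrix of per-window distance-to-identity-line vectors.

    ``normalization="global"`` holds the Delta field, ``"local"`` the delta
    field (Delta divided elementwise by the window average).  Rows sum to
    zero (closure); ``window_avg`` retains the moving averages used.
    """

    vectors: np.ndarray
    order: int
    normalization: str
    window_avg: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.normalization not in ("global", "local"):
            raise ValueError(
                f"normalization must be 'global' or 'local', got {self.normalization!r}"
            )
        resid = np.abs(self.vectors.sum(axis=1))
        if resid.size and float(resid.max()) > CLOSURE_TOL:
            raise AssertionError(
                f"closure violated: max |row sum| = {resid.max():.3e} > {CLOSURE_TOL:g}"
            )

    @property
    def n_windows(self) -> int:
        return int(self.vectors.shape[0])

    @property
    def M(self) -> int:
        """Length of the underlying record."""
        return self.n_windows + self.order - 1


def normalize_global(rr: RRSeries) -> NormalizedSeries:
    """Divide the record by its mean (circadian filtration level).

    Returns ``x_i = X_i / mean(X)``; ``mean(x) == 1`` to machine precision
    and the result is invariant under rescaling of the raw intervals.
    """
    mean = float(rr.intervals.mean())
    if np.all(rr.intervals == rr.intervals[0]):
        # a constant record normalizes to exactly ones (zero variability);
        # bypass division rounding so the Delta field is exactly zero
        return NormalizedSeries(x=np.ones(rr.M), global_mean=float(rr.intervals[0]))
    return NormalizedSeries(x=rr.intervals / mean, global_mean=mean)


def _check_order(order: int, m: int) -> None:
    if not isinstance(order, (int, np.integer)):
        raise TypeError(f"order must be an integer, got {order!r}")
    if order < 2:
        raise ValueError(f"order N must be >= 2, got {order}")
    if order > m:
        raise ValueError(f"order N={order} exceeds record length M={m}")


def moving_average(x: NormalizedSeries, order: int) -> MovingAverageSeries:
    """N-th order forward moving averages (local filtration level).

    ``avg[i] = mean(x[i:i+N])`` for i = 0 .. M-N, i.e. M - N + 1 windows.
    """
    _check_order(order, x.M)
    windows = sliding_window_view(x.x, order)
    return MovingAverageSeries(avg=windows.mean(axis=1), order=int(order))


def delta_field(
    x: NormalizedSeries, order: int, normalization: str = "global"
) -> DeltaField:
    """Per-window vector distances to the identity line.

    global : ``Delta_{i,k} = x_{i+k} - <x>_i``
    local  : ``delta_{i,k} = Delta_{i,k} / <x>_i``

    Each row sums to zero (closure); the field is the N-dimensional
    return-map representation of the record's variability.
    """
    ma = moving_average(x, order)
    windows = sliding_window_view(x.x, order)
    vectors = windows - ma.avg[:, None]
    if normalization == "local":
        vectors = vectors / ma.avg[:, None]
    return DeltaField(
        vectors=vectors,
        order=int(order),
        normalization=normalization,
        window_avg=ma.avg,
    )


def truncate_for_graph(field_: DeltaField) -> np.ndarray:
    """First N-1 components of each row (the informative dimensions).

    Closure makes the dropped last component recoverable as the negative
    sum of the kept ones.
    """
    return field_.vectors[:, :-1]
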