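"""Generalized-angle matching of Delta windows against catalog lines.

Whether a window realizes a catalog sequence is decided by the generalized
angle theta between its truncated Delta vector (first N-1 components; the
last is redundant by closure) and the truncated, renormalized line
direction:

    cos theta = (Delta_trunc . A_trunc) / (||Delta_trunc|| ||A_trunc||).

Matching is orientation-sensitive -- a line and its negation are distinct
physiological events -- and a window matches when theta falls below a
tolerance theta_tilde (equivalently cos theta >= cos theta_tilde; default
cos theta_tilde = 0.98).  The *presence* of a line in a record of M beats
is the percentage of beats covered by matched windows:

    presence = 100 * m * (N - 1) / (M - N),

with m the number of matched events.  A single isolated event produces
several near-matching overlapping windows, so by default a match at window
i suppresses windows i+1 .. i+N-1 for the same line, making m an event
count; the literal every-window count is available with
``suppress_overlap=False``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np

from .catalog import ArrhythmiaLine, default_catalog
from .geometry import DeltaField, RRSeries, delta_field, normalize_global, truncate_for_graph
from .variability import primary_variability

__all__ = [
    "MatchRecord",
    "PresenceResult",
    "SignatureVector",
    "CrossOrderError",
    "DEFAULT_COS_TOLERANCE",
    "QUIESCENCE_EPS",
    "tolerance_from_cos",
    "cos_theta",
    "presence",
    "signature",
    "signature_space_point",
]

#: default matching threshold on cos(theta)
DEFAULT_COS_TOLERANCE = 0.98
#: windows with truncated norm at or below this are numerically angle-free
QUIESCENCE_EPS = 1e-6


class CrossOrderError(ValueError):
    """Field order does not match the line's native order."""


def tolerance_from_cos(cos_threshold: float) -> float:
    """Angular tolerance (radians) equivalent to a cos(theta) threshold."""
    if not -1.0 <= cos_threshold <= 1.0:
        raise ValueError("cos threshold must lie in [-1, 1]")
    return math.acos(cos_threshold)


@dataclass(frozen=True)
class MatchRecord:
    """One matched window: 1-based index, line, angle cosine, amplitude t."""

    window_index: int
    line_name: str
    cos_theta: float
    amplitude: float
    window_norm: float

    def __post_init__(self) -> None:
        if abs(self.cos_theta) > 1 + 1e-12:
            raise ValueError(f"|cos theta| = {abs(self.cos_theta)} > 1")


@dataclass(frozen=True)
class PresenceResult:
    line_name: str
    m: int
    presence_percent: float
    tolerance: float  # max angle, radians
    M: int
    N: int
    matches: list = dc_field(default_factory=list, repr=False)


@dataclass(frozen=True)
class SignatureVector:
    """Per-record presences (report row order) plus the primary variability."""

    presences: dict
    phi: float
    N: int
    M_used: int


def cos_theta(window: np.ndarray, line: ArrhythmiaLine, eps: float = QUIESCENCE_EPS) -> float:
    """Generalized-angle cosine between a truncated Delta window and a line.

    ``window`` must already be truncated to N-1 components.  Quiescent
    windows (norm <= eps) have no meaningful direction and are rejected.
    """
    w = np.asarray(window, dtype=float)
    u = line.truncated_unit()
    if w.size != u.size:
        raise CrossOrderError(
            f"window has {w.size + 1} components but line {line.name} has order "
            f"{line.order}; rebuild the field at the line's native order"
        )
    nrm = float(np.linalg.norm(w))
    if nrm <= eps:
        raise ValueError(
            f"quiescent window (norm {nrm:.3e} <= eps {eps:g}): angle undefined"
        )
    return float(w @ u) / nrm


def presence(
    field: DeltaField,
    line: ArrhythmiaLine,
    tolerance: float | None = None,
    cos_tolerance: float | None = None,
    suppress_overlap: bool = True,
    eps: float = QUIESCENCE_EPS,
    min_amplitude: float = 0.0,
) -> PresenceResult:
    """Presence percentage of one catalog line in a Delta field.

    Exactly one of ``tolerance`` (max angle, radians) or ``cos_tolerance``
    may be given; the default is cos theta_tilde = 0.98.  Procedure: the
    angle is measured around each window, windows with theta below the
    tolerance are counted (with optional overlap suppression), and the
    count is converted to the percent of beats covered,
    ``100 * m * (N-1) / (M-N)``.
    """
    if field.order != line.order:
        raise CrossOrderError(
            f"field has order {field.order} but line {line.name} has native order "
            f"{line.order}; rebuild the field at the line's order"
        )
    if tolerance is None and cos_tolerance is None:
        cos_tolerance = DEFAULT_COS_TOLERANCE
    if tolerance is not None:
        if cos_tolerance is not None:
            raise ValueError("give either tolerance (radians) or cos_tolerance, not both")
        if not 0.0 < tolerance < math.pi:
            raise ValueError("tolerance must lie in (0, pi) radians")
        cos_tolerance = math.cos(tolerance)
    else:
        tolerance = math.acos(cos_tolerance)

    n = field.order
    M = field.M
    if M <= n:
        raise ValueError(f"presence undefined for M <= N (M={M}, N={n})")

    T = truncate_for_graph(field)
    norms = np.linalg.norm(T, axis=1)
    u = line.truncated_unit()
    amplitudes = T @ u
    evaluable = norms > eps
    cosines = np.full(norms.shape, np.nan)
    np.divide(amplitudes, norms, out=cosines, where=evaluable)

    matched = evaluable & (cosines >= cos_tolerance)
    if min_amplitude > 0:
        matched &= np.abs(amplitudes) >= min_amplitude

    idx = np.flatnonzero(matched)
    if suppress_overlap and idx.size:
        kept = []
        next_free = -1
        for i in idx:
            if i >= next_free:
                kept.append(i)
                next_free = i + n  # windows i+1 .. i+N-1 are ineligible
        idx = np.asarray(kept, dtype=int)

    matches = [
        MatchRecord(
            window_index=int(i) + 1,
            line_name=line.name,
            cos_theta=float(cosines[i]),
            amplitude=float(amplitudes[i]),
            window_norm=float(norms[i]),
        )
        for i in idx
    ]
    m = len(matches)
    return PresenceResult(
        line_name=line.name,
        m=m,
        presence_percent=100.0 * m * (n - 1) / (M - n),
        tolerance=float(tolerance),
        M=M,
        N=n,
        matches=matches,
    )


def signature(
    rr: RRSeries,
    order: int = 5,
    cos_tolerance: float = DEFAULT_COS_TOLERANCE,
    m_cap: int | None = None,
    suppress_overlap: bool = True,
    b2_order_policy: str = "native",
    scale_factor: float = 100.0,
    eps: float = QUIESCENCE_EPS,
    min_amplitude: float = 0.0,
    collect_matches: bool = False,
) -> tuple[SignatureVector, list[PresenceResult]]:
    """Full per-record signature: catalog presences plus Phi_N.

    B2 is evaluated at its native order (N+1) on a second field built from
    the same record under ``b2_order_policy="native"`` (the default);
    ``"fragments"`` evaluates the order-N fragments instead and reports
    their summed presence under "B2".  Returns the signature and the
    per-line :class:`PresenceResult` detail.
    """
    rr = rr.capped(m_cap)
    min_m = 2 * max(order, order + 1 if b2_order_policy == "native" else order)
    if rr.M < min_m:
        raise ValueError(
            f"record too short for an order-{order} signature: need at least "
            f"{min_m} beats, got {rr.M}"
        )
    x = normalize_global(rr)
    base_field = delta_field(x, order, "global")
    results: list[PresenceResult] = []

    def run(line: ArrhythmiaLine, fld: DeltaField) -> PresenceResult:
        return presence(
            fld,
            line,
            cos_tolerance=cos_tolerance,
            suppress_overlap=suppress_overlap,
            eps=eps,
            min_amplitude=min_amplitude,
        )

    catalog = default_catalog(order, b2_order_policy="native")  # row order; B2 handled below
    presences: dict[str, float] = {}
    for line in catalog[:-1]:  # A1+, A1-, A2+, A2-, B1 at the base order
        res = run(line, base_field)
        results.append(res)
        presences[line.name] = res.presence_percent

    if b2_order_policy == "native":
        b2_line = catalog[-1]
        b2_field = delta_field(x, b2_line.order, "global")
        res = run(b2_line, b2_field)
        results.append(res)
        presences["B2"] = res.presence_percent
    elif b2_order_policy == "fragments":
        from .catalog import b2_fragments

        total = 0.0
        for frag in b2_fragments(order - 1):
            res = run(frag, base_field)
            results.append(res)
            total += res.presence_percent
        presences["B2"] = total
    else:
        raise ValueError(f"unknown b2_order_policy {b2_order_policy!r}")

    pv = primary_variability(base_field, scale_factor=scale_factor)
    sig = SignatureVector(presences=presences, phi=pv.phi, N=order, M_used=rr.M)
    if not collect_matches:
        results = [
            PresenceResult(
                line_name=r.line_name,
                m=r.m,
                presence_percent=r.presence_percent,
                tolerance=r.tolerance,
                M=r.M,
                N=r.N,
                matches=[],
            )
            for r in results
        ]
    return sig, results


def signature_space_point(sig: SignatureVector) -> tuple[float, float, float]:
    """The (presence A1+, presence B1, Phi) point used for cohort scatter."""
    return (sig.presences["A1+"], sig.presences["B1"], sig.phi)
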