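"""Universal arrhythmic line sequences as unit directions in Delta space.

Each catalog entry is a *line* ``A * t`` through the origin of the order-N
Delta field, parametrized by an amplitude t; a window whose Delta vector
sits (to within an angular tolerance) on such a line realizes the
corresponding beat sequence regardless of heart rate or variability
strength.  The families:

A1+/A1-   zero-mean linear ramp: regular acceleration (+, RR intervals
          shrinking across the window) or deceleration (-) of the beat
          rate; the basic adaptability mode of a healthy heart.
A2+/A2-   full-period sinusoidal modulation over N beats; the
          breath-coupled mode (respiratory sinus arrhythmia), sub-dominant
          in healthy subjects.
B1        compensated, isolated ectopic beat: a premature beat (-1)
          immediately followed by a compensatory pause (+1), flanked by
          quiet beats.  Dominant in heart failure.
B2 family (m, -1 x m, 0) at order m+2: a noticeable pause followed by a
          proportional run of m faster beats that exactly compensate it
          (regular paroxysmal tachycardia).  The canonical member m=4
          lives in the sixth-order section.
B3_{m,i}  the pause displaced to interior position i of the compensating
          run -- an intermediate form joining two subsequent
          pause-tachycardia sequences.
SHADOW    two-level step directions traced by windows that only partially
          overlap a B2 event; they accompany B2 lines in the graph.

A direction is *compensated* when its components sum to zero (every
realizable Delta row is, by closure) and *terminated* when its last
component is zero (the window's final beat matches the local average).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "ArrhythmiaLine",
    "make_a1",
    "make_a2",
    "make_b1",
    "make_b1_split",
    "make_b2",
    "make_b2_family",
    "b2_fragments",
    "make_b3",
    "make_shadow",
    "default_catalog",
    "catalog_to_json",
    "catalog_from_json",
]

_UNIT_TOL = 1e-12


@dataclass(frozen=True)
class ArrhythmiaLine:
    """A named, order-N, unit-norm line direction in Delta space."""

    name: str
    order: int
    direction: np.ndarray
    compensated: bool
    terminated: bool
    family_index: int | None = None
    position_index: int | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        if d.ndim != 1 or d.size != self.order:
            raise ValueError(
                f"direction must have length order={self.order}, got shape {d.shape}"
            )
        nrm = float(np.linalg.norm(d))
        if nrm == 0:
            raise ValueError("direction cannot be the zero vector")
        if abs(nrm - 1.0) > _UNIT_TOL:
            d = d / nrm
        object.__setattr__(self, "direction", d)
        if self.compensated and abs(float(d.sum())) > 1e-10:
            raise ValueError(f"line {self.name}: compensated but components sum to {d.sum():.3e}")
        if self.terminated and abs(float(d[-1])) > 1e-10:
            raise ValueError(f"line {self.name}: terminated but last component is {d[-1]:.3e}")

    def truncated_unit(self) -> np.ndarray:
        """First N-1 components, renormalized (for generalized-angle matching)."""
        t = self.direction[:-1]
        nrm = float(np.linalg.norm(t))
        if nrm == 0:
            raise ValueError(f"line {self.name}: truncated direction is zero")
        return t / nrm

    def negated(self, name: str | None = None) -> "ArrhythmiaLine":
        return ArrhythmiaLine(
            name=name if name is not None else f"-{self.name}",
            order=self.order,
            direction=-self.direction,
            compensated=self.compensated,
            terminated=self.terminated,
            family_index=self.family_index,
            position_index=self.position_index,
        )


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def make_a1(order: int, sign: str = "+") -> ArrhythmiaLine:
    """Zero-mean linear ramp; "+" = accelerating beat rate (RR shrinking)."""
    if order < 2:
        raise ValueError("A1 requires N >= 2")
    if sign not in ("+", "-"):
        raise ValueError(f"sign must be '+' or '-', got {sign!r}")
    ramp = np.arange(order - 1, -order, -2, dtype=float)  # (N-1, N-3, ..., -(N-1))
    if sign == "-":
        ramp = -ramp
    return ArrhythmiaLine(
        name=f"A1{sign}",
        order=order,
        direction=_unit(ramp),
        compensated=True,
        terminated=False,
    )


def make_a2(order: int, sign: str = "+", phase: float = 0.0) -> ArrhythmiaLine:
    """Full-period sinusoid over N beats; zero-sum for any phase."""
    if order < 3:
        raise ValueError("A2 requires N >= 3 (the sinusoid degenerates below)")
    if sign not in ("+", "-"):
        raise ValueError(f"sign must be '+' or '-', got {sign!r}")
    k = np.arange(order, dtype=float)
    wave = np.sin(2.0 * np.pi * k / order + phase)
    # a sampled full period sums to zero analytically; remove rounding dust
    wave = wave - wave.mean()
    if sign == "-":
        wave = -wave
    return ArrhythmiaLine(
        name=f"A2{sign}",
        order=order,
        direction=_unit(wave),
        compensated=True,
        terminated=abs(wave[-1]) < 1e-15,
    )


def make_b1(order: int, position: int | None = None) -> ArrhythmiaLine:
    """Compensated ectopic beat: -1 at ``position``, +1 right after.

    ``position`` defaults to N-3, the canonical interior pair for N=5
    (the direction (0, 0, -1, 1, 0)).  Valid positions keep the pair fully
    interior, 0 <= position <= N-3, so that the sequence is terminated.
    """
    if order < 3:
        raise ValueError("B1 requires N >= 3")
    if position is None:
        position = order - 3
    if not 0 <= position <= order - 3:
        raise ValueError(
            f"B1 position must be in [0, {order - 3}] for N={order}, got {position}"
        )
    d = np.zeros(order)
    d[position] = -1.0
    d[position + 1] = 1.0
    name = "B1" if position == order - 3 else f"B1_p{position}"
    return ArrhythmiaLine(
        name=name,
        order=order,
        direction=_unit(d),
        compensated=True,
        terminated=position + 1 < order - 1,
        position_index=position,
    )


def make_b1_split(order: int) -> ArrhythmiaLine:
    """The (1, 0, ..., 0, -1) variant with the pair split to the window ends.

    Kept constructible for completeness but excluded from the default
    signature: in real records more than two quiet beats surround an
    ectopic pair, so this line does not clearly appear.
    """
    if order < 3:
        raise ValueError("B1_split requires N >= 3")
    d = np.zeros(order)
    d[0] = 1.0
    d[-1] = -1.0
    return ArrhythmiaLine(
        name="B1_split",
        order=order,
        direction=_unit(d),
        compensated=True,
        terminated=False,
    )


def make_b2_family(m: int) -> ArrhythmiaLine:
    """Pause-plus-run member m at its native order m+2: (m, -1 x m, 0)."""
    if m < 2:
        raise ValueError("B2 family requires m >= 2")
    order = m + 2
    d = np.concatenate(([float(m)], -np.ones(m), [0.0]))
    name = "B2" if m == 4 else f"B2_{m}"
    return ArrhythmiaLine(
        name=name,
        order=order,
        direction=_unit(d),
        compensated=True,
        terminated=True,
        family_index=m,
    )


def make_b2(order: int = 6) -> ArrhythmiaLine:
    """The B2 member whose native order is ``order`` (canonical: order 6, m=4)."""
    if order < 4:
        raise ValueError("B2 requires order >= 4 (m >= 2)")
    return make_b2_family(order - 2)


def b2_fragments(m: int = 4) -> list[ArrhythmiaLine]:
    """Sub-native-order fragments of a B2 event, at order m+1.

    Windows of order m+1 sliding over a (pause, m fast beats) event cannot
    contain the whole compensated sequence; the two dominant Delta
    directions they trace are returned (named B2_1, B2_2).  These are the
    fifth-order lines that accompany the canonical m=4 event when the
    analysis is run at N=5.
    """
    if m < 3:
        raise ValueError("fragments need m >= 3")
    order = m + 1
    # event deviations on a flat unit baseline
    event = np.concatenate(([float(m)], -np.ones(m), [0.0]))
    out = []
    for j, offset in enumerate((0, 1), start=1):
        w = event[offset : offset + order]
        d = w - w.mean()
        out.append(
            ArrhythmiaLine(
                name=f"B2_{j}",
                order=order,
                direction=_unit(d),
                compensated=True,
                terminated=abs(d[-1] - 0.0) < 1e-12,
                family_index=m,
                position_index=offset,
            )
        )
    return out


def make_b3(m: int, i: int) -> ArrhythmiaLine:
    """Pause displaced to interior position ``i`` of the compensating run.

    Order m+2 direction with component m at position i (1 <= i <= m), -1
    at the other m leading positions, and a terminating 0.  i = 0 would
    reproduce B2 itself and is rejected.
    """
    if m < 2:
        raise ValueError("B3 requires m >= 2")
    if not 1 <= i <= m:
        raise ValueError(f"B3 position i must be in [1, {m}] for m={m}, got {i}")
    d = -np.ones(m + 2)
    d[i] = float(m)
    d[-1] = 0.0
    return ArrhythmiaLine(
        name=f"B3_{m}_{i}",
        order=m + 2,
        direction=_unit(d),
        compensated=True,
        terminated=True,
        family_index=m,
        position_index=i,
    )


def make_shadow(m: int, i: int) -> ArrhythmiaLine:
    """Shadow of a B2 event: the partial-overlap window direction.

    A window of the native order m+2 that starts i beats after the pause of
    a B2 event sees the tail of the fast run followed by recovered normal
    beats; its Delta row is the two-level step with m+1-i components equal
    to -(i+1) followed by i+1 components equal to m+1-i.  These directions
    appear alongside B2 lines whenever pause-tachycardia events are present
    and are complementary to the B3 family.
    """
    if m < 2:
        raise ValueError("shadow requires m >= 2")
    if not 1 <= i <= m:
        raise ValueError(f"shadow position i must be in [1, {m}] for m={m}, got {i}")
    d = np.concatenate(
        (np.full(m + 1 - i, -(i + 1.0)), np.full(i + 1, float(m + 1 - i)))
    )
    return ArrhythmiaLine(
        name=f"SHADOW_{m}_{i}",
        order=m + 2,
        direction=_unit(d),
        compensated=True,
        terminated=False,
        family_index=m,
        position_index=i,
    )


def default_catalog(order: int = 5, b2_order_policy: str = "native") -> list[ArrhythmiaLine]:
    """The signature line set, in report row order.

    For the canonical order 5: A1+, A1-, A2+, A2-, B1 (canonical interior
    position), B2.  B2 is included at its native order N+1 (a cross-order
    entry, the compensated form of the pause-tachycardia run) unless
    ``b2_order_policy="fragments"`` selects the order-N fragments instead.
    """
    if b2_order_policy not in ("native", "fragments"):
        raise ValueError(f"unknown b2_order_policy {b2_order_policy!r}")
    lines = [
        make_a1(order, "+"),
        make_a1(order, "-"),
        make_a2(order, "+"),
        make_a2(order, "-"),
        make_b1(order),
    ]
    if b2_order_policy == "native":
        lines.append(make_b2_family(order - 1))
    else:
        lines.extend(b2_fragments(order - 1))
    return lines


def catalog_to_json(lines: list[ArrhythmiaLine], path) -> None:
    """Serialize a catalog so alternative transcriptions can be swapped in."""
    payload = [
        {
            "name": ln.name,
            "order": ln.order,
            "direction": [float(v) for v in ln.direction],
            "compensated": bool(ln.compensated),
            "terminated": bool(ln.terminated),
            "family_index": None if ln.family_index is None else int(ln.family_index),
            "position_index": None if ln.position_index is None else int(ln.position_index),
        }
        for ln in lines
    ]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def catalog_from_json(path) -> list[ArrhythmiaLine]:
    payload = json.loads(Path(path).read_text())
    return [
        ArrhythmiaLine(
            name=e["name"],
            order=int(e["order"]),
            direction=np.asarray(e["direction"], dtype=float),
            compensated=bool(e["compensated"]),
            terminated=bool(e["terminated"]),
            family_index=e.get("family_index"),
            position_index=e.get("position_index"),
        )
        for e in payload
    ]
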