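"""Seeded synthetic RR-interval generator with injected catalog events.

The baseline emulates a sinus-rhythm record: a constant mean interval
modulated by (i) an AR(1)-correlated multiplicative noise (short-range
correlated sinus variability) and (ii) a sinusoidal respiratory modulation
with a near-period-5 beat period (default 5.1 beats, deliberately
incommensurate with the canonical analysis order N=5 so the strided phase
drifts).  Arrhythmic events *overwrite* their beats with zero-sum template
patterns scaled by an amplitude a, so that on a noise-free baseline the
covering window's Delta row lies exactly on the corresponding catalog line
and recovery tests are exact:

ramp+/ramp-    A1 linear ramp over ``length`` beats (deviations
               a * (L-1, L-3, ..., -(L-1)) / 2).
ectopic_pair   B1: RR_j -> RR*(1-a), RR_{j+1} -> RR*(1+a).
pause_tachy    B2 family: pause a*m then m beats at -a (``length`` = m).
sinus_burst    A2: one full sine period over ``length`` beats.

``generate`` returns the series plus a ground-truth log (kind, index,
amplitude, matched catalog line and its native order) consumed by the
recovery tests and the CLI.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .geometry import RRSeries

__all__ = ["EventSpec", "SynthSpec", "event_template", "generate", "scenario_presets"]

_EVENT_KINDS = ("ramp+", "ramp-", "ectopic_pair", "pause_tachy", "sinus_burst")


@dataclass(frozen=True)
class EventSpec:
    """One injected arrhythmic event.

    ``beat_index`` is the 0-based index of the event's first beat;
    ``length`` is the template length L (for ``pause_tachy`` it is the run
    length m, footprint m+1 beats).  ``amplitude`` is the fractional
    deviation a.
    """

    kind: str
    beat_index: int
    amplitude: float = 0.2
    length: int = 5

    def __post_init__(self) -> None:
        if self.kind not in _EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}; one of {_EVENT_KINDS}")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.beat_index < 0:
            raise ValueError("beat_index must be non-negative")

    @property
    def footprint(self) -> int:
        """Number of beats the template overwrites."""
        if self.kind == "ectopic_pair":
            return 2
        if self.kind == "pause_tachy":
            return self.length + 1
        return self.length

    @property
    def line_name(self) -> str:
        return {
            "ramp+": "A1+",
            "ramp-": "A1-",
            "ectopic_pair": "B1",
            "pause_tachy": "B2" if self.length == 4 else f"B2_{self.length}",
            "sinus_burst": "A2+",
        }[self.kind]

    @property
    def native_order(self) -> int:
        """Window order at which the event sits exactly on its line."""
        if self.kind == "ectopic_pair":
            return 5  # canonical interior position in an order-5 window
        if self.kind == "pause_tachy":
            return self.length + 2
        return self.length


def event_template(ev: EventSpec) -> np.ndarray:
    """Zero-sum fractional deviations the event writes onto its beats."""
    a, L = ev.amplitude, ev.length
    if ev.kind in ("ramp+", "ramp-"):
        ramp = np.arange(L - 1, -L, -2, dtype=float) / 2.0
        return a * ramp if ev.kind == "ramp+" else -a * ramp
    if ev.kind == "ectopic_pair":
        return np.array([-a, a])
    if ev.kind == "pause_tachy":
        return a * np.concatenate(([float(L)], -np.ones(L)))
    if ev.kind == "sinus_burst":
        wave = np.sin(2.0 * np.pi * np.arange(L) / L)
        return a * (wave - wave.mean())
    raise AssertionError(ev.kind)


@dataclass(frozen=True)
class SynthSpec:
    """Full description of a synthetic record; deterministic given ``seed``."""

    M: int = 3000
    mean_rr: float = 0.8
    noise_sd: float = 0.03
    ar_coefficient: float = 0.8
    resp_amplitude: float = 0.025
    resp_period_beats: float = 5.1
    events: tuple = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.M < 2:
            raise ValueError("M must be >= 2")
        if self.mean_rr <= 0:
            raise ValueError("mean_rr must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.ar_coefficient < 1:
            raise ValueError("ar_coefficient must lie in [0, 1)")
        if self.resp_amplitude < 0:
            raise ValueError("resp_amplitude must be >= 0")
        if self.resp_period_beats <= 2:
            raise ValueError("resp_period_beats must exceed 2")
        object.__setattr__(self, "events", tuple(self.events))
        for ev in self.events:
            if not isinstance(ev, EventSpec):
                raise TypeError("events must be EventSpec instances")
            if ev.beat_index + ev.footprint + 1 > self.M:
                raise ValueError(
                    f"event {ev.kind} at beat {ev.beat_index} (footprint "
                    f"{ev.footprint}) runs past the record end M={self.M} "
                    "(one trailing normal beat is required)"
                )

    def to_json(self) -> str:
        d = asdict(self)
        d["events"] = [asdict(ev) for ev in self.events]
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SynthSpec":
        d = json.loads(text)
        d["events"] = tuple(EventSpec(**ev) for ev in d.get("events", ()))
        return cls(**d)


def generate(
    spec: SynthSpec, min_spacing: int | None = None
) -> tuple[RRSeries, list[dict]]:
    """Generate the RR series and the ground-truth event log.

    With ``min_spacing`` given, event start indices must be at least that
    many beats apart (recovery tests request >= 2N to keep matched windows
    non-overlapping); violations raise rather than silently merge.
    """
    if min_spacing is not None:
        starts = sorted(ev.beat_index for ev in spec.events)
        for a, b in zip(starts, starts[1:]):
            if b - a < min_spacing:
                raise ValueError(
                    f"events at beats {a} and {b} closer than the requested "
                    f"minimum spacing {min_spacing}"
                )
    rng = np.random.default_rng(spec.seed)
    i = np.arange(spec.M)
    resp = spec.resp_amplitude * np.sin(2.0 * np.pi * i / spec.resp_period_beats)
    if spec.noise_sd > 0:
        phi = spec.ar_coefficient
        innov = rng.normal(0.0, spec.noise_sd * np.sqrt(1.0 - phi * phi), size=spec.M)
        noise = np.empty(spec.M)
        noise[0] = rng.normal(0.0, spec.noise_sd)
        for k in range(1, spec.M):  # AR(1) with stationary sd = noise_sd
            noise[k] = phi * noise[k - 1] + innov[k]
    else:
        noise = np.zeros(spec.M)
    frac = noise + resp
    log: list[dict] = []
    for ev in spec.events:
        tpl = event_template(ev)
        frac[ev.beat_index : ev.beat_index + tpl.size] = tpl
        # keep the beat after the event quiet so terminated templates close
        frac[ev.beat_index + tpl.size] = 0.0
        log.append(
            {
                "kind": ev.kind,
                "index": int(ev.beat_index),
                "amplitude": float(ev.amplitude),
                "length": int(ev.length),
                "line_name": ev.line_name,
                "order": int(ev.native_order),
            }
        )
    rr = RRSeries(
        intervals=spec.mean_rr * (1.0 + frac),
        source_id=f"synthetic(seed={spec.seed})",
        unit_declared="seconds",
    )
    return rr, log


def _place_events(
    rng: np.random.Generator,
    M: int,
    kinds_and_rates: list[tuple[str, float, float, int]],
    spacing: int = 12,
) -> tuple:
    """Lay events of several kinds at jittered positions, non-overlapping."""
    events = []
    taken: list[tuple[int, int]] = []
    for kind, rate, amplitude, length in kinds_and_rates:
        count = int(round(rate * M))
        for _ in range(count):
            for _attempt in range(50):
                start = int(rng.integers(spacing, M - spacing - length - 2))
                if all(abs(start - s) >= spacing + f for s, f in taken):
                    ev = EventSpec(kind=kind, beat_index=start, amplitude=amplitude, length=length)
                    events.append(ev)
                    taken.append((start, ev.footprint))
                    break
    return tuple(sorted(events, key=lambda e: e.beat_index))


def scenario_presets(seed: int = 0, M: int = 3000) -> dict[str, SynthSpec]:
    """Three named study conditions with planted event statistics.

    nsr_like  ramp (A1) events dominate, ectopic beats rare; moderate
              correlated noise and visible respiratory modulation.
    hf_like   ectopic pairs (B1) and pause-tachycardia runs (B2) dominate,
              ramps rare, respiratory modulation depressed.
    sd_like   few ectopics but strong, long-correlated noise: large
              primary variability with modest B1 presence.
    """
    rng = np.random.default_rng(seed)
    nsr = SynthSpec(
        M=M,
        noise_sd=0.025,
        ar_coefficient=0.8,
        resp_amplitude=0.025,
        events=_place_events(
            rng,
            M,
            [
                ("ramp+", 1 / 250, 0.18, 5),
                ("ramp-", 1 / 350, 0.18, 5),
                ("sinus_burst", 1 / 500, 0.15, 5),
                ("ectopic_pair", 1 / 1500, 0.25, 2),
            ],
        ),
        seed=int(rng.integers(2**31)),
    )
    hf = SynthSpec(
        M=M,
        noise_sd=0.035,
        ar_coefficient=0.5,
        resp_amplitude=0.005,
        events=_place_events(
            rng,
            M,
            [
                ("ectopic_pair", 1 / 60, 0.3, 2),
                ("pause_tachy", 1 / 250, 0.15, 4),
                ("ramp+", 1 / 1500, 0.15, 5),
            ],
        ),
        seed=int(rng.integers(2**31)),
    )
    sd = SynthSpec(
        M=M,
        noise_sd=0.07,
        ar_coefficient=0.95,
        resp_amplitude=0.005,
        events=_place_events(
            rng,
            M,
            [
                ("ectopic_pair", 1 / 400, 0.3, 2),
                ("pause_tachy", 1 / 600, 0.2, 4),
            ],
        ),
        seed=int(rng.integers(2**31)),
    )
    return {"nsr_like": nsr, "hf_like": hf, "sd_like": sd}
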