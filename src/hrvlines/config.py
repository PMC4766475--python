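"""Run configuration shared by the CLI and scripted pipelines."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict


@dataclass(frozen=True)
class RunConfig:
    """Validated knobs for a full analysis run.

    ``tolerance_cos`` is the matching threshold on cos(theta);
    ``max_beats=4200`` mirrors the standardized record length used for
    cohort-comparable Phi values.  ``b2_order_policy`` chooses whether B2
    is evaluated at its native sixth order ("native", default) or through
    its order-N fragments ("fragments").
    """

    order: int = 5
    tolerance_cos: float = 0.98
    max_beats: int | None = None
    suppress_overlap: bool = True
    b2_order_policy: str = "native"
    scale_factor: float = 100.0
    seed: int = 0
    output_dir: str = "hrvlines_out"

    def __post_init__(self) -> None:
        if self.order < 2:
            raise ValueError("order must be >= 2")
        if not -1.0 < self.tolerance_cos < 1.0:
            raise ValueError("tolerance_cos must lie in (-1, 1)")
        if self.max_beats is not None and self.max_beats < 2 * (self.order + 1):
            raise ValueError("max_beats too small for the requested order")
        if self.b2_order_policy not in ("native", "fragments"):
            raise ValueError("b2_order_policy must be 'native' or 'fragments'")
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")

    @property
    def tolerance_radians(self) -> float:
        return math.acos(self.tolerance_cos)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)
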