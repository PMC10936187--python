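"""Shared result container for consumer uptake, used by both engines."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

ENGINES = ("analytic", "fd", "fd_extrapolated")


@dataclass(frozen=True)
class UptakeResult:
    """Consumer uptake of one scenario.

    ``absolute_uptake`` is the surface-integrated diffusive flux into the
    consumer sphere in relative-concentration units (D * um * conc);
    ``volume_normalized_uptake`` divides it by the consumer cell volume
    (4/3 pi r^3), reflecting that resource requirements scale with cell size.
    """

    absolute_uptake: float
    volume_normalized_uptake: float
    engine: str
    scenario_id: str
    converged: bool = True
    iterations: int = 0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.engine not in ENGINES:
            raise ValueError(f"unknown engine tag {self.engine!r}; expected one of {ENGINES}")
        if self.converged and not self.absolute_uptake > 0.0:
            raise ValueError("converged uptake must be strictly positive")
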