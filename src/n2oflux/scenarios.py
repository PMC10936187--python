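"""Scenario geometry and parameter sweeps for the two-cell diffusion model.

A scenario is one producer/consumer geometry: a producing sphere of radius
``R`` held at relative concentration 1, a consuming sphere of radius ``r``
held at 0, separated by a surface-to-surface gap ``d``, inside a cubic
domain whose boundary is also held at 0.  All lengths are micrometres; the
diffusion coefficient is relative (default 1) because only relative uptake
rates are ever reported.

The default sweep is a full cross-combination of five consumer radii, four
producer radii and five gaps (100 scenarios, 20 size combinations per gap).
The exact grid values of the original study are not published, so the
default is a documented reconstruction constrained by the published facts
(100 scenarios, 20 per gap, gaps spanning 0-2 um including 0.1 um,
consumer-to-producer radius ratios spanning roughly 0.1 to 1, producer
radii spanning a threefold range); it is tagged ``default-reconstruction``
and fully overridable through :func:`build_custom_sweep` or a config file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

DEFAULT_DOMAIN_SIDE = 20.0
DEFAULT_CONSUMER_RADII = (0.05, 0.1, 0.2, 0.35, 0.5)
DEFAULT_PRODUCER_RADII = (0.5, 0.75, 1.0, 1.5)
DEFAULT_GAPS = (0.0, 0.1, 0.5, 1.0, 2.0)


class ScenarioError(ValueError):
    """Raised when a scenario violates its geometric invariants."""


@dataclass(frozen=True)
class Scenario:
    """Geometry and boundary conditions of one producer/consumer simulation."""

    producer_radius: float
    consumer_radius: float
    gap: float
    domain_side: float = DEFAULT_DOMAIN_SIDE
    diffusivity: float = 1.0
    producer_surface_conc: float = 1.0
    consumer_surface_conc: float = 0.0
    boundary_conc: float = 0.0
    scenario_id: str = ""

    def __post_init__(self) -> None:
        if not self.producer_radius > 0:
            raise ScenarioError(f"producer_radius must be > 0, got {self.producer_radius}")
        if not self.consumer_radius > 0:
            raise ScenarioError(f"consumer_radius must be > 0, got {self.consumer_radius}")
        if self.gap < 0:
            raise ScenarioError(f"gap must be >= 0, got {self.gap}")
        if not self.diffusivity > 0:
            raise ScenarioError(f"diffusivity must be > 0, got {self.diffusivity}")
        R, r, d = self.producer_radius, self.consumer_radius, self.gap
        if not R + r + d + max(R, r) < self.domain_side / 2:
            raise ScenarioError(
                f"spheres do not fit in the domain with clearance: "
                f"R={R}, r={r}, d={d}, domain_side={self.domain_side} "
                f"(require R + r + d + max(R, r) < side/2)"
            )
        if not self.scenario_id:
            object.__setattr__(self, "scenario_id", f"R{R:g}_r{r:g}_d{d:g}")

    @property
    def center_distance(self) -> float:
        """Center-to-center distance L = R + r + d."""
        return self.producer_radius + self.consumer_radius + self.gap

    @property
    def radius_ratio(self) -> float:
        """Consumer-to-producer radius ratio r/R."""
        return self.consumer_radius / self.producer_radius

    @property
    def consumer_volume(self) -> float:
        return (4.0 / 3.0) * math.pi * self.consumer_radius**3

    def centers(self) -> tuple[tuple[float, float, float], tuple[float, float, float]]:
        """Sphere centers in domain coordinates ([0, side]^3).

        The cells sit on the horizontal (x) axis, symmetric about the domain
        center; producer first.
        """
        half = self.domain_side / 2.0
        L = self.center_distance
        return (half - L / 2.0, half, half), (half + L / 2.0, half, half)

    def with_gap(self, gap: float) -> "Scenario":
        return replace(self, gap=gap, scenario_id="")


@dataclass(frozen=True)
class SweepGrid:
    """Full cross-combination of consumer radii, producer radii and gaps."""

    scenarios: tuple[Scenario, ...]
    consumer_radii: tuple[float, ...]
    producer_radii: tuple[float, ...]
    gaps: tuple[float, ...]
    domain_side: float = DEFAULT_DOMAIN_SIDE
    provenance: str = "custom"

    def __post_init__(self) -> None:
        expected = len(self.consumer_radii) * len(self.producer_radii) * len(self.gaps)
        if len(self.scenarios) != expected:
            raise ScenarioError(
                f"sweep is not a full cross-product: {len(self.scenarios)} scenarios, "
                f"expected {expected}"
            )

    def __len__(self) -> int:
        return len(self.scenarios)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scenario_id": [s.scenario_id for s in self.scenarios],
                "producer_radius_um": [s.producer_radius for s in self.scenarios],
                "consumer_radius_um": [s.consumer_radius for s in self.scenarios],
                "gap_um": [s.gap for s in self.scenarios],
                "domain_side_um": [s.domain_side for s in self.scenarios],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def radius_from_volume(volume: float) -> float:
    """Radius of a sphere of the given volume (um^3 -> um)."""
    if not volume > 0:
        raise ValueError(f"volume must be > 0, got {volume}")
    return (3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0)


def build_custom_sweep(
    consumer_radii: Sequence[float],
    producer_radii: Sequence[float],
    gaps: Sequence[float],
    domain_side: float = DEFAULT_DOMAIN_SIDE,
    diffusivity: float = 1.0,
    provenance: str = "custom",
) -> SweepGrid:
    """Full cross-product sweep, producer-major then consumer then gap order."""
    if not len(consumer_radii) or not len(producer_radii) or not len(gaps):
        raise ScenarioError("consumer_radii, producer_radii and gaps must be non-empty")
    scenarios = []
    for R in producer_radii:
        for r in consumer_radii:
            for d in gaps:
                try:
                    scenarios.append(
                        Scenario(
                            producer_radius=R,
                            consumer_radius=r,
                            gap=d,
                            domain_side=domain_side,
                            diffusivity=diffusivity,
                        )
                    )
                except ScenarioError as exc:
                    raise ScenarioError(
                        f"invalid scenario (R={R}, r={r}, d={d}): {exc}"
                    ) from exc
    return SweepGrid(
        scenarios=tuple(scenarios),
        consumer_radii=tuple(consumer_radii),
        producer_radii=tuple(producer_radii),
        gaps=tuple(gaps),
        domain_side=domain_side,
        provenance=provenance,
    )


def build_default_sweep() -> SweepGrid:
    """The default reconstructed 100-scenario sweep (20 size combinations x 5 gaps)."""
    return build_custom_sweep(
        DEFAULT_CONSUMER_RADII,
        DEFAULT_PRODUCER_RADII,
        DEFAULT_GAPS,
        domain_side=DEFAULT_DOMAIN_SIDE,
        provenance="default-reconstruction",
    )


@dataclass(frozen=True)
class EcologicalScenario:
    """A scenario built from cell volumes, with the size ratios it implies.

    The volume ratio is the field's usual "cell size ratio"; the radius ratio
    is what the diffusion model actually consumes.
    """

    scenario: Scenario
    consumer_volume: float
    producer_volume: float
    volume_ratio: float
    radius_ratio: float


def ecological_scenario(
    consumer_volume: float,
    producer_volume: float,
    gap: float,
    domain_side: float = DEFAULT_DOMAIN_SIDE,
) -> EcologicalScenario:
    """Scenario from cell volumes (um^3), e.g. DPANN 0.004 vs bacterial 0.096."""
    r = radius_from_volume(consumer_volume)
    R = radius_from_volume(producer_volume)
    scenario = Scenario(
        producer_radius=R, consumer_radius=r, gap=gap, domain_side=domain_side
    )
    return EcologicalScenario(
        scenario=scenario,
        consumer_volume=consumer_volume,
        producer_volume=producer_volume,
        volume_ratio=consumer_volume / producer_volume,
        radius_ratio=r / R,
    )


def load_sweep_config(path: str | Path) -> SweepGrid:
    """Build a sweep from a YAML config; omitted keys take the defaults.

    Recognized keys: consumer_radii_um, producer_radii_um, gaps_um,
    domain_side_um, diffusivity.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ScenarioError(f"config {path} must be a mapping")
    known = {
        "consumer_radii_um",
        "producer_radii_um",
        "gaps_um",
        "domain_side_um",
        "diffusivity",
        "engine",
        "fd_spacings_um",
        "validation_scenarios",
    }
    unknown = set(cfg) - known
    if unknown:
        raise ScenarioError(f"unknown config keys: {sorted(unknown)}")
    provenance = "custom"
    if not any(k in cfg for k in ("consumer_radii_um", "producer_radii_um", "gaps_um")):
        provenance = "default-reconstruction"
    return build_custom_sweep(
        cfg.get("consumer_radii_um", DEFAULT_CONSUMER_RADII),
        cfg.get("producer_radii_um", DEFAULT_PRODUCER_RADII),
        cfg.get("gaps_um", DEFAULT_GAPS),
        domain_side=cfg.get("domain_side_um", DEFAULT_DOMAIN_SIDE),
        diffusivity=cfg.get("diffusivity", 1.0),
        provenance=provenance,
    )
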