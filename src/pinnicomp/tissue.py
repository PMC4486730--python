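"""Tissue masses, fat masses, and body-composition proportions.

Volumes from the cones geometry are converted to masses by tissue
density and to fat masses by tissue fat fraction, under either the
traditional parameterization (sculp treated as blubber at 0.94 g/mL,
90.3% fat) or the modified one (skin separated; newly measured blubber
density and molt-phase-specific fat fractions).

Unit convention throughout: volumes cm^3 (= mL), masses kg, densities
g/mL, depths cm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import yaml

from .geometry import VolumePartition

__all__ = [
    "TissueProperties",
    "CompositionEstimate",
    "load_tissue_properties",
    "skin_density_from_core",
    "traditional_estimate",
    "modified_estimate",
    "total_body_density",
    "non_blubber_density",
    "sculp_summary",
]

PHASES = ("early", "late")


@dataclass
class TissueProperties:
    """Tissue densities, depths, and fat fractions with uncertainty.

    Each field is a ``(mean, sd)`` pair.  Defaults are the adult female
    northern elephant seal values shipped with the package; other
    species or phases can be loaded from a YAML config.
    """

    blubber_density: tuple = (0.89, 0.03)
    skin_density: tuple = (1.17, 0.13)
    skin_depth_cm: tuple = (1.32, 0.16)
    fat_in_blubber: dict = field(
        default_factory=lambda: {"early": (0.853, 0.026), "late": (0.823, 0.031)}
    )
    fat_in_skin: tuple = (0.161, 0.007)
    traditional_sculp_density: tuple = (0.94, 0.0)
    traditional_fat_fraction: tuple = (0.903, 0.003)

    def __post_init__(self):
        for name, (m, _) in (("blubber_density", self.blubber_density),
                             ("skin_density", self.skin_density),
                             ("traditional_sculp_density", self.traditional_sculp_density)):
            if m <= 0:
                raise ValueError(f"{name} mean must be positive")
        props = [self.fat_in_skin, self.traditional_fat_fraction,
                 *self.fat_in_blubber.values()]
        if any(not (0 < m < 1) for m, _ in props):
            raise ValueError("fat fractions must lie in (0, 1)")

    def fat_in_blubber_for(self, phase: str) -> tuple:
        if phase not in self.fat_in_blubber:
            raise KeyError(f"unknown molt phase {phase!r}; expected one of {PHASES}")
        return self.fat_in_blubber[phase]


def load_tissue_properties(path=None) -> TissueProperties:
    """Load tissue properties from YAML (package default when path is None)."""
    if path is None:
        text = (resources.files("pinnicomp") / "data/tissue_properties.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)

    def pair(key):
        return (float(raw[key]["mean"]), float(raw[key]["sd"]))

    return TissueProperties(
        blubber_density=pair("blubber_density"),
        skin_density=pair("skin_density"),
        skin_depth_cm=pair("skin_depth_cm"),
        fat_in_blubber={"early": pair("fat_in_blubber_early"),
                        "late": pair("fat_in_blubber_late")},
        fat_in_skin=pair("fat_in_skin"),
        traditional_sculp_density=pair("traditional_sculp_density"),
        traditional_fat_fraction=pair("traditional_fat_fraction"),
    )


@dataclass
class CompositionEstimate:
    """Per-tissue masses and whole-body composition for one animal."""

    method: str
    phase: str | None
    blubber_mass_kg: float
    blubber_fat_kg: float
    skin_mass_kg: float
    skin_fat_kg: float
    total_mass_kg: float
    proportion_fat: float
    proportion_adipose: float
    flags: list = field(default_factory=list)

    @property
    def total_fat_kg(self) -> float:
        return self.blubber_fat_kg + self.skin_fat_kg

    def __post_init__(self):
        tissue = self.blubber_mass_kg + self.skin_mass_kg
        if tissue > self.total_mass_kg:
            self.flags.append("tissue_mass_exceeds_total")
        for p in (self.proportion_fat, self.proportion_adipose):
            if not 0.0 <= p <= 1.0:
                self.flags.append("proportion_outside_unit_interval")

    def as_dict(self):
        return {
            "method": self.method,
            "phase": self.phase,
            "blubber_mass_kg": self.blubber_mass_kg,
            "blubber_fat_kg": self.blubber_fat_kg,
            "skin_mass_kg": self.skin_mass_kg,
            "skin_fat_kg": self.skin_fat_kg,
            "total_fat_kg": self.total_fat_kg,
            "proportion_fat": self.proportion_fat,
            "proportion_adipose": self.proportion_adipose,
            "flags": ";".join(self.flags),
        }


def skin_density_from_core(rho_t: float, rho_b: float, d_t: float, d_d: float) -> float:
    """Skin density inferred from a blubber+skin core sample.

    A core of total depth ``d_t`` and density ``rho_t`` containing a
    skin layer of depth ``d_d`` atop blubber of density ``rho_b`` gives
    ``rho_skin = rho_t + (rho_t - rho_b) * (d_t - d_d) / d_d``.
    """
    if d_d <= 0:
        raise ValueError("skin depth d_d must be positive")
    if d_t < d_d:
        raise ValueError("core depth d_t cannot be smaller than skin depth d_d")
    return rho_t + (rho_t - rho_b) * (d_t - d_d) / d_d


def traditional_estimate(v_blubber: float, mass: float,
                         props: TissueProperties | None = None) -> CompositionEstimate:
    """Traditional composition: the whole sculp shell treated as blubber.

    Uses the literature sculp density (0.94 g/mL) and fat fraction
    (0.903); skin is not separated.
    """
    props = props or TissueProperties()
    if mass <= 0:
        raise ValueError("total mass must be positive")
    if v_blubber < 0:
        raise ValueError("blubber volume must be non-negative")
    rho = props.traditional_sculp_density[0]
    f = props.traditional_fat_fraction[0]
    blubber_mass = v_blubber * rho / 1000.0
    fat = blubber_mass * f
    return CompositionEstimate(
        method="traditional", phase=None,
        blubber_mass_kg=blubber_mass, blubber_fat_kg=fat,
        skin_mass_kg=0.0, skin_fat_kg=0.0, total_mass_kg=mass,
        proportion_fat=fat / mass, proportion_adipose=blubber_mass / mass,
    )


def modified_estimate(partition: VolumePartition, mass: float,
                      props: TissueProperties | None = None,
                      phase: str = "early") -> CompositionEstimate:
    """Modified composition: skin and blubber as separate tissues.

    Blubber mass uses the carcass-measured pure blubber density and the
    molt-phase fat fraction; skin mass uses skin density and skin fat
    fraction.  Proportion adipose counts blubber only (skin is not
    adipose tissue).
    """
    props = props or TissueProperties()
    if mass <= 0:
        raise ValueError("total mass must be positive")
    f_blub = props.fat_in_blubber_for(phase)[0]
    blubber_mass = partition.v_blubber * props.blubber_density[0] / 1000.0
    blubber_fat = blubber_mass * f_blub
    skin_mass = partition.v_skin * props.skin_density[0] / 1000.0
    skin_fat = skin_mass * props.fat_in_skin[0]
    total_fat = blubber_fat + skin_fat
    return CompositionEstimate(
        method="modified", phase=phase,
        blubber_mass_kg=blubber_mass, blubber_fat_kg=blubber_fat,
        skin_mass_kg=skin_mass, skin_fat_kg=skin_fat, total_mass_kg=mass,
        proportion_fat=total_fat / mass, proportion_adipose=blubber_mass / mass,
    )


def total_body_density(mass: float, v_total: float) -> float:
    """Whole-body density [g/mL] from measured mass and cones volume."""
    if v_total <= 0:
        raise ValueError("total volume must be positive")
    return 1000.0 * mass / v_total


def non_blubber_density(mass: float, partition: VolumePartition,
                        props: TissueProperties | None = None) -> float:
    """Density [g/mL] of everything that is not blubber (skin included)."""
    props = props or TissueProperties()
    blubber_mass = partition.v_blubber * props.blubber_density[0] / 1000.0
    num = mass - blubber_mass
    den = partition.v_total - partition.v_blubber
    if num <= 0 or den <= 0:
        raise ValueError("non-blubber mass and volume must both be positive")
    return 1000.0 * num / den


def sculp_summary(partition: VolumePartition,
                  props: TissueProperties | None = None,
                  phase: str = "early") -> dict:
    """Density and fat fraction of the sculp (skin + blubber) layer."""
    props = props or TissueProperties()
    v_sculp = partition.v_skin + partition.v_blubber
    if v_sculp <= 0:
        raise ValueError("sculp volume must be positive")
    blubber_mass = partition.v_blubber * props.blubber_density[0] / 1000.0
    skin_mass = partition.v_skin * props.skin_density[0] / 1000.0
    blubber_fat = blubber_mass * props.fat_in_blubber_for(phase)[0]
    skin_fat = skin_mass * props.fat_in_skin[0]
    sculp_mass = blubber_mass + skin_mass
    return {
        "sculp_density_g_ml": 1000.0 * sculp_mass / v_sculp,
        "sculp_fat_fraction": (blubber_fat + skin_fat) / sculp_mass,
    }
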