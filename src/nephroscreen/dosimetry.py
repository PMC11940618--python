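"""Equilibrium mass-balance dosimetry for multi-well culture systems.

Nominal (applied) concentrations overstate the biologically available dose
when a chemical partitions into serum protein, serum lipid, well headspace
or the plastic labware.  This module computes the fraction unbound in the
culture medium, fub_media, from an equilibrium mass balance over those
compartments, and converts nominal concentrations (including right-censored
PODs) to free concentrations.

The model treats the chemical as neutral and distributes total mass over
equivalent sorbent volumes:

    fub_media = V_w / (V_w + K_prot·V_prot + K_lip·V_lip + K_aw·V_air + V_pl)

with sorbent affinities estimated from log Kow by standard one-parameter
correlations (serum albumin: log K_prot = 0.71·log Kow + 0.42; storage
lipid: log K_lip = 1.01·log Kow + 0.12; polystyrene, optional:
log K_pl[m] = 0.97·log Kow − 6.94, area-referenced) and the air term from
the air–water partition coefficient Kaw.  Non-volatile chemicals default to
log Kaw = −30, which makes the air term numerically zero.  All correlations
are plain module-level functions and can be swapped by passing replacement
callables.  Ionization is ignored; for strong acids/bases the free fraction
is underestimated (see the methods note).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

from ._censored import CensoredValue, as_censored

__all__ = [
    "PhysChemProfile",
    "CultureSystem",
    "DosimetryResult",
    "compute_fub_media",
    "to_free_concentration",
]

#: Default log Kaw assigned to non-volatile chemicals.
LOG_KAW_NONVOLATILE = -30.0

PROTEIN_DENSITY_G_PER_ML = 1.36
LIPID_DENSITY_G_PER_ML = 0.9


@dataclass(frozen=True)
class PhysChemProfile:
    """Chemical-specific inputs to the mass balance.

    ``log_kow`` is required; ``log_kaw`` defaults to −30 (non-volatile).
    ``log_koa``, ``melting_point_C`` and ``water_solubility_mg_L`` are
    carried for alternative model plug-ins but unused by the default
    correlations.  ``fub_plasma`` is the fraction unbound in human plasma,
    used downstream for free-Cmax margins.
    """

    log_kow: float
    log_kaw: float = LOG_KAW_NONVOLATILE
    log_koa: float | None = None
    melting_point_C: float | None = None
    water_solubility_mg_L: float | None = None
    fub_plasma: float = 1.0

    def __post_init__(self) -> None:
        if self.log_kow is None or not math.isfinite(self.log_kow):
            raise ValueError("log_kow is required and must be finite (no default)")
        if not 0 < self.fub_plasma <= 1:
            raise ValueError(f"fub_plasma must be in (0, 1], got {self.fub_plasma}")


@dataclass(frozen=True)
class CultureSystem:
    """Well-level composition of the in vitro system.

    Volumes in µL, area in mm².  ``serum_volume_fraction`` is the volume
    fraction of the medium that is serum (0.002–0.10 across the screened
    formulations); ``serum_protein_g_per_L`` and ``serum_lipid_g_per_L`` are
    per unit serum.  Plastic binding is off by default.
    """

    serum_volume_fraction: float
    medium_volume_uL: float = 50.0
    headspace_volume_uL: float = 80.0
    plastic_area_mm2: float = 30.0
    serum_protein_g_per_L: float = 38.0
    serum_lipid_g_per_L: float = 2.5
    plastic_binding_enabled: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.serum_volume_fraction < 1:
            raise ValueError(
                f"serum_volume_fraction must be in [0, 1), got {self.serum_volume_fraction}"
            )
        for name in ("medium_volume_uL", "headspace_volume_uL", "plastic_area_mm2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.medium_volume_uL <= 0:
            raise ValueError("medium_volume_uL must be > 0")


@dataclass(frozen=True)
class DosimetryResult:
    """fub_media plus the equilibrium mass fraction in each compartment."""

    fub_media: float
    compartment_fractions: dict[str, float]


def log_k_protein_water(log_kow: float) -> float:
    """Serum-albumin–water partition coefficient (log10) from log Kow."""
    return 0.71 * log_kow + 0.42


def log_k_lipid_water(log_kow: float) -> float:
    """Storage-lipid–water partition coefficient (log10) from log Kow."""
    return 1.01 * log_kow + 0.12


def log_k_plastic_water_m(log_kow: float) -> float:
    """Polystyrene–water sorption coefficient (log10 of metres) from log Kow."""
    return 0.97 * log_kow - 6.94


def compute_fub_media(
    chem: PhysChemProfile,
    system: CultureSystem,
    k_protein: Callable[[float], float] = log_k_protein_water,
    k_lipid: Callable[[float], float] = log_k_lipid_water,
    k_plastic: Callable[[float], float] = log_k_plastic_water_m,
) -> DosimetryResult:
    """Fraction unbound in medium from the equilibrium mass balance.

    Returns the free aqueous fraction of the nominal concentration together
    with the mass fraction in each compartment (aqueous, serum protein,
    serum lipid, air, plastic); the fractions sum to 1.
    """
    v_w = system.medium_volume_uL
    serum_uL = v_w * system.serum_volume_fraction
    # sorbent equivalent volumes in µL: g → mL via density, mL → µL
    v_prot = serum_uL * system.serum_protein_g_per_L * 1e-3 / PROTEIN_DENSITY_G_PER_ML
    v_lip = serum_uL * system.serum_lipid_g_per_L * 1e-3 / LIPID_DENSITY_G_PER_ML

    cap_prot = 10.0 ** k_protein(chem.log_kow) * v_prot
    cap_lip = 10.0 ** k_lipid(chem.log_kow) * v_lip
    cap_air = 10.0 ** chem.log_kaw * system.headspace_volume_uL
    if system.plastic_binding_enabled:
        # K_pl in metres × area in m² → m³; 1 m³ = 1e9 µL
        cap_pl = 10.0 ** k_plastic(chem.log_kow) * system.plastic_area_mm2 * 1e-6 * 1e9
    else:
        cap_pl = 0.0

    total = v_w + cap_prot + cap_lip + cap_air + cap_pl
    fub = v_w / total
    fractions = {
        "aqueous": v_w / total,
        "serum_protein": cap_prot / total,
        "serum_lipid": cap_lip / total,
        "air": cap_air / total,
        "plastic": cap_pl / total,
    }
    return DosimetryResult(fub_media=fub, compartment_fractions=fractions)


def to_free_concentration(
    nominal: float | CensoredValue, fub: float
) -> CensoredValue:
    """Free (unbound aqueous) concentration from a nominal one.

    free = nominal × fub.  A censored nominal POD stays censored with its
    bound scaled by the same factor.
    """
    if not 0 < fub <= 1:
        raise ValueError(f"fub must be in (0, 1], got {fub}")
    return as_censored(nominal).scaled(fub)
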