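"""Stopping-power physics for dual-energy-CT derived proton RSP.

This module implements the small set of closed-form relations that link a
material's elemental composition to the quantities a dual-energy CT scanner
reports (effective atomic number Zeff, relative electron density RED) and to
the proton relative stopping power (RSP):

* the Mayneord power-law effective atomic number,
  ``Zeff = [sum_i w_i (Z_i/A_i) Z_i^n / sum_i w_i (Z_i/A_i)]^(1/n)`` with
  ``n = 3.21``;
* the relative electron density,
  ``RED = rho * N_A * sum_i w_i Z_i/A_i / rho_e,w``;
* the Bragg-additivity mean excitation energy,
  ``ln I_m = sum_j w_j (Z_j/A_j) ln I_j / sum_j w_j (Z_j/A_j)``;
* the Bethe-Bloch stopping-power ratio relative to water,
  ``RSP = RED * [ln(2 m_e c^2 beta^2 / (1 - beta^2)) - beta^2 - ln I_m]
              / [ln(2 m_e c^2 beta^2 / (1 - beta^2)) - beta^2 - ln I_w]``;
* the water-equivalent-thickness identity ``RSP = WET / t``.

An empirical, piecewise-linear ``ln I`` versus ``Zeff`` correlation
(:class:`ZeffICorrelation`) stands in for the proprietary mapping a clinical
scanner applies when only the voxel Zeff is known.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import CalibrationError, InvalidInputError

__all__ = [
    "ElementalComponent",
    "Composition",
    "MaterialSpec",
    "PhysicsConstants",
    "ZeffICorrelation",
    "CONSTANTS",
    "WATER_MASS_FRACTIONS",
    "mayneord_zeff",
    "relative_electron_density",
    "bragg_additivity_lnI",
    "calibrate_correlation",
    "beta_squared",
    "bethe_bloch_rsp",
    "rsp_from_wet",
    "theoretical_rsp",
]

logger = logging.getLogger(__name__)

#: Mass fractions of water (NIST standard composition).
WATER_MASS_FRACTIONS = {"H": 0.111894, "O": 0.888106}


@dataclass(frozen=True)
class ElementalComponent:
    """One element of a mixture: mass fraction plus elemental constants.

    ``i_value_ev`` may be omitted when only Zeff/RED are needed; the
    Bragg-additivity rule requires it.
    """

    symbol: str
    mass_fraction: float
    atomic_number: int
    atomic_mass: float
    i_value_ev: float | None = None

    def __post_init__(self):
        if self.mass_fraction < 0:
            raise InvalidInputError(f"{self.symbol}: mass fraction must be >= 0")
        if self.atomic_number < 1:
            raise InvalidInputError(f"{self.symbol}: atomic number must be >= 1")
        if self.atomic_mass <= 0:
            raise InvalidInputError(f"{self.symbol}: atomic mass must be > 0")
        if self.i_value_ev is not None and self.i_value_ev <= 0:
            raise InvalidInputError(f"{self.symbol}: I-value must be > 0")

    @property
    def z_over_a(self) -> float:
        return self.atomic_number / self.atomic_mass


class Composition:
    """A normalized elemental composition (mass fractions summing to 1).

    Compositions whose fractions do not sum to one are renormalized; a
    warning is logged when the deviation exceeds 1e-3.
    """

    def __init__(self, components: Iterable[ElementalComponent]):
        components = tuple(components)
        if not components:
            raise InvalidInputError("composition needs at least one component")
        total = sum(c.mass_fraction for c in components)
        if total <= 0:
            raise InvalidInputError("composition weights sum to zero")
        if abs(total - 1.0) > 1e-3:
            logger.warning(
                "composition weights sum to %.6f; renormalizing", total
            )
        if abs(total - 1.0) > 1e-12:
            components = tuple(
                replace(c, mass_fraction=c.mass_fraction / total)
                for c in components
            )
        self.components: tuple[ElementalComponent, ...] = components

    def __iter__(self):
        return iter(self.components)

    def __len__(self):
        return len(self.components)

    def __repr__(self):
        parts = ", ".join(
            f"{c.symbol}:{c.mass_fraction:.4f}" for c in self.components
        )
        return f"Composition({parts})"

    @classmethod
    def from_fractions(
        cls, fractions: dict[str, float], element_table: dict[str, "ElementRecord"] | None = None
    ) -> "Composition":
        """Build from ``{symbol: mass fraction}`` using the bundled element table."""
        from .materials import element_table as _default_table

        table = element_table if element_table is not None else _default_table()
        comps = []
        for symbol, w in fractions.items():
            rec = table[symbol]
            comps.append(
                ElementalComponent(
                    symbol=symbol,
                    mass_fraction=w,
                    atomic_number=rec.atomic_number,
                    atomic_mass=rec.atomic_mass,
                    i_value_ev=rec.i_value_ev,
                )
            )
        return cls(comps)

    def electron_fraction_sum(self) -> float:
        """``sum_i w_i Z_i / A_i`` (mol electrons per gram, times 1/mol)."""
        return sum(c.mass_fraction * c.z_over_a for c in self.components)


@dataclass
class MaterialSpec:
    """A named material: composition, bulk density, optional reference values.

    Manufacturer-supplied (override) RED/Zeff and beam-measured RSP take
    precedence over composition-derived values when building phantom
    references; the composition-derived values remain available for QA.
    """

    name: str
    composition: Composition | None
    mass_density: float | None = None  # g/cm^3
    red_override: float | None = None
    zeff_override: float | None = None
    rsp_ref: float | None = None
    rsp_ref_sd: float | None = None

    def __post_init__(self):
        if self.mass_density is not None and self.mass_density <= 0:
            raise InvalidInputError(f"{self.name}: density must be > 0")
        for label in ("red_override", "zeff_override", "rsp_ref"):
            v = getattr(self, label)
            if v is not None and v <= 0:
                raise InvalidInputError(f"{self.name}: {label} must be > 0")

    @property
    def reference_red(self) -> float | None:
        """Manufacturer override if present, else the computed RED."""
        if self.red_override is not None:
            return self.red_override
        if self.composition is not None and self.mass_density is not None:
            return relative_electron_density(self.composition, self.mass_density)
        return None

    @property
    def reference_zeff(self) -> float | None:
        if self.zeff_override is not None:
            return self.zeff_override
        if self.composition is not None:
            return mayneord_zeff(self.composition)
        return None


@dataclass(frozen=True)
class PhysicsConstants:
    """Physical constants and conventions used throughout the package.

    ``water_i_ev`` is fixed at 75.3 eV (the water I-value convention this
    RSP formulation uses); ``mayneord_exponent`` is the power-law exponent
    n = 3.21. ``kinetic_energy_mev`` is the default proton energy used for
    beta; RSP is insensitive to it at the sub-percent level across the
    therapeutic range, see docs/methods.md.
    """

    electron_rest_mev: float = 0.511
    proton_rest_mev: float = 938.272
    water_i_ev: float = 75.3
    avogadro: float = 6.02214076e23
    mayneord_exponent: float = 3.21
    kinetic_energy_mev: float = 100.0
    # electrons/cm^3 of water at 1.000 g/cm^3, from the standard composition
    water_electron_density: float = field(default=0.0)

    def __post_init__(self):
        if self.water_electron_density == 0.0:
            zoa = (
                WATER_MASS_FRACTIONS["H"] * (1 / 1.008)
                + WATER_MASS_FRACTIONS["O"] * (8 / 15.999)
            )
            object.__setattr__(
                self, "water_electron_density", self.avogadro * zoa
            )
        for name in (
            "electron_rest_mev",
            "proton_rest_mev",
            "water_i_ev",
            "avogadro",
            "mayneord_exponent",
            "water_electron_density",
        ):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"constant {name} must be > 0")


CONSTANTS = PhysicsConstants()


def mayneord_zeff(
    composition: Composition, exponent: float | None = None
) -> float:
    """Mayneord power-law effective atomic number of a mixture.

    ``[sum_i w_i (Z_i/A_i) Z_i^n / sum_i w_i (Z_i/A_i)]^(1/n)``, n = 3.21.
    The result always lies between the smallest and largest Z present.
    """
    n = exponent if exponent is not None else CONSTANTS.mayneord_exponent
    num = 0.0
    den = 0.0
    for c in composition:
        t = c.mass_fraction * c.z_over_a
        num += t * c.atomic_number**n
        den += t
    if den <= 0:
        raise InvalidInputError("composition has zero electron content")
    return (num / den) ** (1.0 / n)


def relative_electron_density(
    composition: Composition,
    mass_density: float,
    constants: PhysicsConstants = CONSTANTS,
) -> float:
    """Electron density relative to water: ``rho N_A sum w_i Z_i/A_i / rho_e,w``."""
    if mass_density <= 0:
        raise InvalidInputError("mass density must be > 0")
    return (
        mass_density
        * constants.avogadro
        * composition.electron_fraction_sum()
        / constants.water_electron_density
    )


def bragg_additivity_lnI(composition: Composition) -> float:
    """Bragg-additivity mean excitation energy, returned as ``ln(I_m / eV)``.

    Electron-fraction-weighted mean of the elemental ``ln I_j``; raises if
    any component lacks an elemental I-value.
    """
    num = 0.0
    den = 0.0
    for c in composition:
        if c.i_value_ev is None:
            raise InvalidInputError(f"{c.symbol}: elemental I-value missing")
        t = c.mass_fraction * c.z_over_a
        num += t * math.log(c.i_value_ev)
        den += t
    if den <= 0:
        raise InvalidInputError("composition has zero electron content")
    return num / den


@dataclass(frozen=True)
class ZeffICorrelation:
    """Piecewise-linear empirical ``ln I`` versus Zeff correlation.

    Clinical DECT pipelines assign a voxel's mean excitation energy from its
    effective atomic number through a proprietary empirical curve; this class
    is the package's open equivalent, calibrated from reference materials via
    :func:`calibrate_correlation`. Queries outside the node range clamp to
    the end nodes (no extrapolation).
    """

    node_zeff: tuple[float, ...]
    node_lni: tuple[float, ...]

    def __post_init__(self):
        z = np.asarray(self.node_zeff, dtype=float)
        l = np.asarray(self.node_lni, dtype=float)
        if z.size != l.size or z.size < 2:
            raise CalibrationError("need >= 2 (Zeff, ln I) nodes")
        if not np.all(np.diff(z) > 0):
            raise CalibrationError("Zeff nodes must be strictly increasing")

    def lni(self, zeff):
        """``ln(I/eV)`` at the given Zeff (scalar or array), clamped."""
        return np.interp(zeff, self.node_zeff, self.node_lni)

    def i_value(self, zeff):
        """``I`` in eV at the given Zeff (scalar or array)."""
        return np.exp(self.lni(zeff))


def calibrate_correlation(
    reference_materials: Sequence[MaterialSpec],
    anchor_water: bool = True,
    mode: str = "fit",
    constants: PhysicsConstants = CONSTANTS,
) -> ZeffICorrelation:
    """Calibrate the piecewise-linear ``ln I`` vs Zeff curve.

    For each material, Zeff (Mayneord) and ``ln I`` (Bragg additivity) are
    computed from its composition. Two calibration modes:

    ``"fit"`` (default)
        Least-squares straight line of ``ln I`` on Zeff, returned as a
        two-node curve spanning the calibration range. Tissue surrogates
        scatter around the I-Zeff trend (chemically different materials can
        share a Zeff), so interpolating *through* every point produces a
        jagged, non-monotone curve whose kinks rectify zero-mean Zeff noise
        into a systematic I shift; the fitted line has zero curvature and
        keeps noisy voxel averages unbiased.

    ``"interpolate"``
        Pass exactly through every (Zeff, ln I) point, duplicate Zeff nodes
        merged by averaging ``ln I``.

    With ``anchor_water=True`` the curve is shifted by a constant so that
    water's Zeff maps exactly to the conventional ``I_w`` = 75.3 eV:
    elemental Bragg additivity ignores molecular binding and lands ~8 % low
    for water, and anchoring restores the I-scale the RSP formula uses for
    its denominator.

    Queries outside the node range clamp to the end nodes.
    """
    pairs: dict[float, list[float]] = {}
    for m in reference_materials:
        if m.composition is None:
            continue
        z = round(mayneord_zeff(m.composition, constants.mayneord_exponent), 9)
        pairs.setdefault(z, []).append(bragg_additivity_lnI(m.composition))
    nodes = sorted((z, float(np.mean(ls))) for z, ls in pairs.items())
    if len(nodes) < 2:
        raise CalibrationError("need >= 2 distinct Zeff nodes to calibrate")
    if mode == "fit":
        z_arr = np.array([z for z, _ in nodes])
        l_arr = np.array([l for _, l in nodes])
        slope, intercept = np.polyfit(z_arr, l_arr, 1)
        # span a guard band beyond the calibration range so the end clamps
        # sit well outside the Zeff values noisy voxels actually reach
        zs = (float(z_arr[0] - 2.0), float(z_arr[-1] + 2.0))
        ls = tuple(float(slope * z + intercept) for z in zs)
    elif mode == "interpolate":
        zs = tuple(z for z, _ in nodes)
        ls = tuple(l for _, l in nodes)
    else:
        raise InvalidInputError(f"unknown calibration mode {mode!r}")
    if anchor_water:
        water = Composition.from_fractions(WATER_MASS_FRACTIONS)
        zw = mayneord_zeff(water, constants.mayneord_exponent)
        shift = math.log(constants.water_i_ev) - float(np.interp(zw, zs, ls))
        ls = tuple(l + shift for l in ls)
    return ZeffICorrelation(node_zeff=zs, node_lni=ls)


def beta_squared(
    kinetic_energy_mev: float, constants: PhysicsConstants = CONSTANTS
) -> float:
    """``beta^2`` of a proton of the given kinetic energy (relativistic)."""
    if kinetic_energy_mev <= 0:
        raise InvalidInputError("kinetic energy must be > 0")
    gamma_inv = constants.proton_rest_mev / (
        kinetic_energy_mev + constants.proton_rest_mev
    )
    return 1.0 - gamma_inv**2


def _stopping_bracket(lni, beta2: float, constants: PhysicsConstants):
    """``ln(2 m_e c^2 beta^2/(1-beta^2)) - beta^2 - ln I`` with I in eV."""
    two_me_ev = 2.0e6 * constants.electron_rest_mev
    return np.log(two_me_ev * beta2 / (1.0 - beta2)) - beta2 - lni


def bethe_bloch_rsp(
    red,
    i_m_ev,
    kinetic_energy_mev: float | None = None,
    constants: PhysicsConstants = CONSTANTS,
):
    """Relative stopping power from RED and the material I-value.

    ``RSP = RED * L(I_m) / L(I_w)`` where ``L`` is the Bethe stopping
    bracket at the proton's ``beta^2``. Accepts scalars or arrays; when
    ``I_m`` equals ``I_w`` the bracket ratio is exactly one and RSP = RED.
    """
    T = (
        kinetic_energy_mev
        if kinetic_energy_mev is not None
        else constants.kinetic_energy_mev
    )
    beta2 = beta_squared(T, constants)
    red = np.asarray(red, dtype=float)
    i_m_ev = np.asarray(i_m_ev, dtype=float)
    if np.any(red <= 0):
        raise InvalidInputError("RED must be > 0")
    if np.any(i_m_ev <= 0):
        raise InvalidInputError("I_m must be > 0")
    num = _stopping_bracket(np.log(i_m_ev), beta2, constants)
    den = _stopping_bracket(math.log(constants.water_i_ev), beta2, constants)
    if den <= 0 or np.any(num <= 0):
        raise InvalidInputError(
            "stopping bracket non-positive (I too large for this energy)"
        )
    out = red * num / den
    return float(out) if out.ndim == 0 else out


def rsp_from_wet(wet_mm: float, thickness_mm: float) -> float:
    """RSP from a water-equivalent-thickness measurement: ``WET / t``."""
    if thickness_mm <= 0:
        raise InvalidInputError("physical thickness must be > 0")
    return wet_mm / thickness_mm


def theoretical_rsp(
    material: MaterialSpec,
    kinetic_energy_mev: float | None = None,
    constants: PhysicsConstants = CONSTANTS,
) -> float:
    """Composition-based RSP: Bragg-additivity I plus the Bethe bracket ratio.

    Uses the manufacturer RED override when present (reference precedence),
    otherwise the composition-derived RED.
    """
    if material.composition is None:
        raise InvalidInputError(f"{material.name}: no composition")
    red = material.reference_red
    if red is None:
        raise InvalidInputError(f"{material.name}: no density or RED override")
    i_m = math.exp(bragg_additivity_lnI(material.composition))
    return bethe_bloch_rsp(red, i_m, kinetic_energy_mev, constants)
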