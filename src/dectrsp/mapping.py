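"""Voxel-wise conversion of matched Zeff/RED volumes to an RSP volume."""

from __future__ import annotations

import logging

import numpy as np

from .errors import InvalidInputError
from .physics import CONSTANTS, PhysicsConstants, ZeffICorrelation, bethe_bloch_rsp
from .volume import PropertyVolume

__all__ = ["rsp_map", "RED_FLOOR"]

logger = logging.getLogger(__name__)

#: RED assigned to voxels that are non-positive after noise (air floor).
RED_FLOOR = 0.001


def rsp_map(
    zeff_vol: PropertyVolume,
    red_vol: PropertyVolume,
    correlation: ZeffICorrelation,
    kinetic_energy_mev: float | None = None,
    constants: PhysicsConstants = CONSTANTS,
) -> PropertyVolume:
    """Per-voxel RSP from Zeff and RED volumes on an identical grid.

    Each voxel's mean excitation energy comes from the empirical
    correlation at its Zeff (clamped to the calibrated range), then the
    Bethe-Bloch ratio scales its RED into RSP. Voxels whose RED is
    non-positive (possible after additive noise) are clamped to the air
    floor; the count is logged. Non-finite input voxels propagate as NaN
    with a logged count.
    """
    if zeff_vol.quantity != "zeff" or red_vol.quantity != "red":
        raise InvalidInputError(
            f"expected (zeff, red) volumes, got "
            f"({zeff_vol.quantity}, {red_vol.quantity})"
        )
    zeff_vol.require_same_grid(red_vol)

    zeff = np.asarray(zeff_vol.values, dtype=float)
    red = np.asarray(red_vol.values, dtype=float).copy()

    bad = ~(np.isfinite(zeff) & np.isfinite(red))
    if np.any(bad):
        logger.warning("rsp_map: %d non-finite input voxels", int(bad.sum()))
    clamped = red <= 0
    n_clamped = int(np.count_nonzero(clamped & ~bad))
    if n_clamped:
        logger.info("rsp_map: clamped %d non-positive RED voxels to %.3g",
                    n_clamped, RED_FLOOR)
        red[clamped] = RED_FLOOR

    i_m = correlation.i_value(np.where(bad, correlation.node_zeff[0], zeff))
    rsp = bethe_bloch_rsp(
        np.where(bad, RED_FLOOR, red), i_m, kinetic_energy_mev, constants
    )
    rsp = np.where(bad, np.nan, rsp)
    return red_vol.with_values(rsp, "rsp")
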