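"""Synthetic tissue-characterization phantoms.

Builds voxelized Zeff/RED volumes that emulate what a dual-energy CT
decomposition exports for the five physical phantoms used in the accuracy
study: the 33 cm Gammex-type Model 467 disk, the 40 x 30 cm Advanced
Electron Density (AED) body phantom with its 20 cm head insert, and the
27 / 18 cm custom wax "George" body and head phantoms. Each preset places
cylindrical tissue-surrogate inserts on rings at the documented
center-to-outer-edge radii and edge-to-edge gaps; angular layout within a
ring (not documented for the physical phantoms) is sequential from a start
angle with the exact printed gap between neighbors.

The simulated maps are piecewise constant (each voxel takes its material's
reference Zeff/RED) plus independent additive Gaussian noise at the
magnitudes measured on the scanner, and optionally an exponential-decay
bias field near high-density inserts to mimic scatter/beam-hardening
artifacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Sequence

import numpy as np
import yaml

from .errors import GeometryError, InvalidInputError
from .materials import reference_materials
from .reference_tables import load_noise_table, load_rsp_reference
from .volume import PropertyVolume

__all__ = [
    "InsertSpec",
    "PhantomOutline",
    "PhantomSpec",
    "NoiseModel",
    "BiasSource",
    "PRESET_NAMES",
    "preset_phantom",
    "build_label_volume",
    "render_property_maps",
    "add_noise",
    "add_highz_bias",
    "noise_presets",
    "simulate",
    "SimulationResult",
    "save_phantom_spec",
    "load_phantom_spec",
]

#: Zeff/RED assigned to voxels outside the phantom outline. The RED floor
#: of 0.001 (instead of true air ~0.0011) avoids divide-by-zero downstream.
AIR_ZEFF = 7.70
AIR_RED = 0.001


@dataclass(frozen=True)
class InsertSpec:
    """A cylindrical insert: in-plane position, size, and assigned values."""

    name: str
    center_cm: tuple[float, float]
    diameter_cm: float
    material: str | None = None
    zeff: float | None = None
    red: float | None = None
    rsp_ref: float | None = None
    rsp_ref_sd: float | None = None

    def __post_init__(self):
        if self.diameter_cm <= 0:
            raise InvalidInputError(f"{self.name}: diameter must be > 0")
        for label in ("zeff", "red"):
            v = getattr(self, label)
            if v is not None and v <= 0:
                raise InvalidInputError(f"{self.name}: {label} must be > 0")

    @property
    def radius_cm(self) -> float:
        return self.diameter_cm / 2.0


@dataclass(frozen=True)
class PhantomOutline:
    """Outer cross-section: a circle or an axis-aligned ellipse (cm)."""

    shape: str  # "circle" | "ellipse"
    diameter_cm: float | None = None
    width_cm: float | None = None
    height_cm: float | None = None

    def __post_init__(self):
        if self.shape == "circle":
            if not self.diameter_cm or self.diameter_cm <= 0:
                raise InvalidInputError("circle outline needs diameter > 0")
        elif self.shape == "ellipse":
            if (
                not self.width_cm
                or not self.height_cm
                or self.width_cm <= 0
                or self.height_cm <= 0
            ):
                raise InvalidInputError("ellipse outline needs width/height > 0")
        else:
            raise InvalidInputError(f"unknown outline shape {self.shape!r}")

    @property
    def semi_axes_cm(self) -> tuple[float, float]:
        if self.shape == "circle":
            r = self.diameter_cm / 2.0
            return (r, r)
        return (self.width_cm / 2.0, self.height_cm / 2.0)

    @property
    def equivalent_diameter_cm(self) -> float:
        """Diameter of the circle with the same cross-sectional area."""
        a, b = self.semi_axes_cm
        return 2.0 * math.sqrt(a * b)

    def contains_circle(self, center_cm, radius_cm, margin_cm=0.0) -> bool:
        a, b = self.semi_axes_cm
        x, y = center_cm
        if self.shape == "circle":
            return math.hypot(x, y) + radius_cm <= a - margin_cm
        # conservative: inflate the point by the insert radius on both axes
        return ((abs(x) + radius_cm) / (a - margin_cm)) ** 2 + (
            (abs(y) + radius_cm) / (b - margin_cm)
        ) ** 2 <= 1.0

    def mask(self, x_cm: np.ndarray, y_cm: np.ndarray) -> np.ndarray:
        a, b = self.semi_axes_cm
        return (x_cm[:, None] / a) ** 2 + (y_cm[None, :] / b) ** 2 <= 1.0


@dataclass
class PhantomSpec:
    """A phantom: outline + background material + positioned inserts."""

    name: str
    outline: PhantomOutline
    background_material: str
    background_zeff: float
    background_red: float
    inserts: list[InsertSpec]
    height_cm: float = 5.0

    def __post_init__(self):
        for ins in self.inserts:
            if not self.outline.contains_circle(ins.center_cm, ins.radius_cm):
                raise GeometryError(
                    f"insert {ins.name!r} extends outside the outline"
                )
        for i, a in enumerate(self.inserts):
            for b in self.inserts[i + 1 :]:
                d = math.dist(a.center_cm, b.center_cm)
                if d < a.radius_cm + b.radius_cm:
                    raise GeometryError(
                        f"inserts {a.name!r} and {b.name!r} overlap"
                    )

    def insert(self, name: str) -> InsertSpec:
        for ins in self.inserts:
            if ins.name == name:
                return ins
        raise KeyError(name)


# ---------------------------------------------------------------------------
# Presets


def _ring(radius_cm, names, diameter_cm, edge_gap_cm, start_angle_deg=0.0):
    """Sequential ring placement with the exact edge gap between neighbors.

    The angular step subtends a chord of ``gap + diameter``; any slack after
    the last insert is left as one larger closing gap.
    """
    chord = edge_gap_cm + diameter_cm
    if chord > 2 * radius_cm:
        raise GeometryError("gap + diameter exceeds the ring diameter")
    step = 2.0 * math.asin(chord / (2.0 * radius_cm))
    if (len(names) - 1) * step >= 2.0 * math.pi:
        raise GeometryError("ring cannot hold that many inserts at this gap")
    out = []
    a0 = math.radians(start_angle_deg)
    for i, name in enumerate(names):
        a = a0 + i * step
        out.append((name, (radius_cm * math.cos(a), radius_cm * math.sin(a))))
    return out


PRESET_NAMES = ("model467", "aed_body", "aed_head", "george_body", "george_head")

# per-preset plug diameters (cm); not printed for the physical phantoms —
# 2.8 cm matches the standard characterization-phantom plug, the custom
# George Head wax plugs are smaller so the printed ring geometry closes.
_DIAMETERS = {
    "model467": 2.8,
    "aed_body": 2.8,
    "aed_head": 2.8,
    "george_body": 2.8,
    "george_head": 2.0,
}
_GEORGE_HEAD_SINUS_D = 1.5


def _reference_row(preset: str, plug: str):
    df = load_rsp_reference()
    row = df[(df.preset == preset) & (df.plug == plug)]
    if row.empty:
        raise KeyError(f"no reference row for {preset}/{plug}")
    return row.iloc[0]


def _insert_from_row(preset, plug, center, diameter) -> InsertSpec:
    r = _reference_row(preset, plug)
    return InsertSpec(
        name=plug,
        center_cm=center,
        diameter_cm=diameter,
        material=r.material,
        zeff=float(r.zeff_ref),
        red=float(r.red_ref),
        rsp_ref=float(r.rsp_ref),
        rsp_ref_sd=float(r.rsp_ref_sd),
    )


def _background(material_name: str) -> tuple[str, float, float]:
    m = reference_materials()[material_name]
    return material_name, float(m.reference_zeff), float(m.reference_red)


def _aed_head_layout(d):
    """Central solid-water plug plus a uniform ring of nine."""
    ring_names = [
        "Adipose",
        "CaCO3 30%",
        "Brain",
        "Solid Water 2",
        "CaCO3 50%",
        "Breast",
        "True Water 1",
        "Cortical bone",
        "Solid Water 3",
    ]
    out = [("Solid Water 1", (0.0, 0.0))]
    for i, name in enumerate(ring_names):
        a = 2.0 * math.pi * i / len(ring_names)
        out.append((name, (6.5 * math.cos(a), 6.5 * math.sin(a))))
    return out


@lru_cache(maxsize=None)
def preset_phantom(name: str) -> PhantomSpec:
    """Build one of the five study phantoms by preset key.

    Keys: ``model467``, ``aed_body``, ``aed_head``, ``george_body``,
    ``george_head``. Insert names and assigned Zeff/RED/RSP references come
    from the bundled per-insert reference table.
    """
    if name not in PRESET_NAMES:
        raise KeyError(f"unknown phantom preset {name!r}")
    d = _DIAMETERS[name]

    if name == "model467":
        outline = PhantomOutline("circle", diameter_cm=33.0)
        bg = _background("Gammex Solid Water")
        # outer ring: edge at 12 cm, 5 cm gaps; inner ring: edge at 7 cm,
        # 1.4 cm gaps (brain next to cortical bone, LN-300 radially close
        # to cortical bone, as on the physical phantom)
        placed = _ring(
            12.0 - d / 2,
            ["Adipose", "LN-300", "Breast", "Solid Water 1", "LN-450",
             "Solid Water 2", "Solid Water 3", "Solid Water 4"],
            d, 5.0,
        )
        placed += _ring(
            7.0 - d / 2,
            ["Brain", "Cortical bone", "CB2-30%", "CB2-50%", "B-200",
             "Inner bone", "Liver", "True Water"],
            d, 1.4,
        )
        height = 5.0
    elif name == "george_body":
        outline = PhantomOutline("circle", diameter_cm=27.0)
        bg = _background("Blue Wax")
        placed = _ring(
            10.0 - d / 2,
            ["Brain", "Spinal cord", "Cortical bone", "Enamel",
             "Trabecular bone", "Spinal disk"],
            d, 3.5,
        )
        height = 5.0
    elif name == "george_head":
        outline = PhantomOutline("circle", diameter_cm=18.0)
        bg = _background("Blue Wax")
        ring_r = 7.0 - d / 2
        placed = _ring(
            ring_r,
            ["Brain", "Spinal cord", "Spinal disk", "Trabecular bone",
             "Dentin", "Cortical bone", "Enamel"],
            d, 3.3,
        )
        # sinus: between enamel and cortical bone, pulled radially inward so
        # its edge sits 1.6 cm from each of their edges
        chord = 3.3 + d
        step = 2.0 * math.asin(chord / (2.0 * ring_r))
        c_dist = 1.6 + d / 2 + _GEORGE_HEAD_SINUS_D / 2
        mid_r = ring_r * math.cos(step / 2.0)
        inward = math.sqrt(c_dist**2 - (chord / 2.0) ** 2)
        mid_angle = 5.5 * step  # between ring indices 5 and 6
        r_sinus = mid_r - inward
        placed.append(
            ("Sinus", (r_sinus * math.cos(mid_angle), r_sinus * math.sin(mid_angle)))
        )
        height = 5.0
    elif name == "aed_head":
        outline = PhantomOutline("circle", diameter_cm=20.0)
        bg = _background("AED Solid Water")
        placed = _aed_head_layout(d)
        height = 16.5
    else:  # aed_body
        outline = PhantomOutline("ellipse", width_cm=40.0, height_cm=30.0)
        bg = _background("AED Solid Water")
        placed = _aed_head_layout(d)
        body_names = ["LN-300", "Inner bone", "LN-450", "Liver",
                      "Solid Water 4", "True Water 2"]
        for i, plug in enumerate(body_names):
            a = 2.0 * math.pi * i / len(body_names)
            placed.append((plug, (16.5 * math.cos(a), 11.5 * math.sin(a))))
        height = 16.5

    inserts = []
    for plug, center in placed:
        dia = _GEORGE_HEAD_SINUS_D if (name == "george_head" and plug == "Sinus") else d
        inserts.append(_insert_from_row(name, plug, center, dia))
    return PhantomSpec(
        name=name,
        outline=outline,
        background_material=bg[0],
        background_zeff=bg[1],
        background_red=bg[2],
        inserts=inserts,
        height_cm=height,
    )


# ---------------------------------------------------------------------------
# Voxelization and rendering


def build_label_volume(
    spec: PhantomSpec,
    in_plane_spacing_mm: float = 1.0,
    slice_thickness_mm: float = 2.5,
    n_slices: int = 10,
    margin_mm: float = 10.0,
) -> PropertyVolume:
    """Voxelize a phantom: label 0 = outside, 1 = background, k+2 = insert k.

    Voxel-center-in-shape rule on a grid centered on the phantom axis;
    labels are identical across slices.
    """
    if in_plane_spacing_mm <= 0 or slice_thickness_mm <= 0:
        raise InvalidInputError("spacing must be > 0")
    if n_slices < 1:
        raise InvalidInputError("need at least one slice")
    a, b = spec.outline.semi_axes_cm
    nx = 2 * math.ceil((10.0 * a + margin_mm) / in_plane_spacing_mm) + 1
    ny = 2 * math.ceil((10.0 * b + margin_mm) / in_plane_spacing_mm) + 1
    spacing = (in_plane_spacing_mm, in_plane_spacing_mm, slice_thickness_mm)
    x_cm = (np.arange(nx) - (nx - 1) / 2.0) * in_plane_spacing_mm / 10.0
    y_cm = (np.arange(ny) - (ny - 1) / 2.0) * in_plane_spacing_mm / 10.0

    plane = np.zeros((nx, ny), dtype=np.int16)
    plane[spec.outline.mask(x_cm, y_cm)] = 1
    for k, ins in enumerate(spec.inserts):
        dx = x_cm - ins.center_cm[0]
        dy = y_cm - ins.center_cm[1]
        disk = dx[:, None] ** 2 + dy[None, :] ** 2 <= ins.radius_cm**2
        if np.any(plane[disk] > 1):
            raise GeometryError(
                f"insert {ins.name!r} overlaps another insert after voxelization"
            )
        plane[disk] = k + 2

    values = np.repeat(plane[:, :, None], n_slices, axis=2)
    return PropertyVolume.centered(values, spacing, "label")


def render_property_maps(
    labels: PropertyVolume, spec: PhantomSpec
) -> tuple[PropertyVolume, PropertyVolume]:
    """Piecewise-constant Zeff and RED maps from a label volume."""
    if labels.quantity != "label":
        raise InvalidInputError("expected a label volume")
    n = len(spec.inserts)
    if labels.values.max() > n + 1:
        raise InvalidInputError("label volume inconsistent with spec")
    zeff_lut = np.empty(n + 2)
    red_lut = np.empty(n + 2)
    zeff_lut[0], red_lut[0] = AIR_ZEFF, AIR_RED
    zeff_lut[1], red_lut[1] = spec.background_zeff, spec.background_red
    for k, ins in enumerate(spec.inserts):
        if ins.zeff is None or ins.red is None:
            raise InvalidInputError(f"insert {ins.name!r} lacks assigned values")
        zeff_lut[k + 2] = ins.zeff
        red_lut[k + 2] = ins.red
    lab = labels.values.astype(np.intp)
    return (
        labels.with_values(zeff_lut[lab], "zeff"),
        labels.with_values(red_lut[lab], "red"),
    )


# ---------------------------------------------------------------------------
# Noise and bias


@dataclass(frozen=True)
class NoiseModel:
    """Per-quantity Gaussian noise magnitudes for one acquisition."""

    sigma_zeff: float
    sigma_red: float
    sigma_rsp: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if min(self.sigma_zeff, self.sigma_red, self.sigma_rsp) < 0:
            raise InvalidInputError("noise sigma must be >= 0")


@lru_cache(maxsize=1)
def noise_presets() -> dict[str, NoiseModel]:
    """Measured noise levels keyed ``<preset>_<ctdi>`` (e.g. model467_14.55)."""
    out = {}
    for _, r in load_noise_table().iterrows():
        out[r.key] = NoiseModel(
            sigma_zeff=float(r.sigma_zeff),
            sigma_red=float(r.sigma_red),
            sigma_rsp=float(r.sigma_rsp),
        )
    return out


def add_noise(volume: PropertyVolume, sigma: float, seed: int) -> PropertyVolume:
    """Add i.i.d. zero-mean Gaussian noise; identity for ``sigma == 0``."""
    if sigma < 0:
        raise InvalidInputError("sigma must be >= 0")
    if sigma == 0:
        return volume.with_values(volume.values.copy())
    rng = np.random.default_rng(seed)
    noisy = volume.values + rng.normal(0.0, sigma, size=volume.shape)
    return volume.with_values(noisy)


@dataclass(frozen=True)
class BiasSource:
    """Exponential in-plane bias: ``amplitude * exp(-d / decay)``."""

    center_cm: tuple[float, float]
    amplitude: float = 0.0
    decay_cm: float = 1.0

    def __post_init__(self):
        if self.decay_cm <= 0:
            raise InvalidInputError("decay length must be > 0")


def add_highz_bias(
    volume: PropertyVolume, sources: Sequence[BiasSource]
) -> PropertyVolume:
    """Add smooth positive bias around high-density structures.

    Emulates the residual scatter/beam-hardening shift observed near dense
    inserts; ``amplitude = 0`` sources are no-ops.
    """
    out = volume.values.astype(float).copy()
    for src in sources:
        if src.amplitude == 0.0:
            continue
        d_mm = volume.inplane_distance(
            (10.0 * src.center_cm[0], 10.0 * src.center_cm[1])
        )
        out += (src.amplitude * np.exp(-d_mm / (10.0 * src.decay_cm)))[:, :, None]
    return volume.with_values(out)


# ---------------------------------------------------------------------------
# One-call simulation


@dataclass
class SimulationResult:
    spec: PhantomSpec
    labels: PropertyVolume
    zeff: PropertyVolume
    red: PropertyVolume
    noise: NoiseModel | None
    seed: int


def simulate(
    phantom: str | PhantomSpec,
    noise: str | NoiseModel | None = None,
    seed: int = 0,
    in_plane_spacing_mm: float = 1.0,
    slice_thickness_mm: float = 2.5,
    n_slices: int = 10,
    bias_sources: Sequence[BiasSource] = (),
) -> SimulationResult:
    """Voxelize a phantom and emit noisy (optionally biased) Zeff/RED maps.

    ``noise`` may be a measured-noise key (see :func:`noise_presets`), a
    :class:`NoiseModel`, or None for noiseless maps. The Zeff and RED
    volumes get independent noise streams derived from ``seed``.
    """
    spec = preset_phantom(phantom) if isinstance(phantom, str) else phantom
    if isinstance(noise, str):
        try:
            noise = noise_presets()[noise]
        except KeyError:
            raise KeyError(
                f"unknown noise key {noise!r}; known: {sorted(noise_presets())}"
            ) from None
    labels = build_label_volume(
        spec, in_plane_spacing_mm, slice_thickness_mm, n_slices
    )
    zeff, red = render_property_maps(labels, spec)
    if bias_sources:
        zeff = add_highz_bias(zeff, bias_sources)
        red = add_highz_bias(red, bias_sources)
    if noise is not None:
        child = np.random.SeedSequence(seed).spawn(2)
        zeff = add_noise(zeff, noise.sigma_zeff, child[0])
        red = add_noise(red, noise.sigma_red, child[1])
    return SimulationResult(
        spec=spec, labels=labels, zeff=zeff, red=red, noise=noise, seed=seed
    )


# ---------------------------------------------------------------------------
# YAML round-trip for phantom specs


def _spec_to_dict(spec: PhantomSpec) -> dict:
    o = spec.outline
    outline = {"shape": o.shape}
    if o.shape == "circle":
        outline["diameter_cm"] = o.diameter_cm
    else:
        outline.update(width_cm=o.width_cm, height_cm=o.height_cm)
    return {
        "name": spec.name,
        "outline": outline,
        "background": {
            "material": spec.background_material,
            "zeff": spec.background_zeff,
            "red": spec.background_red,
        },
        "height_cm": spec.height_cm,
        "inserts": [
            {
                "name": i.name,
                "center_cm": list(i.center_cm),
                "diameter_cm": i.diameter_cm,
                "material": i.material,
                "zeff": i.zeff,
                "red": i.red,
                "rsp_ref": i.rsp_ref,
                "rsp_ref_sd": i.rsp_ref_sd,
            }
            for i in spec.inserts
        ],
    }


def save_phantom_spec(spec: PhantomSpec, path):
    with open(path, "w") as fh:
        yaml.safe_dump(_spec_to_dict(spec), fh, sort_keys=False)


def load_phantom_spec(path) -> PhantomSpec:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return PhantomSpec(
        name=d["name"],
        outline=PhantomOutline(**d["outline"]),
        background_material=d["background"]["material"],
        background_zeff=d["background"]["zeff"],
        background_red=d["background"]["red"],
        inserts=[
            InsertSpec(
                name=i["name"],
                center_cm=tuple(i["center_cm"]),
                diameter_cm=i["diameter_cm"],
                material=i.get("material"),
                zeff=i.get("zeff"),
                red=i.get("red"),
                rsp_ref=i.get("rsp_ref"),
                rsp_ref_sd=i.get("rsp_ref_sd"),
            )
            for i in d["inserts"]
        ],
        height_cm=d.get("height_cm", 5.0),
    )
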