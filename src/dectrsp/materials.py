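"""Material tables: bundled elemental constants and tissue-surrogate library.

The delimited material-table format has one row per (material, element) pair
carrying a mass fraction, plus one property row per material (empty element
column) carrying the bulk density and optional manufacturer/measured
reference values:

    material,element,mass_fraction,mass_density,red_ref,zeff_ref,rsp_ref,rsp_ref_sd,in_calibration
    Water,H,0.111894,,,,,,
    Water,O,0.888106,,,,,,
    Water,,,1.000,1.00,7.42,1.000,0.000,1

``red_ref``/``zeff_ref`` are manufacturer-supplied overrides that take
precedence over composition-derived values; ``rsp_ref`` is a beam-measured
RSP. ``in_calibration`` flags materials used to calibrate the default
Zeff -> I correlation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path

from .errors import MaterialTableError
from .physics import (
    Composition,
    ElementalComponent,
    MaterialSpec,
    ZeffICorrelation,
    calibrate_correlation,
)

__all__ = [
    "ElementRecord",
    "element_table",
    "load_material_table",
    "reference_materials",
    "default_correlation",
]


@dataclass(frozen=True)
class ElementRecord:
    symbol: str
    name: str
    atomic_number: int
    atomic_mass: float
    i_value_ev: float


def _data_path(name: str):
    return resources.files("dectrsp.data") / name


@lru_cache(maxsize=1)
def element_table() -> dict[str, ElementRecord]:
    """Bundled elemental Z/A/I table keyed by symbol."""
    table = {}
    with _data_path("elements.csv").open() as fh:
        rows = [r for r in csv.DictReader(_strip_comments(fh))]
    for r in rows:
        rec = ElementRecord(
            symbol=r["symbol"],
            name=r["name"],
            atomic_number=int(r["atomic_number"]),
            atomic_mass=float(r["atomic_mass"]),
            i_value_ev=float(r["i_value_ev"]),
        )
        table[rec.symbol] = rec
    return table


def _strip_comments(fh):
    for line in fh:
        if not line.lstrip().startswith("#"):
            yield line


def _parse_float(value: str, row: int, label: str) -> float | None:
    value = (value or "").strip()
    if not value:
        return None
    try:
        return float(value)
    except ValueError as exc:
        raise MaterialTableError(f"bad {label} {value!r}", row) from exc


def load_material_table(path) -> dict[str, MaterialSpec]:
    """Parse a material table file into named :class:`MaterialSpec` objects.

    Raises :class:`MaterialTableError` (with the 1-based data row number)
    for unknown elements, malformed numbers, or materials lacking both a
    density and a RED override.
    """
    elements = element_table()
    fractions: dict[str, list[tuple[str, float]]] = {}
    props: dict[str, dict] = {}
    order: list[str] = []

    opener = (
        path.open() if hasattr(path, "open") else open(Path(path), newline="")
    )
    with opener as fh:
        reader = csv.DictReader(_strip_comments(fh))
        if reader.fieldnames is None or "material" not in reader.fieldnames:
            raise MaterialTableError("missing header with 'material' column")
        for i, r in enumerate(reader, start=1):
            name = (r.get("material") or "").strip()
            if not name:
                raise MaterialTableError("empty material name", i)
            if name not in fractions:
                fractions[name] = []
                order.append(name)
            elem = (r.get("element") or "").strip()
            if elem:
                if elem not in elements:
                    raise MaterialTableError(f"unknown element {elem!r}", i)
                w = _parse_float(r.get("mass_fraction"), i, "mass_fraction")
                if w is None:
                    raise MaterialTableError("missing mass_fraction", i)
                fractions[name].append((elem, w))
            else:
                props[name] = {
                    "mass_density": _parse_float(r.get("mass_density"), i, "mass_density"),
                    "red_override": _parse_float(r.get("red_ref"), i, "red_ref"),
                    "zeff_override": _parse_float(r.get("zeff_ref"), i, "zeff_ref"),
                    "rsp_ref": _parse_float(r.get("rsp_ref"), i, "rsp_ref"),
                    "rsp_ref_sd": _parse_float(r.get("rsp_ref_sd"), i, "rsp_ref_sd"),
                    "in_calibration": (r.get("in_calibration") or "").strip() in ("1", "true", "yes"),
                    "_row": i,
                }

    out: dict[str, MaterialSpec] = {}
    for name in order:
        p = props.get(name, {})
        comp = None
        if fractions[name]:
            comp = Composition(
                ElementalComponent(
                    symbol=sym,
                    mass_fraction=w,
                    atomic_number=elements[sym].atomic_number,
                    atomic_mass=elements[sym].atomic_mass,
                    i_value_ev=elements[sym].i_value_ev,
                )
                for sym, w in fractions[name]
            )
        if p.get("mass_density") is None and p.get("red_override") is None:
            raise MaterialTableError(
                f"material {name!r} has neither mass_density nor red_ref",
                p.get("_row"),
            )
        spec = MaterialSpec(
            name=name,
            composition=comp,
            mass_density=p.get("mass_density"),
            red_override=p.get("red_override"),
            zeff_override=p.get("zeff_override"),
            rsp_ref=p.get("rsp_ref"),
            rsp_ref_sd=p.get("rsp_ref_sd"),
        )
        spec.in_calibration = bool(p.get("in_calibration"))  # type: ignore[attr-defined]
        out[name] = spec
    return out


@lru_cache(maxsize=1)
def reference_materials() -> dict[str, MaterialSpec]:
    """The bundled tissue-surrogate library (compositions, densities, refs)."""
    return load_material_table(_data_path("reference_materials.csv"))


@lru_cache(maxsize=1)
def default_correlation() -> ZeffICorrelation:
    """Zeff -> ln I correlation calibrated on the bundled surrogate set."""
    mats = [
        m
        for m in reference_materials().values()
        if getattr(m, "in_calibration", False) and m.composition is not None
    ]
    return calibrate_correlation(mats)
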