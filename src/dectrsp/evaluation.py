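"""Accuracy evaluation: ROI statistics, percent errors, MAPE, noise, reports.

The evaluation protocol mirrors phantom QA practice: for each insert a
concentric circular ROI covering 60 % of the insert area is contoured
across all slices and its mean compared with the insert's reference value
as a signed percent error; inserts are grouped into tissue categories by
reference relative electron density; accuracy per category and overall is
summarized as the mean absolute percent error (MAPE); image noise is the
sample SD of a small central circle; and Body-versus-Head acquisitions are
compared with a paired two-sided Student's t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EvaluationError, InvalidInputError
from .phantom import InsertSpec, PhantomSpec
from .physics import CONSTANTS, ZeffICorrelation, bethe_bloch_rsp
from .reference_tables import load_rsp_reference
from .volume import PropertyVolume

__all__ = [
    "TISSUE_BINS",
    "classify_tissue",
    "percent_error",
    "mape",
    "extract_roi_mean",
    "noise_sigma",
    "paired_t_test",
    "ROIResult",
    "CategoryStats",
    "EvaluationReport",
    "summarize",
    "evaluate_phantom",
    "table_roi_results",
]

#: Tissue-category bins on reference RED (inclusive bounds).
TISSUE_BINS: dict[str, tuple[float, float]] = {
    "air_lung": (0.28, 0.44),
    "fat": (0.93, 0.97),
    "water": (0.99, 1.00),
    "muscle": (1.02, 1.08),
    "bone": (1.09, 1.78),
}
CATEGORY_ORDER = tuple(TISSUE_BINS)


def classify_tissue(reference_red: float) -> str:
    """Assign a tissue category from the reference RED.

    Values inside a bin map to it; values in the gaps (or beyond the ends,
    e.g. an air cavity at 0.20 or dental enamel at 1.875) map to the bin
    with the nearest boundary.
    """
    if reference_red <= 0:
        raise InvalidInputError("reference RED must be > 0")
    best, best_d = None, math.inf
    for name, (lo, hi) in TISSUE_BINS.items():
        if lo <= reference_red <= hi:
            return name
        d = min(abs(reference_red - lo), abs(reference_red - hi))
        if d < best_d:
            best, best_d = name, d
    return best


def percent_error(measured: float, reference: float) -> float:
    """Signed percent error ``100 (measured - reference) / reference``."""
    if reference == 0:
        raise InvalidInputError("reference must be nonzero")
    return 100.0 * (measured - reference) / reference


def mape(percent_errors: Iterable[float]) -> float:
    """Mean absolute percent error of a set of signed percent errors."""
    pe = np.asarray(list(percent_errors), dtype=float)
    if pe.size == 0:
        raise InvalidInputError("need at least one percent error")
    return float(np.mean(np.abs(pe)))


def _roi_mask(volume: PropertyVolume, center_cm, radius_mm: float) -> np.ndarray:
    d = volume.inplane_distance((10.0 * center_cm[0], 10.0 * center_cm[1]))
    return d <= radius_mm


def extract_roi_mean(
    volume: PropertyVolume,
    insert: InsertSpec,
    area_fraction: float = 0.60,
) -> float:
    """Mean over a concentric circular ROI across all slices.

    The ROI diameter is ``sqrt(area_fraction)`` times the insert diameter,
    so the contour covers exactly ``area_fraction`` of the insert area.
    """
    if not (0.0 < area_fraction <= 1.0):
        raise InvalidInputError("area fraction must be in (0, 1]")
    radius_mm = math.sqrt(area_fraction) * 10.0 * insert.radius_cm
    mask = _roi_mask(volume, insert.center_cm, radius_mm)
    n = int(mask.sum())
    if n == 0:
        raise EvaluationError(
            f"ROI for insert {insert.name!r} contains no voxels"
        )
    return float(volume.values[mask, :].mean())


def noise_sigma(
    volume: PropertyVolume,
    center_cm: tuple[float, float] = (0.0, 0.0),
    diameter_cm: float = 2.8,
) -> float:
    """Sample SD (n-1) of voxels in a central circle across all slices.

    The 2.8 cm circle is the default; a 1 cm circle is used when the
    phantom center is itself an insert (measure inside it, away from
    edges).
    """
    mask = _roi_mask(volume, center_cm, 10.0 * diameter_cm / 2.0)
    vals = volume.values[mask, :].ravel()
    if vals.size < 2:
        raise EvaluationError("noise circle holds fewer than 2 voxels")
    return float(vals.std(ddof=1))


def paired_t_test(pairs: Sequence[tuple[float, float]]) -> float:
    """Two-sided paired Student's t-test p-value on (a, b) differences.

    Identical sequences return 1.0 by convention (no difference, no
    scatter); zero-variance differences with nonzero mean are degenerate
    and raise.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise InvalidInputError("need >= 2 (a, b) pairs")
    diff = arr[:, 0] - arr[:, 1]
    if np.all(diff == diff[0]):
        if diff[0] == 0.0:
            return 1.0
        raise EvaluationError(
            "differences have zero variance and nonzero mean"
        )
    return float(stats.ttest_rel(arr[:, 0], arr[:, 1]).pvalue)


# ---------------------------------------------------------------------------
# Result records and aggregation


@dataclass(frozen=True)
class ROIResult:
    """One insert's ROI outcome against its reference value."""

    insert: str
    phantom: str
    sfov: str
    quantity: str
    roi_mean: float
    reference: float
    residual: float
    percent_error: float
    category: str

    @classmethod
    def from_measurement(
        cls, insert, phantom, sfov, quantity, roi_mean, reference, reference_red
    ) -> "ROIResult":
        return cls(
            insert=insert,
            phantom=phantom,
            sfov=sfov,
            quantity=quantity,
            roi_mean=roi_mean,
            reference=reference,
            residual=roi_mean - reference,
            percent_error=percent_error(roi_mean, reference),
            category=classify_tissue(reference_red),
        )


@dataclass(frozen=True)
class CategoryStats:
    category: str
    n: int
    mape: float
    mean_pe: float
    sd_pe: float

    def __post_init__(self):
        if self.n < 1:
            raise InvalidInputError("category with no inserts")
        # a mean of absolute values can never be smaller than |mean|
        assert self.mape >= abs(self.mean_pe) - 1e-12


@dataclass
class EvaluationReport:
    """Aggregate accuracy report: per-insert rows plus summary statistics."""

    rows: list[ROIResult]
    category_stats: list[CategoryStats]
    overall_mape: float
    overall_mape_sd: float
    mean_pe: float
    sd_pe: float
    mean_residual: float
    sd_residual: float
    paired_p: float | None = None
    noise: dict[str, float] = field(default_factory=dict)

    def per_insert_frame(self) -> pd.DataFrame:
        """Per-insert table with study-style rounding (RSP 3 dp, PE 2 dp)."""
        df = pd.DataFrame(
            {
                "phantom": [r.phantom for r in self.rows],
                "insert": [r.insert for r in self.rows],
                "sfov": [r.sfov for r in self.rows],
                "quantity": [r.quantity for r in self.rows],
                "category": [r.category for r in self.rows],
                "roi_mean": [round(r.roi_mean, 3) for r in self.rows],
                "reference": [round(r.reference, 3) for r in self.rows],
                "residual": [round(r.residual, 3) for r in self.rows],
                "percent_error": [round(r.percent_error, 2) for r in self.rows],
            }
        )
        return df

    def category_frame(self) -> pd.DataFrame:
        recs = [
            {
                "category": c.category,
                "n": c.n,
                "mape": round(c.mape, 2),
                "mean_pe": round(c.mean_pe, 2),
                "sd_pe": round(c.sd_pe, 2) if np.isfinite(c.sd_pe) else np.nan,
            }
            for c in self.category_stats
        ]
        recs.append(
            {
                "category": "overall",
                "n": len(self.rows),
                "mape": round(self.overall_mape, 2),
                "mean_pe": round(self.mean_pe, 2),
                "sd_pe": round(self.sd_pe, 2),
            }
        )
        return pd.DataFrame(recs)

    def write(self, out_dir):
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.per_insert_frame().to_csv(out / "per_insert.csv", index=False)
        self.category_frame().to_csv(out / "by_category.csv", index=False)
        return out


def summarize(
    roi_results: Sequence[ROIResult],
    paired_p: float | None = None,
    noise: dict[str, float] | None = None,
) -> EvaluationReport:
    """Aggregate ROI results into per-category and overall statistics.

    All aggregation happens on unrounded values (SDs with the n-1
    denominator); rounding is applied only when tables are written. Rows
    are ordered phantom-then-insert; mixing quantities in one aggregate is
    an error.
    """
    rows = list(roi_results)
    if not rows:
        raise InvalidInputError("no ROI results to summarize")
    if len({r.quantity for r in rows}) > 1:
        raise InvalidInputError("cannot aggregate mixed quantities")
    rows.sort(key=lambda r: (r.phantom, r.insert))

    def _sd(x):
        return float(np.std(x, ddof=1)) if len(x) > 1 else float("nan")

    stats_out = []
    for cat in CATEGORY_ORDER:
        pes = [r.percent_error for r in rows if r.category == cat]
        if not pes:
            continue
        stats_out.append(
            CategoryStats(
                category=cat,
                n=len(pes),
                mape=mape(pes),
                mean_pe=float(np.mean(pes)),
                sd_pe=_sd(pes),
            )
        )
    pes = [r.percent_error for r in rows]
    res = [r.residual for r in rows]
    return EvaluationReport(
        rows=rows,
        category_stats=stats_out,
        overall_mape=mape(pes),
        overall_mape_sd=_sd([abs(p) for p in pes]),
        mean_pe=float(np.mean(pes)),
        sd_pe=_sd(pes),
        mean_residual=float(np.mean(res)),
        sd_residual=_sd(res),
        paired_p=paired_p,
        noise=dict(noise or {}),
    )


def evaluate_phantom(
    volume: PropertyVolume,
    spec: PhantomSpec,
    sfov: str = "body",
    reference: str = "measured",
    correlation: ZeffICorrelation | None = None,
    kinetic_energy_mev: float | None = None,
    area_fraction: float = 0.60,
) -> list[ROIResult]:
    """ROI-evaluate every insert of a phantom on one property volume.

    ``reference`` selects the comparison value: ``"measured"`` uses the
    beam-measured RSP reference carried by the insert (or the assigned
    Zeff/RED for those quantities); ``"theoretical"`` (RSP only) recomputes
    the reference from the insert's assigned Zeff/RED through the same
    correlation and Bethe-Bloch ratio — the pipeline-identity oracle used
    to verify that simulation plus evaluation add no systematic error.
    """
    results = []
    for ins in spec.inserts:
        roi = extract_roi_mean(volume, ins, area_fraction)
        if volume.quantity == "zeff":
            ref = ins.zeff
        elif volume.quantity == "red":
            ref = ins.red
        elif reference == "theoretical":
            if correlation is None:
                raise InvalidInputError(
                    "theoretical RSP reference needs a correlation"
                )
            ref = bethe_bloch_rsp(
                ins.red, float(correlation.i_value(ins.zeff)),
                kinetic_energy_mev, CONSTANTS,
            )
        else:
            ref = ins.rsp_ref
        if ref is None:
            raise EvaluationError(
                f"insert {ins.name!r} lacks a {volume.quantity} reference"
            )
        results.append(
            ROIResult.from_measurement(
                insert=ins.name,
                phantom=spec.name,
                sfov=sfov,
                quantity=volume.quantity,
                roi_mean=roi,
                reference=float(ref),
                reference_red=float(ins.red),
            )
        )
    return results


def table_roi_results(sfov: str = "body") -> list[ROIResult]:
    """ROI results reconstructed from the bundled per-insert study table.

    Residuals and percent errors are taken from the table as printed (they
    were computed from unrounded ROI means upstream, so recomputing them
    from the rounded means would shift the last digit).
    """
    if sfov not in ("body", "head"):
        raise InvalidInputError("sfov must be 'body' or 'head'")
    df = load_rsp_reference()
    rows = []
    for _, r in df.iterrows():
        mean = r[f"rsp_mean_{sfov}"]
        if pd.isna(mean):
            continue
        rows.append(
            ROIResult(
                insert=r.plug,
                phantom=r.phantom,
                sfov=sfov,
                quantity="rsp",
                roi_mean=float(mean),
                reference=float(r.rsp_ref),
                residual=float(r[f"residual_{sfov}"]),
                percent_error=float(r[f"pe_{sfov}"]),
                category=classify_tissue(float(r.red_ref)),
            )
        )
    return rows
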