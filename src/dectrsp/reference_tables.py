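"""Bundled study tables: per-insert RSP references/measurements and noise."""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd

__all__ = ["load_rsp_reference", "load_noise_table"]


def _read(name: str) -> pd.DataFrame:
    with (resources.files("dectrsp.data") / name).open() as fh:
        return pd.read_csv(fh, comment="#")


@lru_cache(maxsize=1)
def load_rsp_reference() -> pd.DataFrame:
    """Per-insert reference values and DECT ROI means per SFOV.

    Columns: preset, phantom, plug, material, red_ref, zeff_ref, rsp_ref,
    rsp_ref_sd, rsp_mean_head, residual_head, pe_head, rsp_mean_body,
    residual_body, pe_body. Head columns are NaN for phantoms scanned only
    with the Body field of view.
    """
    return _read("rsp_reference_table.csv")


@lru_cache(maxsize=1)
def load_noise_table() -> pd.DataFrame:
    """Measured map noise per phantom/dose (sigma of a central circle)."""
    return _read("noise_table.csv")
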