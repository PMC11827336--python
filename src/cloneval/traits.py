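"""Stem volume from field measurements and trait standardization.

Individual tree volume with bark is computed from circumference at breast
height (CBH, cm), total height (TH, m) and a fixed stem taper multiplier:

    VOL (m^3) = (CBH^2 * pi / 40000) * TH * ST

Volume is usually converted to dm^3 and z-standardized before modelling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "compute_volume",
    "compute_volume_dm3",
    "standardize",
    "StandardizedTrait",
    "add_volume_columns",
    "DEFAULT_STEM_TAPER",
]

DEFAULT_STEM_TAPER = 0.45


def compute_volume(cbh_cm, th_m, stem_taper: float = DEFAULT_STEM_TAPER):
    """Total individual volume with bark in cubic metres.

    Accepts scalars or arrays; missing (NaN) measurements yield missing
    volume.  Negative inputs are rejected.
    """
    cbh = np.asarray(cbh_cm, dtype=float)
    th = np.asarray(th_m, dtype=float)
    if not 0.0 < stem_taper <= 1.0:
        raise ValueError(f"stem taper must be in (0, 1], got {stem_taper}")
    if np.any(cbh[np.isfinite(cbh)] < 0) or np.any(th[np.isfinite(th)] < 0):
        raise ValueError("CBH and TH must be non-negative")
    vol = (cbh**2 * np.pi / 40000.0) * th * stem_taper
    if vol.ndim == 0:
        return float(vol)
    return vol


def compute_volume_dm3(cbh_cm, th_m, stem_taper: float = DEFAULT_STEM_TAPER):
    """Volume in cubic decimetres (1 m^3 = 1000 dm^3)."""
    vol = compute_volume(cbh_cm, th_m, stem_taper)
    return vol * 1000.0


@dataclass
class StandardizedTrait:
    """z-scores together with the centring constants used to produce them."""

    values: np.ndarray
    center: float
    scale: float


def standardize(x, ddof: int = 1) -> StandardizedTrait:
    """z-standardize a trait vector: ``z_i = (x_i - mean) / sd``.

    The scale uses the sample (n-1) standard deviation by default.  Missing
    values are ignored when estimating the centre and scale and propagate
    as missing z-scores.
    """
    x = np.asarray(x, dtype=float)
    obs = x[np.isfinite(x)]
    if obs.size < 2:
        raise ValueError("need at least two observed values to standardize")
    mu = float(obs.mean())
    sd = float(obs.std(ddof=ddof))
    if sd == 0.0:
        raise ValueError("trait has zero dispersion; cannot standardize")
    return StandardizedTrait(values=(x - mu) / sd, center=mu, scale=sd)


def add_volume_columns(
    df: pd.DataFrame,
    cbh_col: str = "cbh_cm",
    th_col: str = "th_m",
    stem_taper: float = DEFAULT_STEM_TAPER,
    per_site: bool = False,
    site_col: str = "site",
) -> pd.DataFrame:
    """Augment a phenotype table with vol_m3, vol_dm3 and vol_z columns.

    Trees with a missing CBH or TH (mortality) get missing volumes and are
    meant to be dropped from model rows downstream rather than imputed.
    Standardization is global by default; ``per_site=True`` standardizes
    within each site instead.
    """
    out = df.copy()
    out["vol_m3"] = compute_volume(out[cbh_col].to_numpy(), out[th_col].to_numpy(), stem_taper)
    out["vol_dm3"] = out["vol_m3"] * 1000.0
    if per_site:
        z = np.full(len(out), np.nan)
        for _, idx in out.groupby(site_col).groups.items():
            z[out.index.get_indexer(idx)] = standardize(
                out.loc[idx, "vol_dm3"].to_numpy()
            ).values
        out["vol_z"] = z
    else:
        out["vol_z"] = standardize(out["vol_dm3"].to_numpy()).values
    return out
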