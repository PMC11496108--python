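"""Uptake/release rate estimation from spent vs. control culture medium.

Three routes: fold change of peak areas against a known fresh-medium
concentration, absolute quantification by isotope dilution against a 12C
standard, and direct enzymatic/clinical assays. All rates are normalized to
umol per gram tissue per day, release positive and uptake negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .labeling import P_NATURAL, natural_mid

__all__ = [
    "ExchangeMeasurement",
    "rate_from_foldchange",
    "concentration_by_isotope_dilution",
    "ingest_direct_assay",
    "UnidentifiableError",
]

DEFAULT_WINDOW_H = 22.0  # collection window after the 2-h medium change
DEFAULT_VOLUME_ML = 1.3


class UnidentifiableError(ValueError):
    pass


@dataclass
class ExchangeMeasurement:
    metabolite: str
    rate: float  # umol / g tissue / day; release positive
    sd: float = np.nan
    method: str = "fold_change"  # fold_change | isotope_dilution | direct_assay | literature
    window_h: float = DEFAULT_WINDOW_H
    volume_ml: float = DEFAULT_VOLUME_ML
    tissue_mass_g: float = np.nan

    def __post_init__(self):
        if self.window_h <= 0 or self.volume_ml <= 0:
            raise ValueError("window and volume must be positive")


def _normalize_rate(delta_c_mM: float, volume_ml: float, mass_g: float, window_h: float) -> float:
    """Concentration change (mM = umol/ml) -> umol per gram per day."""
    if mass_g <= 0:
        raise ValueError("tissue mass must be positive")
    return delta_c_mM * volume_ml / (mass_g * window_h) * 24.0


def rate_from_foldchange(
    metabolite: str,
    c_fresh_mM: float,
    fold_change: float,
    tissue_mass_g: float,
    sd_fold: float = np.nan,
    window_h: float = DEFAULT_WINDOW_H,
    volume_ml: float = DEFAULT_VOLUME_ML,
) -> ExchangeMeasurement:
    """Rate from known fresh concentration c and spent/control area ratio f.

    The release-positive concentration change is c*(f-1): f < 1 means the
    metabolite decreased in spent medium (uptake, negative rate).
    """
    if c_fresh_mM < 0 or fold_change < 0:
        raise ValueError("concentration and fold change must be non-negative")
    delta_release = c_fresh_mM * (fold_change - 1.0)
    rate = _normalize_rate(delta_release, volume_ml, tissue_mass_g, window_h)
    sd = (
        _normalize_rate(c_fresh_mM * sd_fold, volume_ml, tissue_mass_g, window_h)
        if np.isfinite(sd_fold)
        else np.nan
    )
    return ExchangeMeasurement(
        metabolite, rate, sd, "fold_change", window_h, volume_ml, tissue_mass_g
    )


def concentration_by_isotope_dilution(
    x_mix: np.ndarray,
    x_spent: np.ndarray,
    c0: float,
    p_nat: float = P_NATURAL,
    min_contrast: float = 1e-3,
) -> tuple[float, float]:
    """Solve (c + c0) x_mix = c x_spent + c0 x0 for the spent concentration c.

    ``x0 = Bin(n, p_nat)`` is the fresh 12C standard's MID. The MI system is
    over-determined; c is the least-squares solution over all MI indices.
    Returns ``(c, residual_norm)``. Raises :class:`UnidentifiableError` when
    the spent labeling is indistinguishable from natural abundance.
    """
    x_mix = np.asarray(x_mix, dtype=float)
    x_spent = np.asarray(x_spent, dtype=float)
    if x_mix.shape != x_spent.shape:
        raise ValueError("MID length mismatch")
    if c0 <= 0:
        raise ValueError("standard concentration must be positive")
    n = len(x_spent) - 1
    x0 = natural_mid(n, p_nat)
    if np.max(np.abs(x_spent - x0)) < min_contrast:
        raise UnidentifiableError(
            "spent-medium labeling indistinguishable from the 12C standard"
        )
    # c * (x_mix - x_spent) = c0 * (x0 - x_mix)
    a = x_mix - x_spent
    b = c0 * (x0 - x_mix)
    denom = float(a @ a)
    if denom < 1e-300:
        raise UnidentifiableError("degenerate mixture: x_mix equals x_spent")
    c = float(a @ b) / denom
    residual = float(np.linalg.norm(c * a - b))
    if c < 0:
        warnings.warn(f"negative concentration {c:.4g} clipped to 0", stacklevel=2)
        c = 0.0
    return c, residual


def ingest_direct_assay(
    table: pd.DataFrame,
    window_h: float = DEFAULT_WINDOW_H,
    volume_ml: float = DEFAULT_VOLUME_ML,
) -> list[ExchangeMeasurement]:
    """Rates from assayed fresh/spent concentrations.

    ``table`` columns: metabolite, c_fresh_mM, c_spent_mM, tissue_mass_g and
    optionally sd_mM. Rows with a missing concentration are skipped with a
    warning.
    """
    out = []
    for _, row in table.iterrows():
        if pd.isna(row.get("c_fresh_mM")) or pd.isna(row.get("c_spent_mM")):
            warnings.warn(
                f"{row.get('metabolite')}: missing assay value, skipped", stacklevel=2
            )
            continue
        delta = float(row["c_spent_mM"]) - float(row["c_fresh_mM"])
        rate = _normalize_rate(delta, volume_ml, float(row["tissue_mass_g"]), window_h)
        sd = np.nan
        if "sd_mM" in table.columns and pd.notna(row["sd_mM"]):
            sd = _normalize_rate(
                float(row["sd_mM"]), volume_ml, float(row["tissue_mass_g"]), window_h
            )
        out.append(
            ExchangeMeasurement(
                str(row["metabolite"]), rate, sd, "direct_assay",
                window_h, volume_ml, float(row["tissue_mass_g"]),
            )
        )
    return out
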