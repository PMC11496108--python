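"""Mass-isotopomer processing: peak areas to corrected MIDs and enrichment.

Pipeline per metabolite: integrate-areas -> fractions; flag colliding MI
peaks using unlabeled control extracts; correct for natural 13C abundance by
inverting the binomial convolution; aggregate replicates.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.stats import binom

__all__ = [
    "P_NATURAL",
    "DataQualityWarning",
    "natural_mid",
    "areas_to_mid",
    "collision_filter",
    "binomial_correct",
    "enrichment",
    "process_peak_areas",
]

P_NATURAL = 0.0107  # natural 13C abundance


class DataQualityWarning(UserWarning):
    pass


def natural_mid(n: int, p_nat: float = P_NATURAL) -> np.ndarray:
    """Binomial MID Bin(n, p_nat) of an unlabeled n-carbon compound."""
    return binom.pmf(np.arange(n + 1), n, p_nat)


def areas_to_mid(areas) -> np.ndarray | None:
    """Normalize integrated MI areas to fractions; None if all areas are zero."""
    a = np.asarray(areas, dtype=float)
    if np.any(a < 0):
        raise ValueError("negative peak area")
    total = a.sum()
    if total == 0:
        return None
    return a / total


def collision_filter(
    unlabeled_mid: np.ndarray,
    threshold: float = 0.05,
    p_nat: float = P_NATURAL,
) -> np.ndarray:
    """Keep/remove decisions for each MI index of a metabolite.

    An MI index i >= 1 is removed when its apparent fraction in the unlabeled
    control exceeds the expected natural-abundance binomial fraction by more
    than ``threshold`` (a colliding peak from an unrelated compound). M0 is
    always kept. Returns a boolean keep-mask of length n+1.
    """
    x = np.asarray(unlabeled_mid, dtype=float)
    n = len(x) - 1
    expected = natural_mid(n, p_nat)
    keep = (x - expected) <= threshold
    keep[0] = True
    return keep


def _binomial_convolution_matrix(n: int, p_nat: float) -> np.ndarray:
    """Lower-triangular L with measured = L @ tracer_only.

    A tracer isotopomer with j labeled carbons has n-j unlabeled atoms, each
    naturally 13C with probability p_nat, so it appears at mass j+k with
    probability Bin(n-j, p_nat)(k).
    """
    L = np.zeros((n + 1, n + 1))
    for j in range(n + 1):
        L[j:, j] = binom.pmf(np.arange(n + 1 - j), n - j, p_nat)
    return L


def binomial_correct(
    measured: np.ndarray,
    p_nat: float = P_NATURAL,
    keep: np.ndarray | None = None,
) -> np.ndarray:
    """Remove natural 13C abundance from a measured MID.

    Inverts the lower-triangular binomial convolution by back-substitution,
    then clips small negatives and renormalizes. Fractions below -0.05 before
    clipping trigger a :class:`DataQualityWarning`. ``keep`` optionally zeroes
    collision-removed MI indices before correction.
    """
    x = np.asarray(measured, dtype=float).copy()
    n = len(x) - 1
    if keep is not None:
        x = np.where(np.asarray(keep, bool), x, 0.0)
        if x.sum() <= 0:
            raise ValueError("all MI fractions removed by collision filter")
        x = x / x.sum()
    if p_nat < 1e-12:  # scipy's binom.pmf overflows for subnormal p
        return x
    L = _binomial_convolution_matrix(n, p_nat)
    corrected = solve_triangular(L, x, lower=True)
    if corrected.min() < -0.05:
        warnings.warn(
            f"natural-abundance correction produced fraction {corrected.min():.3f}",
            DataQualityWarning,
            stacklevel=2,
        )
    corrected = np.clip(corrected, 0.0, None)
    return corrected / corrected.sum()


def enrichment(mid) -> float:
    """13C enrichment e = sum(i * x_i) / n."""
    x = np.asarray(mid, dtype=float)
    n = len(x) - 1
    if n == 0:
        raise ValueError("enrichment undefined for a carbon-free species")
    return float(np.dot(np.arange(n + 1), x) / n)


def process_peak_areas(
    df: pd.DataFrame,
    p_nat: float = P_NATURAL,
    collision_threshold: float = 0.05,
    correct: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Turn a long-format peak-area table into corrected MID and enrichment tables.

    ``df`` columns: metabolite, n_carbons, sample, group, mi, area, labeled
    (bool; False marks unlabeled 12C control extracts). Collision decisions
    are made on the mean unlabeled-control MID per metabolite and applied to
    every sample of that metabolite. Returns ``(mid_table, enrichment_table)``
    where mid_table has one row per metabolite/group/MI with replicate mean
    and sample sd in corrected space.
    """
    required = {"metabolite", "n_carbons", "sample", "group", "mi", "area", "labeled"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"peak table missing columns: {sorted(missing)}")

    mid_rows = []
    enr_rows = []
    for met, sub in df.groupby("metabolite", sort=True):
        n = int(sub["n_carbons"].iloc[0])
        # collision mask from the mean of unlabeled controls
        ctrl = sub[~sub["labeled"]]
        keep = np.ones(n + 1, dtype=bool)
        if len(ctrl):
            ctrl_areas = (
                ctrl.groupby("mi")["area"].mean().reindex(range(n + 1), fill_value=0.0)
            )
            ctrl_mid = areas_to_mid(ctrl_areas.to_numpy())
            if ctrl_mid is not None:
                keep = collision_filter(ctrl_mid, collision_threshold, p_nat)
        else:
            warnings.warn(
                f"{met}: no unlabeled control, keeping all MI peaks",
                DataQualityWarning,
                stacklevel=2,
            )

        labeled = sub[sub["labeled"]]
        per_sample: dict[tuple, np.ndarray] = {}
        for (group, sample), rows in labeled.groupby(["group", "sample"]):
            areas = rows.set_index("mi")["area"].reindex(range(n + 1), fill_value=0.0)
            raw = areas_to_mid(areas.to_numpy())
            if raw is None:
                continue  # missing value, excluded downstream
            mid = binomial_correct(raw, p_nat if correct else 0.0, keep=keep)
            per_sample[(group, sample)] = mid
            enr_rows.append(
                {"metabolite": met, "group": group, "sample": sample,
                 "e": enrichment(mid)}
            )
        groups = sorted({g for g, _ in per_sample})
        for group in groups:
            stack = np.array([m for (g, _), m in sorted(per_sample.items()) if g == group])
            mean = stack.mean(axis=0)
            sd = stack.std(axis=0, ddof=1) if len(stack) > 1 else np.full(n + 1, np.nan)
            for i in range(n + 1):
                mid_rows.append(
                    {"metabolite": met, "n_carbons": n, "group": group, "mi": i,
                     "mean": mean[i], "sd": sd[i], "kept": bool(keep[i])}
                )
    return pd.DataFrame(mid_rows), pd.DataFrame(enr_rows)
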