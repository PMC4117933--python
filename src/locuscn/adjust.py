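"""Cross-population adjustment of segmentation scores.

Segmentation scores computed within one major population (SSP) are on that
population's own scale; scores from the pooled all-population run (SSP_P) are
comparable across populations but noisier (a gene split relative to the
pooled average is zeroed).  Regressing SSP_P on SSP within each population
and taking the fitted values combines the two: the final score inherits the
pooled scale while retaining the within-population segmentation's precision.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PopulationFit:
    """Per-population OLS of SSP_P on SSP."""

    population: str
    intercept: float
    slope: float
    n: int


class ZeroVarianceError(ValueError):
    """SSP has no variance; caller should fall back to unadjusted SSP_P."""


def fit_population_regression(
    ssp: np.ndarray, ssp_p: np.ndarray, population: str = ""
) -> PopulationFit:
    """Ordinary least squares of pooled scores on single-population scores."""
    ssp = np.asarray(ssp, dtype=float)
    ssp_p = np.asarray(ssp_p, dtype=float)
    if ssp.shape != ssp_p.shape or ssp.ndim != 1:
        raise ValueError("ssp and ssp_p must be equal-length vectors")
    if ssp.size < 3:
        raise ValueError("need at least 3 samples to fit a regression")
    if np.var(ssp) == 0:
        raise ZeroVarianceError(
            f"population {population!r}: SSP has zero variance; "
            "use SSP_P unadjusted"
        )
    if np.var(ssp_p) == 0:
        # Flat response: slope 0, intercept at the constant.
        return PopulationFit(population, float(ssp_p[0]), 0.0, ssp.size)
    fit = stats.linregress(ssp, ssp_p)
    return PopulationFit(population, float(fit.intercept), float(fit.slope), ssp.size)


def fit_all_populations(table: pd.DataFrame) -> dict[str, PopulationFit]:
    """Fit each population in a score table (columns population, ssp, ssp_p)."""
    fits: dict[str, PopulationFit] = {}
    for pop, sub in table.groupby("population", sort=True):
        fits[str(pop)] = fit_population_regression(
            sub["ssp"].to_numpy(), sub["ssp_p"].to_numpy(), str(pop)
        )
    return fits


def adjust_scores(
    table: pd.DataFrame, fits: Mapping[str, PopulationFit]
) -> pd.DataFrame:
    """Final score per sample: the population fit evaluated at its SSP.

    The input table needs columns ``sample_id``, ``population``, ``ssp``,
    ``ssp_p``; a ``final`` column is added, original columns are retained.
    """
    missing = sorted(set(table["population"]) - set(fits))
    if missing:
        raise KeyError(f"no regression fit for population(s): {missing}")
    out = table.copy()
    b0 = out["population"].map(lambda p: fits[p].intercept)
    b1 = out["population"].map(lambda p: fits[p].slope)
    out["final"] = b0 + b1 * out["ssp"]
    return out


def fits_to_frame(fits: Mapping[str, PopulationFit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"population": f.population, "b0": f.intercept, "b1": f.slope, "n": f.n}
            for f in fits.values()
        ]
    )
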