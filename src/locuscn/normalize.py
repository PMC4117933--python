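"""Cross-sample normalization of window counts.

Two stages:

1. *Observed read-count ratios* — each sample's window counts are converted to
   within-region proportions (removing coverage differences) and divided by
   the cross-sample median proportion of that window (removing shared,
   window-specific effects such as mappability depression).  Under ideal
   mapping the ratio approximates CN/CN_median.
2. *Standardization* — each sample's ratios are centered and scaled robustly
   (median and 1.4826*MAD over its usable windows).  Because most of the 1-2 Mb
   analysis region is CN-invariant, the robust location/scale approximate the
   sample's diploid baseline, and the standardized value plays the role of a
   z-score downstream.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .windows import CountMatrix, WindowGrid


@dataclass
class RatioMatrix:
    """Observed read-count ratios; masked windows hold NaN and are unusable."""

    grid: WindowGrid
    sample_ids: list[str]
    ratios: np.ndarray  # (n_samples, n_windows); NaN where masked
    mask: np.ndarray    # (n_windows,) True = usable


@dataclass
class StdMatrix:
    """Standardized read-count ratios with the per-sample location/scale used."""

    grid: WindowGrid
    sample_ids: list[str]
    x: np.ndarray       # (n_samples, n_windows); NaN where masked
    mask: np.ndarray
    mu: np.ndarray      # per-sample location (median ratio)
    sigma: np.ndarray   # per-sample scale (1.4826*MAD, with fallbacks)


def compute_ratios(counts: CountMatrix) -> RatioMatrix:
    """Observed read-count ratios from raw window counts.

    ``p[s,j] = c[s,j]/N[s]``; the per-window reference is the median of
    ``p[.,j]`` over the samples of the current run; ``r = p/ref``.  Windows
    whose reference is zero carry no usable signal and are masked.
    """
    if len(counts.sample_ids) < 2:
        raise ValueError("need at least 2 samples to form a cross-sample reference")
    totals = counts.totals.astype(float)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"sample {counts.sample_ids[zero[0]]!r} has zero reads in the region"
        )
    p = counts.counts / totals[:, None]
    ref = np.median(p, axis=0)
    mask = ref > 0
    if not mask.any():
        raise ValueError("all windows masked (zero cross-sample reference everywhere)")
    ratios = np.full(p.shape, np.nan)
    ratios[:, mask] = p[:, mask] / ref[mask]
    return RatioMatrix(counts.grid, list(counts.sample_ids), ratios, mask)


def standardize(ratios: RatioMatrix, min_windows: int = 10) -> StdMatrix:
    """Robust per-sample standardization of ratios.

    Location = median, scale = 1.4826*MAD over the sample's unmasked windows.
    If the MAD is zero the sample standard deviation is used; if that is also
    zero the standardized row is all zeros (a perfectly flat profile carries
    no changepoint signal).
    """
    n_usable = int(ratios.mask.sum())
    if n_usable < min_windows:
        raise ValueError(
            f"only {n_usable} unmasked windows; need at least {min_windows}"
        )
    r = ratios.ratios[:, ratios.mask]
    mu = np.median(r, axis=1)
    mad = np.median(np.abs(r - mu[:, None]), axis=1)
    sigma = 1.4826 * mad
    fallback = sigma == 0
    if fallback.any():
        sigma[fallback] = r[fallback].std(axis=1, ddof=1)
    x = np.full(ratios.ratios.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (r - mu[:, None]) / sigma[:, None]
    z[sigma == 0] = 0.0  # flat profile: define all-zero scores
    x[:, ratios.mask] = z
    return StdMatrix(ratios.grid, list(ratios.sample_ids), x, ratios.mask, mu, sigma)
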