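"""Univariate Gaussian mixture clustering of segmentation scores.

Final segmentation scores fall into roughly equally spaced clusters, one per
integer copy number.  A clear reference population is fitted by EM; the
number of groups can be chosen automatically by BIC, or reconstructed from
the score range and the reference population's inter-group distances.
Samples beyond a user-set upper bound are outliers: they are excluded from
model fitting and pinned to the largest CN group with probability 1.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp


@dataclass
class MixtureModel:
    """Ordered univariate Gaussian mixture (means strictly increasing)."""

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    loglik: float = np.nan
    n_iter: int = 0
    converged: bool = True

    @property
    def K(self) -> int:
        return self.means.size

    @property
    def distances(self) -> np.ndarray:
        """Distances between adjacent component means."""
        return np.diff(self.means)


@dataclass
class CNCalls:
    """Per-sample CN group assignments with posterior probabilities."""

    sample_ids: list[str]
    group: np.ndarray          # 0-based group index
    probs: np.ndarray          # (n, K) assignment probabilities
    outlier: np.ndarray        # True -> pinned to largest group, prob 1
    cn: np.ndarray | None = None
    cn_labels: list[str] | None = None

    @property
    def K(self) -> int:
        return self.probs.shape[1]

    def to_frame(self, populations=None, scores=None) -> pd.DataFrame:
        df = pd.DataFrame({"sample_id": self.sample_ids})
        if populations is not None:
            df["population"] = np.asarray(populations)
        if scores is not None:
            df["final"] = np.asarray(scores)
        df["group"] = self.group
        if self.cn is not None:
            df["cn"] = self.cn
            df["cn_label"] = self.cn_labels
        df["max_prob"] = self.probs[np.arange(len(self.sample_ids)), self.group]
        df["outlier"] = self.outlier
        return df


def _loglik_matrix(x: np.ndarray, means, sds, weights) -> np.ndarray:
    return (
        np.log(weights)[None, :]
        - np.log(sds)[None, :]
        - 0.5 * np.log(2 * np.pi)
        - 0.5 * ((x[:, None] - means[None, :]) / sds[None, :]) ** 2
    )


def _kmeanspp_init(x: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    centers = [x[rng.integers(x.size)]]
    for _ in range(1, K):
        d2 = np.min((x[:, None] - np.array(centers)[None, :]) ** 2, axis=1)
        total = d2.sum()
        if total == 0:
            centers.append(x[rng.integers(x.size)])
            continue
        centers.append(x[rng.choice(x.size, p=d2 / total)])
    return np.sort(np.array(centers))


def em_fit(
    scores: np.ndarray,
    K: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-8,
    max_restarts: int = 10,
    n_init: int = 8,
) -> tuple[MixtureModel, np.ndarray]:
    """EM for a K-component univariate Gaussian mixture.

    ``n_init`` k-means++-style initializations are run from ``seed`` and the
    fit with the best log-likelihood is kept (EM on well-separated clusters
    is prone to local optima from a single start).  Convergence when the
    log-likelihood improves by less than ``tol`` (or after ``max_iter``
    iterations).  A component collapsing onto a point discards that start;
    up to ``max_restarts`` extra starts replace collapsed ones before the
    fit is abandoned.  Components are returned sorted by mean.  The
    log-likelihood is checked to be non-decreasing at every iteration.
    """
    x = np.asarray(scores, dtype=float)
    if x.ndim != 1:
        raise ValueError("scores must be a vector")
    if x.size < 5 * K:
        raise ValueError(f"need at least {5 * K} points for K={K}")
    if K == 1:
        mu, sd = float(x.mean()), float(x.std())
        sd = max(sd, 1e-12)
        ll = float(
            -0.5 * x.size * np.log(2 * np.pi)
            - x.size * np.log(sd)
            - 0.5 * ((x - mu) ** 2).sum() / sd**2
        )
        return (
            MixtureModel(np.array([mu]), np.array([sd]), np.array([1.0]), ll, 0),
            np.ones((x.size, 1)),
        )

    data_range = float(np.ptp(x)) or 1.0
    collapse_floor = 1e-6 * data_range
    rng = np.random.default_rng(seed)
    last_error: Exception | None = None
    best: tuple[MixtureModel, np.ndarray] | None = None
    successes = 0
    for attempt in range(n_init + max_restarts):
        if successes >= n_init:
            break
        means = _kmeanspp_init(x, K, rng)
        sds = np.full(K, max(x.std() / K, collapse_floor * 10))
        weights = np.full(K, 1.0 / K)
        prev_ll = -np.inf
        converged = False
        try:
            for it in range(1, max_iter + 1):
                logp = _loglik_matrix(x, means, sds, weights)
                norm = logsumexp(logp, axis=1)
                ll = float(norm.sum())
                if ll < prev_ll - 1e-6 * max(1.0, abs(prev_ll)):
                    raise RuntimeError("EM log-likelihood decreased")
                resp = np.exp(logp - norm[:, None])
                nk = resp.sum(axis=0)
                if (nk < 2).any():
                    # a component collapsed onto (at most) a single point
                    raise _Collapse
                means = (resp * x[:, None]).sum(axis=0) / nk
                var = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
                sds = np.sqrt(var)
                # a well-populated component sitting on identical values is a
                # point mass, not a failure: clamp its scale at the floor
                sds = np.maximum(sds, collapse_floor)
                weights = nk / x.size
                if abs(ll - prev_ll) < tol:
                    prev_ll = ll
                    converged = True
                    break
                prev_ll = ll
            order = np.argsort(means)
            model = MixtureModel(
                means[order], sds[order], weights[order], prev_ll, it, converged
            )
            successes += 1
            if best is None or model.loglik > best[0].loglik:
                logp = _loglik_matrix(x, model.means, model.sds, model.weights)
                resp = np.exp(logp - logsumexp(logp, axis=1)[:, None])
                best = (model, resp)
        except _Collapse as exc:
            last_error = exc
            continue
    if best is None:
        raise RuntimeError(
            f"EM failed: component collapse in {n_init + max_restarts} starts"
        ) from last_error
    return best


class _Collapse(Exception):
    pass


def bic_select(
    scores: np.ndarray, k_range, seed: int = 0
) -> int:
    """Number of components minimizing BIC = -2*loglik + (3K-1)*ln(n).

    K values too large for the sample (n < 5K) are skipped with a warning;
    ties break toward the smaller K.
    """
    x = np.asarray(scores, dtype=float)
    best_k, best_bic = None, np.inf
    any_fit = False
    for K in sorted(k_range):
        if x.size < 5 * K:
            warnings.warn(f"skipping K={K}: fewer than {5 * K} points")
            continue
        try:
            model, _ = em_fit(x, K, seed=seed)
        except RuntimeError:
            continue
        any_fit = True
        p = 3 * K - 1
        bic = -2.0 * model.loglik + p * np.log(x.size)
        if bic < best_bic:
            best_k, best_bic = K, bic
    if not any_fit:
        raise RuntimeError("no mixture size could be fitted")
    return int(best_k)


def robust_distances(model: MixtureModel) -> np.ndarray:
    """Adjacent-mean distances with intra-cluster artifacts removed.

    When model selection splits a nearly point-like cluster in two, the pair
    of components is separated by a distance far below the true inter-group
    spacing.  Distances smaller than half the median distance are treated as
    such artifacts and dropped, so the mean of the remainder estimates the
    spacing between genuine CN groups.
    """
    d = model.distances
    if d.size <= 1:
        return d
    med = np.median(d)
    keep = d >= 0.5 * med
    return d[keep] if keep.any() else d


def fit_reference_grid(
    model: MixtureModel, distance: float | None = None
) -> tuple[float, float]:
    """Fit an integer-spaced grid to a reference mixture's means.

    Returns ``(spacing, anchor)`` where ``anchor`` is the grid position of
    the lowest occupied group.  Model selection sometimes splits a
    near-degenerate cluster in two; the split not only inserts a spurious
    small gap but also shrinks the adjacent genuine gaps, so neither
    averaging (filtered) distances nor taking the raw lowest mean is
    reliable.  Instead, each component mean is assigned an integer grid
    index — cumulative adjacent-gap counts, each gap rounded to its nearest
    whole number of spacings, so a split cluster contributes a zero step
    and a skipped group a double step.  Components sharing a grid index are
    collapsed to their mixing-weight-weighted mean (for a genuine split
    this recovers the original cluster center exactly, and it keeps a
    low-weight stray component from dragging the group position), and the
    spacing and anchor are the least-squares slope and intercept of the
    collapsed means on grid index.  A known ``distance`` (e.g. a
    user-supplied prior distance) fixes the slope and only the intercept is
    fitted.
    """
    order = np.argsort(model.means)
    m = np.asarray(model.means, dtype=float)[order]
    w = np.asarray(model.weights, dtype=float)[order]
    if m.size < 2:
        if distance is None:
            raise ValueError("need at least two component means")
        return float(distance), float(m[0])
    gaps = np.diff(m)
    d0 = float(distance) if distance is not None else float(np.quantile(gaps, 0.75))
    if d0 <= 0:
        d0 = float(gaps.mean())
    steps = np.round(gaps / d0).astype(int)
    g = np.concatenate([[0], np.cumsum(steps)])
    # collapse components sharing a grid index to their weighted mean
    idx = np.unique(g)
    M = np.array([np.average(m[g == i], weights=w[g == i]) for i in idx])
    G = idx.astype(float)
    if distance is not None:
        d = float(distance)
    elif G.size < 2:
        d = float(gaps.mean())
    else:
        gc = G - G.mean()
        d = float((gc * (M - M.mean())).sum() / (gc * gc).sum())
    anchor = float((M - d * G).mean())
    return d, anchor


def estimate_grid_spacing(model: MixtureModel) -> float:
    """Inter-group spacing of a reference fit (see :func:`fit_reference_grid`)."""
    return fit_reference_grid(model)[0]


def choose_K(
    score_min: float, score_max: float, ref_distances: np.ndarray
) -> int:
    """Group count from the score range and reference inter-group distances.

    ``K = max(1, round((score_max - score_min) / mean(ref_distances)))``.
    Outliers must be removed from the range beforehand (see
    :func:`detect_outliers`).
    """
    d = np.asarray(ref_distances, dtype=float)
    if d.size == 0 or (d <= 0).any():
        raise ValueError("ref_distances must be non-empty and positive")
    if score_max < score_min:
        raise ValueError("score_max must be >= score_min")
    return max(1, round((score_max - score_min) / d.mean()))


def detect_outliers(
    scores: np.ndarray, upper_bound: float
) -> tuple[np.ndarray, np.ndarray]:
    """Flag scores above ``upper_bound``.

    Returns ``(kept_values, outlier_indices)``.  Flagged samples are excluded
    from group-count selection and model fitting, and are later pinned to the
    largest CN group with probability 1.
    """
    x = np.asarray(scores, dtype=float)
    if not np.isfinite(upper_bound):
        raise ValueError("upper_bound must be finite")
    out = np.flatnonzero(x > upper_bound)
    if out.size == x.size:
        raise ValueError("all scores flagged as outliers")
    kept = np.delete(x, out)
    return kept, out


def assign_cn(calls: CNCalls, cn_of_first_group: int) -> CNCalls:
    """Map 0-based group indices to integer CN.

    ``CN = group + cn_of_first_group``.  The largest group is an open class
    ("CN or more"): outliers were pinned to it, so its label carries a ">="
    prefix when the model has more than one group.
    """
    if cn_of_first_group < 0:
        raise ValueError("cn_of_first_group must be >= 0")
    calls.cn = calls.group + cn_of_first_group
    top = calls.K - 1
    labels = []
    for g in calls.group:
        cn = int(g) + cn_of_first_group
        if g == top and calls.K > 1:
            labels.append(f">={cn}")
        else:
            labels.append(str(cn))
    calls.cn_labels = labels
    return calls
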