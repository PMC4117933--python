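"""Bayesian ordered Gaussian mixture via Gibbs sampling.

For cohorts with many CN groups the EM fit of a single population is used to
build priors for the full cohort: the ordered component means get Normal
priors on an equally spaced grid (anchor mean plus multiples of the prior
inter-group distance), component variances get inverse-gamma priors matched
to the reference within-group variances, and the mixing proportions get a
symmetric Dirichlet(1) prior.  Latent assignments, means (truncated to keep
the ordering), variances and proportions are sampled in turn.

The schedule mirrors common practice for this model: a short adaptive phase,
a burn-in, a long sampling run, with parameter estimates taken from the final
fraction of sampling iterations (defaults: 100 / 1000 / 20000, retaining the
last 20%, i.e. 4000 draws).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr, ndtri

from .mixture import CNCalls, MixtureModel


@dataclass
class PriorSpec:
    """Reference-derived prior information for the ordered mixture."""

    ref_means: np.ndarray
    ref_vars: np.ndarray
    distance: float               # prior inter-group distance d
    anchor_mean: float            # prior mean of the lowest component
    mean_prior_var: float | None = None  # default: mean of ref_vars
    sigma_shape: float = 3.0      # inverse-gamma shape for component variances

    def __post_init__(self) -> None:
        self.ref_means = np.asarray(self.ref_means, dtype=float)
        self.ref_vars = np.asarray(self.ref_vars, dtype=float)
        if self.distance <= 0:
            raise ValueError("prior distance must be positive")
        if self.mean_prior_var is None:
            self.mean_prior_var = float(self.ref_vars.mean())
        if self.mean_prior_var <= 0:
            raise ValueError("mean_prior_var must be positive")

    @classmethod
    def from_reference(
        cls,
        model: MixtureModel,
        distance: float | None = None,
        data: np.ndarray | None = None,
    ) -> "PriorSpec":
        """Build priors from a reference-population EM fit.

        Spacing and anchor come from the reference's fitted integer grid
        (see :func:`locuscn.mixture.fit_reference_grid`), which is robust to
        model selection splitting a tight cluster; a supplied ``distance``
        fixes the spacing and only the anchor is fitted.  If ``data`` (the
        pooled cohort's outlier-free final scores) is given, the anchor is
        shifted down by whole multiples of the distance when the cohort has
        a populated cluster below the reference's lowest group (the
        reference population may simply lack the lowest CN class): the
        candidate is the lowest kernel-density mode among the scores below
        the anchor that sits more than half a spacing below it and is
        supported by at least three samples (or 1% of the cohort).  A mode
        within half a spacing of the anchor is the anchor group itself, and
        a sparser dip — including the corner case of a single sample about
        one spacing down — is treated as a tail or outlier, not a group;
        supply an explicit K with a matching ``cn_of_first_group``, or an
        outlier bound, for cohorts where that reading is wrong.
        """
        from .mixture import fit_reference_grid

        if model.K < 2 and distance is None:
            raise ValueError(
                "reference fit has a single group; supply a prior distance"
            )
        d, anchor = fit_reference_grid(model, distance)
        if data is not None and d > 0:
            shift = _missing_lower_groups(np.asarray(data, dtype=float),
                                          anchor, d)
            anchor -= shift * d
        return cls(model.means, model.sds**2, d, anchor)


def _missing_lower_groups(x: np.ndarray, anchor: float, d: float) -> int:
    """Number of grid spacings to extend the prior grid below ``anchor``.

    Scores more than half a spacing below the anchor are candidates for a
    CN group the reference population lacks.  They count as a group when
    (a) there are at least max(3, 1% of n) of them — a single straggler is
    a tail or outlier, not a group — and (b) their median sits at least
    0.7 spacings below the anchor, which a genuine missing group always
    clears (its center lies a whole spacing down, give or take grid-fit
    error) while the sub-cut tail of the anchor group itself does not.
    The threshold is deliberately conservative: a missed shift miscalls
    only the few bottom-cluster samples, whereas a spurious shift moves
    every call in the cohort by one.
    """
    below = x[x < anchor - 0.5 * d]
    if below.size < max(3, int(0.01 * x.size)):
        return 0
    r = (anchor - float(np.median(below))) / d
    return round(r) if r >= 0.7 else 0


@dataclass
class MCMCSettings:
    n_adapt: int = 100
    n_burnin: int = 1000
    n_iter: int = 20000
    retain_fraction: float = 0.20
    seed: int = 0

    @property
    def n_retain(self) -> int:
        return int(round(self.retain_fraction * self.n_iter))


@dataclass
class GibbsResult:
    model: MixtureModel          # posterior means of the parameters
    calls: CNCalls               # argmax assignment over retained draws
    chains: dict[str, np.ndarray]  # retained draws: mu, sigma, pi
    warnings: list[str] = field(default_factory=list)


def _sample_truncated_normal(
    mean: float, sd: float, lo: float, hi: float, rng: np.random.Generator
) -> float:
    a = ndtr((lo - mean) / sd) if np.isfinite(lo) else 0.0
    b = ndtr((hi - mean) / sd) if np.isfinite(hi) else 1.0
    if b - a < 1e-12:
        # Interval mass numerically zero: pin to the nearest admissible value.
        return min(max(mean, lo + 1e-9 * sd), hi - 1e-9 * sd)
    u = rng.uniform(a, b)
    return mean + sd * float(ndtri(u))


def gibbs_fit(
    scores: np.ndarray,
    K: int,
    prior: PriorSpec,
    settings: MCMCSettings | None = None,
    sample_ids: list[str] | None = None,
) -> GibbsResult:
    """Fit the ordered K-component mixture by Gibbs sampling.

    Returns posterior-mean parameters, per-sample group probabilities
    (posterior assignment frequencies over the retained draws; CN call =
    argmax with ties broken toward the lower group), and the retained chains.
    """
    x = np.asarray(scores, dtype=float)
    n = x.size
    if n == 0:
        raise ValueError("no scores to fit")
    if K < 1:
        raise ValueError("K must be >= 1")
    settings = settings or MCMCSettings()
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    rng = np.random.default_rng(settings.seed)

    d = prior.distance
    prior_mu = prior.anchor_mean + d * np.arange(K)
    s0sq = float(prior.mean_prior_var)
    a0 = float(prior.sigma_shape)
    b0 = (a0 - 1.0) * float(prior.ref_vars.mean())  # IG mean matches ref var

    mu = prior_mu.copy()
    var = np.full(K, float(prior.ref_vars.mean()))
    pi = np.full(K, 1.0 / K)

    total = settings.n_adapt + settings.n_burnin + settings.n_iter
    n_retain = settings.n_retain
    retain_from = total - n_retain

    chain_mu = np.empty((n_retain, K))
    chain_sigma = np.empty((n_retain, K))
    chain_pi = np.empty((n_retain, K))
    assign_counts = np.zeros((n, K), dtype=np.int64)
    empty_draws = 0

    rows = np.arange(n)
    for it in range(total):
        # latent assignments
        logp = (
            np.log(pi)[None, :]
            - 0.5 * np.log(var)[None, :]
            - 0.5 * (x[:, None] - mu[None, :]) ** 2 / var[None, :]
        )
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        p /= p.sum(axis=1, keepdims=True)
        u = rng.random(n)
        z = (u[:, None] > np.cumsum(p, axis=1)).sum(axis=1)
        z = np.minimum(z, K - 1)

        nk = np.bincount(z, minlength=K)
        sums = np.bincount(z, weights=x, minlength=K)

        # ordered means: truncated-normal conditionals, sweeping upward
        for k in range(K):
            prec = nk[k] / var[k] + 1.0 / s0sq
            m_post = (sums[k] / var[k] + prior_mu[k] / s0sq) / prec
            sd_post = 1.0 / np.sqrt(prec)
            lo = mu[k - 1] if k > 0 else -np.inf
            hi = mu[k + 1] if k < K - 1 else np.inf
            mu[k] = _sample_truncated_normal(m_post, sd_post, lo, hi, rng)

        # component variances: inverse-gamma conditionals
        ssq = np.bincount(z, weights=(x - mu[z]) ** 2, minlength=K)
        shape = a0 + 0.5 * nk
        rate = b0 + 0.5 * ssq
        var = rate / rng.gamma(shape)

        # mixing proportions
        pi = rng.dirichlet(1.0 + nk)

        if not (np.isfinite(mu).all() and np.isfinite(var).all()):
            raise RuntimeError(f"Gibbs chain returned non-finite values at {it}")

        if it >= retain_from:
            r = it - retain_from
            chain_mu[r] = mu
            chain_sigma[r] = np.sqrt(var)
            chain_pi[r] = pi
            assign_counts[rows, z] += 1
            if (nk == 0).any():
                empty_draws += 1

    warnings_out: list[str] = []
    if n_retain and empty_draws > 0.5 * n_retain:
        warnings_out.append(
            f"component empty in {empty_draws}/{n_retain} retained draws"
        )

    probs = assign_counts / max(n_retain, 1)
    group = np.argmax(probs, axis=1)  # ties resolve to the lower group
    model = MixtureModel(
        chain_mu.mean(axis=0),
        chain_sigma.mean(axis=0),
        chain_pi.mean(axis=0),
    )
    calls = CNCalls(
        list(sample_ids), group, probs, np.zeros(n, dtype=bool)
    )
    chains = {"mu": chain_mu, "sigma": chain_sigma, "pi": chain_pi}
    return GibbsResult(model, calls, chains, warnings_out)
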