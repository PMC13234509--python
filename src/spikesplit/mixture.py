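"""Two-component univariate Gaussian mixture fitting by EM.

A quantitative spike trait measured across an F2 population is modelled as a
mixture of two normal distributions with distinct means and variances — one
per putative genotype class.  Maximum-likelihood fitting is by
expectation-maximization: the E-step computes per-observation posterior
responsibilities, the M-step re-estimates weights, means and variances from
responsibility-weighted moments.  The log-likelihood is non-decreasing across
iterations; fits are restarted from jittered initializations and the best
likelihood wins.  Observations are assigned to components by maximum
posterior, and the resulting group sizes feed the Mendelian ratio chi-square
test.

Component 1 is always the component with the *smaller* mean, so for an awn
area trait group 1 is the "fewer awns" group and group 2 the "more awns"
group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .segregation import SegregationCounts

__all__ = [
    "GaussianComponent",
    "MixtureFit",
    "em_fit",
    "split_counts",
    "mixture_to_segregation",
]

#: Relative log-likelihood change below which EM is declared converged.
DEFAULT_TOL = 1e-8
DEFAULT_MAX_ITER = 500
DEFAULT_RESTARTS = 10
#: Variance floor as a fraction of the sample variance; prevents a component
#: collapsing onto a single observation (likelihood singularity).
VARIANCE_FLOOR_FRACTION = 1e-6


@dataclass(frozen=True)
class GaussianComponent:
    """One mixture component in trait units."""

    mean: float
    variance: float
    weight: float

    def __post_init__(self) -> None:
        if self.variance <= 0:
            raise ValueError(f"variance must be positive, got {self.variance}")
        if not (0.0 < self.weight < 1.0):
            raise ValueError(f"weight must be in (0, 1), got {self.weight}")


@dataclass(frozen=True)
class MixtureFit:
    """A fitted two-component mixture with per-observation assignments.

    ``components`` are ordered by ascending mean; ``assignments[i]`` is 0 for
    component 1 (smaller mean) and 1 for component 2.  ``log_likelihood_trace``
    records the per-iteration log-likelihood of the winning restart and is
    non-decreasing.
    """

    components: tuple[GaussianComponent, GaussianComponent]
    assignments: np.ndarray
    responsibilities: np.ndarray
    log_likelihood: float
    log_likelihood_trace: np.ndarray
    n_iter: int
    converged: bool
    seed: int

    @property
    def n(self) -> int:
        return len(self.assignments)

    def __post_init__(self) -> None:
        c1, c2 = self.components
        if c1.mean > c2.mean:
            raise ValueError("components must be ordered by ascending mean")
        if abs(c1.weight + c2.weight - 1.0) > 1e-9:
            raise ValueError("component weights must sum to 1")


def _log_density(x: np.ndarray, means: np.ndarray, variances: np.ndarray) -> np.ndarray:
    """Column j = log N(x | means[j], variances[j])."""
    return -0.5 * (np.log(2.0 * np.pi * variances) + (x[:, None] - means) ** 2 / variances)


def _em_once(
    x: np.ndarray,
    means: np.ndarray,
    variances: np.ndarray,
    weights: np.ndarray,
    tol: float,
    max_iter: int,
    var_floor: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[float], bool]:
    trace: list[float] = []
    log_resp = np.empty((len(x), 2))
    converged = False
    ll_prev = -np.inf
    for _ in range(max_iter):
        # E-step
        log_joint = _log_density(x, means, variances) + np.log(weights)
        log_norm = logsumexp(log_joint, axis=1)
        ll = float(np.sum(log_norm))
        trace.append(ll)
        log_resp = log_joint - log_norm[:, None]
        resp = np.exp(log_resp)
        # M-step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        weights = nk / len(x)
        means = (resp * x[:, None]).sum(axis=0) / nk
        variances = (resp * (x[:, None] - means) ** 2).sum(axis=0) / nk
        variances = np.maximum(variances, var_floor)
        if np.isfinite(ll_prev) and abs(ll - ll_prev) <= tol * max(abs(ll), 1.0):
            converged = True
            break
        ll_prev = ll
    # final log-likelihood/responsibilities under the last parameter update
    log_joint = _log_density(x, means, variances) + np.log(weights)
    log_norm = logsumexp(log_joint, axis=1)
    trace.append(float(np.sum(log_norm)))
    resp = np.exp(log_joint - log_norm[:, None])
    return means, variances, weights, resp, trace, converged


def em_fit(
    values,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    restarts: int = DEFAULT_RESTARTS,
    seed: int = 0,
    k: int = 2,
) -> MixtureFit:
    """Fit a two-component Gaussian mixture by maximum likelihood.

    Initialization places the component means at the 25th and 75th sample
    percentiles with the sample variance as a shared initial variance and
    equal weights; ``restarts - 1`` further starts draw jittered percentile
    pairs from a generator seeded with ``seed``.  The restart with the best
    final log-likelihood is returned, components ordered by ascending mean.

    Parameters
    ----------
    values:
        At least 8 finite, not-all-identical observations.
    tol:
        Convergence threshold on the relative log-likelihood change.
    max_iter, restarts, seed:
        EM iteration cap, number of initializations, and the seed driving the
        jittered restarts.
    k:
        Reserved for future use; only ``k=2`` is supported.
    """
    if k != 2:
        raise NotImplementedError("only two-component mixtures are supported (k=2)")
    x = np.asarray(values, dtype=float).ravel()
    if len(x) < 8:
        raise ValueError(f"need at least 8 observations, got {len(x)}")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    if np.ptp(x) == 0.0:
        raise ValueError("all values identical: degenerate mixture")
    sample_var = float(np.var(x))
    var_floor = VARIANCE_FLOOR_FRACTION * sample_var

    rng = np.random.default_rng(seed)
    inits: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = [
        (
            np.percentile(x, [25.0, 75.0]),
            np.array([sample_var, sample_var]),
            np.array([0.5, 0.5]),
        )
    ]
    for _ in range(max(0, restarts - 1)):
        lo, hi = np.sort(rng.uniform(5.0, 95.0, size=2))
        means0 = np.percentile(x, [lo, hi])
        if means0[0] == means0[1]:  # flat percentile stretch; nudge apart
            means0 = means0 + np.array([-0.5, 0.5]) * np.sqrt(sample_var)
        w0 = rng.uniform(0.2, 0.8)
        inits.append((means0, np.array([sample_var, sample_var]), np.array([w0, 1.0 - w0])))

    best = None
    for means0, vars0, weights0 in inits:
        means, variances, weights, resp, trace, converged = _em_once(
            x, means0.copy(), vars0.copy(), weights0.copy(), tol, max_iter, var_floor
        )
        if best is None or trace[-1] > best[4][-1]:
            best = (means, variances, weights, resp, trace, converged)

    means, variances, weights, resp, trace, converged = best
    order = np.argsort(means)
    means, variances, weights = means[order], variances[order], weights[order]
    # a near-empty component keeps an infinitesimal but valid weight
    weights = np.clip(weights, 1e-12, 1.0 - 1e-12)
    resp = resp[:, order]
    assignments = np.argmax(resp, axis=1)
    components = (
        GaussianComponent(float(means[0]), float(variances[0]), float(weights[0])),
        GaussianComponent(float(means[1]), float(variances[1]), float(weights[1])),
    )
    return MixtureFit(
        components=components,
        assignments=assignments,
        responsibilities=resp,
        log_likelihood=float(trace[-1]),
        log_likelihood_trace=np.asarray(trace),
        n_iter=len(trace) - 1,
        converged=converged,
        seed=seed,
    )


def split_counts(fit: MixtureFit) -> tuple[int, int]:
    """(num1, num2): observations assigned by maximum posterior to each component."""
    counts = np.bincount(fit.assignments, minlength=2)
    return int(counts[0]), int(counts[1])


def mixture_to_segregation(
    fit: MixtureFit,
    trait: str = "trait",
    dominant_component: int | None = None,
) -> SegregationCounts:
    """Convert a mixture split into counts for the ratio chi-square test.

    By default the larger group takes the dominant (first) slot, mirroring the
    convention of assigning the majority phenotype class the 3-part of a 3:1
    ratio.  Pass ``dominant_component`` (1 or 2) to force an orientation, e.g.
    when the recessive phenotype is known to be the high-mean group.
    """
    num1, num2 = split_counts(fit)
    if dominant_component is None:
        observed = (num1, num2) if num1 >= num2 else (num2, num1)
    elif dominant_component == 1:
        observed = (num1, num2)
    elif dominant_component == 2:
        observed = (num2, num1)
    else:
        raise ValueError(f"dominant_component must be 1 or 2, got {dominant_component}")
    return SegregationCounts(trait=trait, observed=observed)
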