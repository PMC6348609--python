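"""Node-age priors on a fixed topology: uniform and conditioned birth-death.

Both priors condition on the root age (which is governed by its calibration
window) and place a density on the ages of the remaining internal nodes:

* **uniform** — flat over every age vector compatible with the topology
  ordering, i.e. each internal non-root age anywhere in (0, root age) subject
  to parents being older than children;
* **birth-death** — each internal non-root age i.i.d. from the conditioned
  birth-death node-age kernel (speciation ``lambda``, extinction ``mu``, full
  sampling), again truncated to order-compatible vectors.  With ``d = lambda
  - mu`` the kernel is proportional to ``lambda * p1(t)`` with ``p1(t) = d^2
  e^{-d t} / (lambda - mu e^{-d t})^2``, normalized on (0, root age); the
  ``lambda = mu`` limit is ``p1(t) = 1/(1 + lambda t)^2``.

The i.i.d.-kernel-times-order-indicator construction is the one used by
mainstream node-dating software.  A rejection sampler over the same density
doubles as the independent oracle for prior-only MCMC on small trees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .trees import Chronogram, Topology, ages_are_valid

__all__ = [
    "TreePriorParams",
    "uniform_age_log_prior",
    "bd_kernel_density",
    "bd_age_log_prior",
    "sample_ages_under_prior",
    "RejectionError",
]

_EPS_D = 1e-10                        # |lambda - mu| below this uses the limit


class RejectionError(RuntimeError):
    """Rejection sampling exceeded its attempt cap."""


@dataclass(frozen=True)
class TreePriorParams:
    """Tree-process prior: ``kind`` "uniform" or "bd" (+ lambda, mu per Ma)."""

    kind: str = "uniform"
    lam: float = 0.01
    mu: float = 0.005

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "bd"):
            raise ValueError(f"unknown tree prior kind {self.kind!r}")
        if self.kind == "bd":
            if self.lam <= 0:
                raise ValueError("birth rate lambda must be positive")
            if self.mu < 0:
                raise ValueError("death rate mu must be non-negative")


def uniform_age_log_prior(chron: Chronogram) -> float:
    """Uniform node-age prior conditional on the root age.

    Internal non-root ages are i.i.d. uniform on (0, root age) truncated to
    order-compatible vectors, so the density is ``root_age ** -n_inner``
    (times an ordering constant) — the root's own marginal is then governed
    entirely by its calibration.  ``-inf`` for order-incompatible vectors.
    """
    topo = chron.topology
    if not ages_are_valid(topo, chron.ages):
        return -np.inf
    n_inner = len(topo.internal_nodes) - 1
    return -n_inner * float(np.log(chron.root_age))


# ---------------------------------------------------------------------------
# conditioned birth-death node-age kernel
# ---------------------------------------------------------------------------

def _kernel_cdf_unnorm(t: np.ndarray, lam: float, mu: float) -> np.ndarray:
    """Integral of lambda * p1 over (0, t] (unnormalized kernel CDF)."""
    t = np.asarray(t, dtype=float)
    d = lam - mu
    if abs(d) < _EPS_D or abs(d) < 1e-8 * lam:
        return lam * t / (1.0 + lam * t)
    if mu == 0.0:
        return -np.expm1(-lam * t)
    z = -d * t
    # 1/(lam - mu e^z) -> 0 as z -> +inf (subcritical d < 0)
    with np.errstate(over="ignore"):
        inv = np.where(z > 500.0, 0.0, 1.0 / (lam - mu * np.exp(np.minimum(z, 500.0))))
    return (lam * d / mu) * (1.0 / (lam - mu) - inv)


def bd_kernel_density(t: float | np.ndarray, root_age: float,
                      lam: float, mu: float) -> float | np.ndarray:
    """Conditioned birth-death node-age kernel density on (0, root_age).

    Normalized to integrate to 1 on the interval; raises outside it.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr <= 0) or np.any(t_arr >= root_age):
        raise ValueError("node age must lie strictly inside (0, root_age)")
    norm = _kernel_cdf_unnorm(np.array(root_age), lam, mu)
    d = lam - mu
    if abs(d) < _EPS_D or abs(d) < 1e-8 * lam:
        dens = lam / (1.0 + lam * t_arr) ** 2 / norm
    else:
        x = np.exp(-d * t_arr)
        dens = lam * d * d * x / (lam - mu * x) ** 2 / norm
    return float(dens) if np.isscalar(t) else dens


def _bd_kernel_logpdf(t: np.ndarray, root_age: float, lam: float, mu: float
                      ) -> np.ndarray:
    """Stable log of the normalized kernel (handles mu >> lambda)."""
    t = np.asarray(t, dtype=float)
    log_norm = math.log(float(_kernel_cdf_unnorm(np.array(root_age), lam, mu)))
    d = lam - mu
    if abs(d) < _EPS_D or abs(d) < 1e-8 * lam:
        return math.log(lam) - 2.0 * np.log1p(lam * t) - log_norm
    z = -d * t
    with np.errstate(over="ignore"):
        log_denom = np.where(
            z > 500.0, math.log(mu) + z,
            np.log(np.abs(lam - mu * np.exp(np.minimum(z, 500.0)))))
    return (math.log(lam) + 2.0 * math.log(abs(d)) + z - 2.0 * log_denom
            - log_norm)


def _bd_kernel_ppf(u: np.ndarray, root_age: float, lam: float, mu: float
                   ) -> np.ndarray:
    """Inverse CDF of the normalized kernel (vectorized, closed form)."""
    u = np.asarray(u, dtype=float)
    g = u * _kernel_cdf_unnorm(np.array(root_age), lam, mu)
    d = lam - mu
    if abs(d) < _EPS_D or abs(d) < 1e-8 * lam:
        return g / (lam * (1.0 - g))
    if mu == 0.0:
        return -np.log1p(-g) / lam
    y = g * mu / (lam * d)
    x = (lam - 1.0 / (1.0 / (lam - mu) - y)) / mu
    return -np.log(x) / d


def bd_age_log_prior(chron: Chronogram, params: TreePriorParams) -> float:
    """Sum of log kernel densities over internal non-root nodes.

    ``-inf`` when the topology ordering is violated; the root age itself is
    conditioned on (its density comes from the root calibration).
    """
    if params.kind != "bd":
        raise ValueError("bd_age_log_prior requires a birth-death prior")
    topo = chron.topology
    if not ages_are_valid(topo, chron.ages):
        return -np.inf
    inner = [n for n in topo.internal_nodes if n != topo.root]
    if not inner:
        return 0.0
    ages = chron.ages[inner]
    if np.any(ages <= 0) or np.any(ages >= chron.root_age):
        return -np.inf
    return float(np.sum(_bd_kernel_logpdf(ages, chron.root_age,
                                          params.lam, params.mu)))


def tree_age_log_prior(chron: Chronogram, params: TreePriorParams) -> float:
    """Dispatch on prior kind (uniform / birth-death)."""
    if params.kind == "uniform":
        return uniform_age_log_prior(chron)
    return bd_age_log_prior(chron, params)


# ---------------------------------------------------------------------------
# reference rejection sampler (oracle for prior-only MCMC; small trees)
# ---------------------------------------------------------------------------

def sample_ages_under_prior(topology: Topology, params: TreePriorParams,
                            calset, n: int, seed: int | np.random.Generator,
                            max_attempts: int = 5_000_000):
    """Draw ``n`` chronograms from the calibration-truncated tree prior.

    Exact rejection sampling: root age uniform in the root window, remaining
    internal ages i.i.d. (uniform or birth-death kernel), accepted when the
    topology ordering and every calibration (including relative constraints)
    hold.  Intended as a validation oracle on small trees; aborts with
    :class:`RejectionError` if the acceptance rate is too low.
    """
    from .calibrations import ResolvedCalibrations  # local import, no cycle

    if not isinstance(calset, ResolvedCalibrations):
        calset = calset.resolve(topology)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    root = topology.root
    inner = np.array([v for v in topology.internal_nodes if v != root], dtype=int)
    lo, hi = calset.root_bounds
    out: list[Chronogram] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > max_attempts:
            raise RejectionError(
                f"rejection sampler drew {attempts - 1} proposals for "
                f"{len(out)}/{n} accepted samples; prior and calibrations "
                "are too constraining for rejection sampling")
        ages = np.zeros(topology.n_nodes)
        ages[root] = rng.uniform(lo, hi)
        if inner.size:
            if params.kind == "uniform":
                ages[inner] = rng.uniform(0.0, ages[root], size=inner.size)
            else:
                ages[inner] = _bd_kernel_ppf(rng.uniform(size=inner.size),
                                             ages[root], params.lam, params.mu)
        if not ages_are_valid(topology, ages):
            continue
        if not calset.satisfied(ages):
            continue
        out.append(Chronogram(topology=topology, ages=ages.copy()))
    return out
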