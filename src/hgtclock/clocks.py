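"""Relaxed-clock branch-rate models: UGAM and autocorrelated lognormal.

Two rate processes on a chronogram:

* **UGAM** — uncorrelated gamma multipliers: each branch carries an i.i.d.
  multiplier with mean 1 and variance ``nu`` (Gamma(shape 1/nu, scale nu)),
  applied to the global rate ``mu_r`` (substitutions/site/Ma).
* **LN** — autocorrelated lognormal: the log of the instantaneous rate
  performs a Brownian walk along the tree with per-Ma variance ``nu``; the
  rate of a branch is the arithmetic mean of its endpoint rates.

Both reduce to a strict clock at ``nu = 0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .trees import Chronogram, Topology

__all__ = [
    "ClockParams",
    "RateAssignment",
    "ugam_log_density",
    "ugam_sample",
    "ln_autocorr_log_density",
    "ln_autocorr_sample",
    "branch_effective_lengths",
]

_NU_FLOOR = 1e-8                      # degenerate-limit guard for densities


@dataclass(frozen=True)
class ClockParams:
    """Clock model tag plus global rate and rate-variance hyperparameter.

    ``mu_r`` is in substitutions/site/Ma.  ``nu`` is the variance of the
    mean-1 branch multipliers (UGAM) or the per-Ma variance of the Brownian
    log-rate (LN).
    """

    model: str                         # "ugam" | "ln"
    mu_r: float
    nu: float

    def __post_init__(self) -> None:
        if self.model not in ("ugam", "ln"):
            raise ValueError(f"unknown clock model {self.model!r}")
        if self.mu_r <= 0:
            raise ValueError("global rate mu_r must be positive")
        if self.nu < 0:
            raise ValueError("rate variance nu must be non-negative")


@dataclass
class RateAssignment:
    """Realized rates: per-branch multipliers (UGAM, keyed by child node) or
    per-node log instantaneous rates (LN)."""

    model: str
    values: np.ndarray                 # one entry per node id

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("rate values must be finite")
        if self.model == "ugam" and np.any(self.values <= 0):
            raise ValueError("UGAM multipliers must be positive")


def ugam_log_density(rates: RateAssignment, nu: float,
                     topology: Topology | None = None) -> float:
    """Log density of UGAM branch multipliers under Gamma(1/nu, nu).

    Each non-root node's entry is the multiplier of the branch above it.
    Remains finite for any ``nu >= 1e-8``; smaller values are clamped.
    """
    if nu <= 0:
        raise ValueError("nu must be positive for a density evaluation")
    nu = max(nu, _NU_FLOOR)
    mult = rates.values[:-1]           # root (last id, postorder) excluded
    if np.any(mult <= 0):
        raise ValueError("UGAM multipliers must be positive")
    shape = 1.0 / nu
    return float(np.sum((shape - 1.0) * np.log(mult) - mult / nu)
                 - mult.size * (math.lgamma(shape) + shape * math.log(nu)))


def ugam_sample(topology: Topology, nu: float,
                seed: int | np.random.Generator) -> RateAssignment:
    """Draw i.i.d. mean-1 gamma multipliers for every branch."""
    if nu < 0:
        raise ValueError("nu must be non-negative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    values = np.ones(topology.n_nodes)
    if nu > 0:
        shape = 1.0 / nu
        values[:-1] = rng.gamma(shape, scale=nu, size=topology.n_nodes - 1)
    return RateAssignment(model="ugam", values=values)


def ln_autocorr_log_density(node_log_rates: np.ndarray | RateAssignment,
                            chronogram: Chronogram, nu: float,
                            root_log_rate_prior: tuple[float, float] | None = None
                            ) -> float:
    """Brownian log-rate density: child ~ Normal(parent, nu * branch duration).

    ``root_log_rate_prior`` is a (mean, variance) normal prior on the root
    log-rate; ``None`` leaves the root term out (useful when it is handled by
    the caller).  Zero-duration branches with differing endpoint log-rates
    have density zero (returns ``-inf``).
    """
    if nu <= 0:
        raise ValueError("nu must be positive for a density evaluation")
    lr = node_log_rates.values if isinstance(node_log_rates, RateAssignment) \
        else np.asarray(node_log_rates, dtype=float)
    topo = chronogram.topology
    dur = chronogram.branch_durations()
    nonroot = np.flatnonzero(topo.parent >= 0)
    diffs = lr[nonroot] - lr[topo.parent[nonroot]]
    var = nu * dur[nonroot]
    total = 0.0
    zero = var <= 0
    if np.any(zero):
        if np.any(diffs[zero] != 0):
            return -np.inf
        diffs, var = diffs[~zero], var[~zero]
    total += float(np.sum(-0.5 * (np.log(2 * np.pi * var) + diffs ** 2 / var)))
    if root_log_rate_prior is not None:
        m, v = root_log_rate_prior
        total += float(stats.norm.logpdf(lr[topo.root], loc=m, scale=math.sqrt(v)))
    return total


def ln_autocorr_sample(chronogram: Chronogram, nu: float, mu_r: float,
                       seed: int | np.random.Generator) -> RateAssignment:
    """Simulate node log-rates root→tips starting at ``log(mu_r)``.

    ``nu = 0`` yields a strict clock with every node rate equal to ``mu_r``.
    """
    if nu < 0:
        raise ValueError("nu must be non-negative")
    if mu_r <= 0:
        raise ValueError("mu_r must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    topo = chronogram.topology
    lr = np.empty(topo.n_nodes)
    lr[topo.root] = math.log(mu_r)
    # preorder: walk ids from root downward (parents have larger postorder ids)
    for node in reversed(range(topo.n_nodes - 1)):
        p = topo.parent[node]
        dt = chronogram.ages[p] - chronogram.ages[node]
        lr[node] = lr[p] + (rng.normal(0.0, math.sqrt(nu * dt)) if nu > 0 and dt > 0 else 0.0)
    return RateAssignment(model="ln", values=lr)


def branch_effective_lengths(chron: Chronogram, rates: RateAssignment,
                             clock: ClockParams) -> np.ndarray:
    """Expected substitutions/site per branch, indexed by child node id.

    UGAM: ``mu_r * multiplier * duration``.  LN: duration times the arithmetic
    mean of the endpoint instantaneous rates (``exp`` of the node log-rates,
    already on the ``mu_r`` scale).  The root entry is 0.
    """
    if rates.model != clock.model:
        raise ValueError("rate assignment does not match clock model")
    dur = chron.branch_durations()
    if clock.model == "ugam":
        lengths = clock.mu_r * rates.values * dur
    else:
        inst = np.exp(rates.values)
        parent_inst = inst[np.maximum(chron.topology.parent, 0)]
        lengths = 0.5 * (inst + parent_inst) * dur
    lengths[chron.topology.root] = 0.0
    return lengths
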