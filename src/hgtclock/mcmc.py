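"""Metropolis-Hastings sampler over node ages, branch rates and
hyperparameters, with prior-only mode and convergence diagnostics.

The chain targets

    p(ages, rates, hypers | data) ∝ L(data | lengths(ages, rates))
        × p_tree(ages) × p_cal(ages) × p_clock(rates | hypers) × p(hypers)

on a fixed rooted topology.  In prior-only mode the likelihood factor is
dropped, so retained samples follow the calibration-truncated tree prior —
the paper-style "remove the sequence data" control run.

Moves (weights configurable): node-age slides inside the window allowed by
the neighboring ages and the node's own hard bound (symmetric), a root-age
slide inside the root window, log-scale branch-multiplier moves (UGAM),
Gaussian node log-rate moves (LN), and log-scale hyperparameter moves.
Hard-bound or ordering violations give a ``-inf`` target and can never be
accepted.  An optional Robbins-Monro adaptation of step sizes runs during the
burn-in fraction and is frozen afterwards, keeping the retained chain valid.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import ProteinAlignment
from .calibrations import CalibrationSet, ResolvedCalibrations
from .clocks import (ClockParams, RateAssignment, branch_effective_lengths,
                     ln_autocorr_log_density, ugam_log_density)
from .substitution import PruningEngine, SiteModelParams
from .tree_priors import (RejectionError, TreePriorParams, _bd_kernel_logpdf,
                          sample_ages_under_prior)
from .trees import Chronogram, Topology

__all__ = [
    "McmcConfig",
    "Trace",
    "run_chain",
    "effective_size",
    "chain_discrepancy",
    "drop_burn_in",
]

DEFAULT_MOVE_WEIGHTS = {
    "age": 40.0,          # node-age slide
    "root": 10.0,         # root-age slide within its calibration window
    "branch_rate": 30.0,  # UGAM multiplier, log-scale
    "hyper": 10.0,        # nu / mu_r / lambda / mu multiplier moves
    "node_rate": 10.0,    # LN node log-rate, Gaussian
    "scale": 10.0,        # all ages x c with compensating rate shift
}


@dataclass(frozen=True)
class McmcConfig:
    """Chain-length, seeding and move configuration for one MCMC run."""

    generations: int = 10_000
    thinning: int = 1
    seed: int = 0
    prior_only: bool = False
    burn_in_fraction: float = 0.20
    move_weights: dict = field(default_factory=lambda: dict(DEFAULT_MOVE_WEIGHTS))
    chain_id: int = 0
    adapt: bool = True
    sample_nu: bool = True
    sample_mu_r: bool = True
    sample_bd_rates: bool = True
    start_attempts: int = 20_000

    def __post_init__(self) -> None:
        if self.generations <= 0:
            raise ValueError("generations must be positive")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if not (0.0 <= self.burn_in_fraction < 1.0):
            raise ValueError("burn-in fraction must lie in [0, 1)")


@dataclass
class Trace:
    """Sampled generations: one row per retained record.

    Columns: ``generation``, ``log_prior``, ``log_likelihood``, hyper
    parameters, and one ``age_<node>`` column per internal node (Ma).
    ``meta`` carries the run manifest (model tags, seed, node→clade map).
    """

    data: pd.DataFrame
    meta: dict = field(default_factory=dict)

    @property
    def n_records(self) -> int:
        return len(self.data)

    @property
    def age_columns(self) -> list[str]:
        return [c for c in self.data.columns if c.startswith("age_")]

    def series(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy()

    def node_age_series(self, node: int) -> np.ndarray:
        return self.data[f"age_{node}"].to_numpy()

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path, meta: dict | None = None) -> "Trace":
        return cls(data=pd.read_csv(path, sep="\t"), meta=meta or {})


def drop_burn_in(trace: Trace, fraction: float) -> Trace:
    """Discard the first ``ceil(fraction * n_records)`` records."""
    if not (0.0 <= fraction < 1.0):
        raise ValueError("burn-in fraction must lie in [0, 1)")
    k = math.ceil(fraction * trace.n_records)
    return Trace(data=trace.data.iloc[k:].reset_index(drop=True),
                 meta=dict(trace.meta, burn_in_dropped=k))


# ---------------------------------------------------------------------------
# convergence diagnostics
# ---------------------------------------------------------------------------

def effective_size(series: np.ndarray) -> float:
    """Effective sample size: n over the integrated autocorrelation time,
    with Geyer's initial-positive-sequence truncation.

    A constant series has no information about mixing; it is reported as
    ESS 0 with a warning.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 2:
        warnings.warn("series too short for an ESS estimate; reporting 0")
        return 0.0
    x = x - x.mean()
    var = np.dot(x, x) / n
    if var == 0.0:
        warnings.warn("constant series: effective size reported as 0")
        return 0.0
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conjugate(f), nfft)[:n] / n
    rho = acov / acov[0]
    # pair sums Gamma_m = rho_{2m} + rho_{2m+1}; IACT = -1 + 2 * sum of the
    # leading positive pair sums
    n_pairs = n // 2
    gammas = rho[0:2 * n_pairs:2] + rho[1:2 * n_pairs:2]
    tau = -1.0
    for g in gammas:
        if g <= 0.0:
            break
        tau += 2.0 * g
    return n / max(tau, 1.0 / n)


def _iact(series: np.ndarray) -> float:
    ess = effective_size(series)
    return np.inf if ess == 0 else series.size / ess


def chain_discrepancy(series_a: np.ndarray, series_b: np.ndarray) -> float:
    """|mean(A) - mean(B)| / pooled standard deviation.

    The run grid flags monitored variables with discrepancy >= 0.30, the
    conventional between-chain agreement cut-off.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    va = a.var(ddof=1) if a.size > 1 else 0.0
    vb = b.var(ddof=1) if b.size > 1 else 0.0
    pooled = math.sqrt((va + vb) / 2.0)
    diff = abs(a.mean() - b.mean())
    if pooled == 0.0:
        return 0.0 if diff == 0.0 else np.inf
    return diff / pooled


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------

@dataclass
class _State:
    ages: np.ndarray
    rates: np.ndarray          # multipliers (ugam) or node log-rates (ln)
    nu: float
    mu_r: float
    lam: float
    mu: float
    log_lik: float = 0.0


class _Model:
    """Bundles the fixed inputs and evaluates target components."""

    def __init__(self, topology: Topology, engine: PruningEngine | None,
                 resolved: ResolvedCalibrations, tree_prior: TreePriorParams,
                 clock: ClockParams, cfg: McmcConfig):
        self.topo = topology
        self.engine = engine
        self.resolved = resolved
        self.tree_prior = tree_prior
        self.clock = clock
        self.cfg = cfg
        self.root = topology.root
        self.inner = np.array(
            [v for v in topology.internal_nodes if v != self.root], dtype=int)
        self.nonroot = np.flatnonzero(topology.parent >= 0)
        self.parent = topology.parent
        root_lo, root_hi = resolved.root_bounds
        if not np.isfinite(root_hi):
            raise ValueError("the root calibration must have a finite upper "
                             "bound; the root age is otherwise improper")
        self.root_window = (root_lo, root_hi)
        # hyperprior means (exponential): nu ~ mean 1; mu_r ~ mean scaled to
        # one expected substitution root-to-tip; lambda, mu ~ mean 1 / 100 Ma
        self.nu_prior_mean = 1.0
        self.mu_r_prior_mean = 1.0 / (0.5 * (root_lo + root_hi))
        self.bd_prior_mean = 0.01

    # -- target components -------------------------------------------------
    def log_prior(self, s: _State) -> float:
        ages = s.ages
        if ages[self.root] <= 0:
            return -np.inf
        if np.any(ages[self.parent[self.nonroot]] <= ages[self.nonroot]):
            return -np.inf
        if not self.resolved.satisfied(ages):
            return -np.inf
        total = 0.0
        if self.inner.size:
            inner_ages = ages[self.inner]
            if np.any(inner_ages <= 0) or np.any(inner_ages >= ages[self.root]):
                return -np.inf
            if self.tree_prior.kind == "bd":
                total += float(np.sum(_bd_kernel_logpdf(
                    inner_ages, float(ages[self.root]), s.lam, s.mu)))
            else:
                # uniform-conditional-on-root: density root_age^-n_inner
                total += -self.inner.size * math.log(float(ages[self.root]))
        total += self._log_clock(s)
        total += self._log_hyper(s)
        return total

    def _log_clock(self, s: _State) -> float:
        if self.clock.model == "ugam":
            ra = RateAssignment(model="ugam", values=s.rates)
            return ugam_log_density(ra, max(s.nu, 1e-8))
        chron = Chronogram.__new__(Chronogram)   # avoid re-validation cost
        chron.topology = self.topo
        chron.ages = s.ages
        return ln_autocorr_log_density(
            s.rates, chron, max(s.nu, 1e-8),
            root_log_rate_prior=(math.log(s.mu_r), 1.0))

    def _log_hyper(self, s: _State) -> float:
        total = 0.0
        if self.cfg.sample_nu:
            total += -s.nu / self.nu_prior_mean - math.log(self.nu_prior_mean)
        if self.cfg.sample_mu_r:
            total += -s.mu_r / self.mu_r_prior_mean - math.log(self.mu_r_prior_mean)
        if self.tree_prior.kind == "bd" and self.cfg.sample_bd_rates:
            total += -(s.lam + s.mu) / self.bd_prior_mean \
                - 2 * math.log(self.bd_prior_mean)
        return total

    def lengths(self, s: _State) -> np.ndarray:
        chron = Chronogram.__new__(Chronogram)
        chron.topology = self.topo
        chron.ages = s.ages
        ra = RateAssignment.__new__(RateAssignment)
        ra.model = self.clock.model
        ra.values = s.rates
        clock = ClockParams(model=self.clock.model, mu_r=s.mu_r, nu=max(s.nu, 1e-12))
        return branch_effective_lengths(chron, ra, clock)


def _initial_ages(topology: Topology, resolved: ResolvedCalibrations,
                  rng: np.random.Generator, attempts: int) -> np.ndarray:
    """Admissible starting ages: rejection sample, else midpoint fallback."""
    try:
        chron = sample_ages_under_prior(
            topology, TreePriorParams(kind="uniform"), resolved, 1, rng,
            max_attempts=attempts)[0]
        return chron.ages.copy()
    except RejectionError:
        pass
    ages = np.zeros(topology.n_nodes)
    # effective lower bound: deepest calibration lower bound in the subtree
    sub_lo = resolved.lower.copy()
    for node in topology.postorder():
        for child in topology.children[node]:
            sub_lo[node] = max(sub_lo[node], sub_lo[child])
    lo, hi = resolved.root_bounds
    ages[topology.root] = 0.5 * (max(lo, sub_lo[topology.root]) + hi)
    for node in reversed(range(topology.n_nodes - 1)):   # preorder
        if not topology.children[node]:
            continue
        cap = min(float(resolved.upper[node]), ages[topology.parent[node]])
        floor = sub_lo[node]
        if cap <= floor:
            raise RuntimeError("no admissible starting state found: "
                               f"node {node} window ({floor}, {cap}) is empty")
        ages[node] = 0.5 * (floor + cap)
    if not resolved.satisfied(ages):
        raise RuntimeError("no admissible starting state found under the "
                           "relative constraints")
    return ages


def run_chain(topology: Topology, aln: ProteinAlignment | None,
              calset: CalibrationSet | ResolvedCalibrations,
              tree_prior: TreePriorParams, clock: ClockParams,
              site_model: SiteModelParams | None, cfg: McmcConfig) -> Trace:
    """Run one MCMC chain and return its trace.

    ``aln`` may be ``None`` only in prior-only mode.  With ``cfg.prior_only``
    the sequence likelihood is dropped and the chain samples the effective
    (calibration-truncated) prior.  Fixed seeds give bit-identical traces.
    """
    resolved = calset if isinstance(calset, ResolvedCalibrations) \
        else calset.resolve(topology)
    engine = None
    if not cfg.prior_only:
        if aln is None:
            raise ValueError("an alignment is required unless prior_only=True")
        if site_model is None:
            raise ValueError("a site model is required unless prior_only=True")
        engine = PruningEngine(aln, topology, site_model)
    model = _Model(topology, engine, resolved, tree_prior, clock, cfg)
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, cfg.chain_id]))

    s = _State(
        ages=_initial_ages(topology, resolved, rng, cfg.start_attempts),
        rates=np.ones(topology.n_nodes) if clock.model == "ugam"
        else np.full(topology.n_nodes, math.log(clock.mu_r)),
        nu=max(clock.nu, 0.1) if cfg.sample_nu else clock.nu,
        mu_r=clock.mu_r, lam=tree_prior.lam, mu=tree_prior.mu,
    )
    log_prior = model.log_prior(s)
    if not np.isfinite(log_prior):
        raise RuntimeError("no admissible starting state found")
    s.log_lik = engine.begin(model.lengths(s)) if engine is not None else 0.0

    # -- move bookkeeping ---------------------------------------------------
    weights = dict(DEFAULT_MOVE_WEIGHTS)
    weights.update(cfg.move_weights or {})
    active = ["age", "root"]
    if clock.model == "ugam":
        active.append("branch_rate")
    else:
        active.append("node_rate")
    hypers = []
    if cfg.sample_nu:
        hypers.append("nu")
    if cfg.sample_mu_r and not cfg.prior_only:
        hypers.append("mu_r")
    if tree_prior.kind == "bd" and cfg.sample_bd_rates:
        hypers.extend(["lam", "mu"])
    if hypers:
        active.append("hyper")
    # the compensated whole-tree scale move rescales every internal age and
    # shifts the rate level so branch lengths (and the likelihood) are exactly
    # unchanged — it mixes the rate-time ridge that single-variable moves
    # cross only slowly
    scale_compensates = (clock.model == "ln"
                         or ("mu_r" in hypers) or cfg.prior_only)
    if scale_compensates:
        active.append("scale")
    probs = np.array([weights[m] for m in active], dtype=float)
    probs /= probs.sum()
    step = {"branch_rate": 0.5, "node_rate": 0.3, "hyper": 0.5, "scale": 0.2}
    adapt_until = math.ceil(cfg.burn_in_fraction * cfg.generations) \
        if cfg.adapt else 0
    adapt_count = dict.fromkeys(step, 0)

    inner = model.inner
    root = topology.root
    children = topology.children
    parent = topology.parent
    nonroot_ids = model.nonroot

    records = []
    rec_ages = list(topology.internal_nodes)
    sample_cols = ["generation", "log_prior", "log_likelihood",
                   "mu_r", "nu", "lam", "mu"] + [f"age_{n}" for n in rec_ages]

    def record(gen: int) -> None:
        records.append((gen, log_prior, s.log_lik, s.mu_r, s.nu, s.lam, s.mu,
                        *(s.ages[n] for n in rec_ages)))

    n_accept = 0
    for gen in range(1, cfg.generations + 1):
        move = active[rng.choice(len(active), p=probs)]
        log_hastings = 0.0
        new_lik_needed = True
        if move == "age":
            if inner.size == 0:
                record(gen) if gen % cfg.thinning == 0 else None
                continue
            node = int(inner[rng.integers(inner.size)])
            lo = max(float(resolved.lower[node]),
                     max(s.ages[c] for c in children[node]))
            hi = min(float(resolved.upper[node]), float(s.ages[parent[node]]))
            if hi <= lo:
                if gen % cfg.thinning == 0:
                    record(gen)
                continue
            old, s.ages[node] = s.ages[node], rng.uniform(lo, hi)
            undo = ("age", node, old)
            if model.engine is None and clock.model == "ugam":
                new_lik_needed = False
        elif move == "root":
            lo = max(model.root_window[0],
                     max(s.ages[c] for c in children[root]))
            hi = model.root_window[1]
            if hi <= lo:
                if gen % cfg.thinning == 0:
                    record(gen)
                continue
            old, s.ages[root] = s.ages[root], rng.uniform(lo, hi)
            undo = ("age", root, old)
            if model.engine is None and clock.model == "ugam":
                new_lik_needed = False
        elif move == "branch_rate":
            node = int(nonroot_ids[rng.integers(nonroot_ids.size)])
            u = rng.uniform(-step["branch_rate"], step["branch_rate"])
            old = s.rates[node]
            s.rates[node] = old * math.exp(u)
            log_hastings = u
            undo = ("rate", node, old)
            if model.engine is None:
                new_lik_needed = False
        elif move == "node_rate":
            node = int(rng.integers(topology.n_nodes))
            old = s.rates[node]
            s.rates[node] = old + rng.normal(0.0, step["node_rate"])
            undo = ("rate", node, old)
            if model.engine is None:
                new_lik_needed = False
        elif move == "scale":
            u = rng.uniform(-step["scale"], step["scale"])
            c = math.exp(u)
            old_ages = s.ages.copy()
            old_rates = s.rates.copy()
            old_mu_r = s.mu_r
            n_scaled = 0
            for n in range(topology.n_nodes):
                if children[n]:
                    s.ages[n] *= c
                    n_scaled += 1
            log_hastings = n_scaled * u
            if clock.model == "ln":
                s.rates -= u               # shifts every instantaneous rate
            elif "mu_r" in hypers:
                s.mu_r = old_mu_r / c
                log_hastings -= u
            undo = ("scale", None, (old_ages, old_rates, old_mu_r))
            new_lik_needed = False         # branch lengths exactly preserved
        else:  # hyper
            name = hypers[rng.integers(len(hypers))]
            u = rng.uniform(-step["hyper"], step["hyper"])
            old = getattr(s, name)
            setattr(s, name, old * math.exp(u))
            log_hastings = u
            undo = ("hyper", name, old)
            # only mu_r (ugam) changes branch lengths hence the likelihood
            new_lik_needed = (name == "mu_r" and clock.model == "ugam"
                              and model.engine is not None)

        if engine is None:
            new_lik_needed = False
        new_prior = model.log_prior(s)
        accepted = False
        lik_proposed = False
        if np.isfinite(new_prior):
            if new_lik_needed:
                new_lik = engine.propose(model.lengths(s))
                lik_proposed = True
            else:
                new_lik = s.log_lik
            log_alpha = (new_prior - log_prior) + (new_lik - s.log_lik) \
                + log_hastings
            if log_alpha >= 0 or rng.random() < math.exp(log_alpha):
                accepted = True
                log_prior = new_prior
                s.log_lik = new_lik
        if accepted:
            if lik_proposed:
                engine.accept()
            n_accept += 1
        else:
            if lik_proposed:
                engine.reject()
            kind, key, old = undo
            if kind == "age":
                s.ages[key] = old
            elif kind == "rate":
                s.rates[key] = old
            elif kind == "scale":
                s.ages, s.rates, s.mu_r = old
            else:
                setattr(s, key, old)

        if gen <= adapt_until and move in step:
            adapt_count[move] += 1
            gain = 2.0 / (1.0 + adapt_count[move]) ** 0.6
            step[move] = float(np.clip(
                step[move] * math.exp(gain * ((1.0 if accepted else 0.0) - 0.24)),
                1e-3, 10.0))

        if gen % cfg.thinning == 0:
            record(gen)

    data = pd.DataFrame.from_records(records, columns=sample_cols)
    meta = {
        "seed": cfg.seed,
        "chain_id": cfg.chain_id,
        "generations": cfg.generations,
        "thinning": cfg.thinning,
        "prior_only": cfg.prior_only,
        "tree_prior": tree_prior.kind,
        "clock_model": clock.model,
        "burn_in_fraction": cfg.burn_in_fraction,
        "acceptance_rate": n_accept / cfg.generations,
        "node_clades": {int(n): sorted(topology.clade_leafset(n))
                        for n in rec_ages},
        "diagnostics_definitions": {
            "effective_size": "n / integrated autocorrelation time, "
                              "initial-positive-sequence truncation",
            "discrepancy": "|mean(A)-mean(B)| / pooled SD",
        },
    }
    return Trace(data=data, meta=meta)
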