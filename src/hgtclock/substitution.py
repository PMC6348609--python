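"""Amino-acid substitution model and pruning likelihood on a clock tree.

The likelihood machinery is the standard reversible-model toolkit: a fixed
exchangeability set (LG, or Poisson for fast tests), stationary frequencies,
discrete-gamma among-site rate variation, eigendecomposition-based transition
matrices, and Felsenstein pruning with per-node rescaling.  Branch lengths are
expected substitutions per site; converting ages and clock rates into those
lengths is the job of :mod:`hgtclock.clocks`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from ._lg_data import LG_EXCHANGEABILITIES, LG_FREQUENCIES
from .alignment import GAP_CODE, ProteinAlignment
from .trees import Topology

__all__ = [
    "SiteModelParams",
    "discrete_gamma_rates",
    "transition_matrix",
    "tree_log_likelihood",
    "PruningEngine",
]

_N_STATES = 20


def _lg_matrix() -> np.ndarray:
    s = np.zeros((_N_STATES, _N_STATES))
    k = 0
    for j in range(_N_STATES - 1):
        for i in range(j + 1, _N_STATES):
            s[i, j] = s[j, i] = LG_EXCHANGEABILITIES[k]
            k += 1
    return s


_EXCHANGE_PRESETS = {
    "LG": _lg_matrix,
    "Poisson": lambda: np.ones((_N_STATES, _N_STATES)) - np.eye(_N_STATES),
}


@dataclass(frozen=True)
class SiteModelParams:
    """Site model: exchangeability preset + frequencies + discrete gamma.

    Parameters
    ----------
    exchangeabilities:
        ``"LG"`` or ``"Poisson"`` (equal exchangeabilities).
    frequencies:
        Stationary amino-acid frequencies over ``ARNDCQEGHILKMFPSTWYV``;
        ``None`` selects the preset's own frequencies (LG frequencies, or
        uniform for Poisson).
    alpha:
        Gamma shape for among-site rate variation (> 0).
    categories:
        Number of equal-probability discrete gamma categories (default 4).
    """

    exchangeabilities: str = "LG"
    frequencies: tuple[float, ...] | None = None
    alpha: float = 1.0
    categories: int = 4

    def __post_init__(self) -> None:
        if self.exchangeabilities not in _EXCHANGE_PRESETS:
            raise ValueError(
                f"unknown exchangeability preset {self.exchangeabilities!r}")
        if self.alpha <= 0:
            raise ValueError("gamma shape alpha must be positive")
        if self.categories < 1:
            raise ValueError("need at least one rate category")
        if self.frequencies is not None:
            freqs = np.asarray(self.frequencies, dtype=float)
            if freqs.shape != (_N_STATES,) or np.any(freqs <= 0):
                raise ValueError("frequencies must be 20 positive reals")
            if abs(freqs.sum() - 1.0) > 1e-9:
                raise ValueError("frequencies must sum to 1 (tolerance 1e-9)")

    def stationary_frequencies(self) -> np.ndarray:
        if self.frequencies is not None:
            return np.asarray(self.frequencies, dtype=float)
        if self.exchangeabilities == "LG":
            return np.asarray(LG_FREQUENCIES, dtype=float)
        return np.full(_N_STATES, 1.0 / _N_STATES)

    def with_empirical_frequencies(self, aln: ProteinAlignment,
                                   pseudocount: float = 0.5
                                   ) -> "SiteModelParams":
        freqs = aln.empirical_frequencies(pseudocount=pseudocount)
        return SiteModelParams(
            exchangeabilities=self.exchangeabilities,
            frequencies=tuple(freqs / freqs.sum()),
            alpha=self.alpha, categories=self.categories)


def discrete_gamma_rates(alpha: float, categories: int) -> np.ndarray:
    """Mean rates of ``categories`` equal-probability Gamma(alpha, alpha) bins.

    Uses the standard category-mean discretization: with cut points at the
    k/K quantiles of Gamma(shape=alpha, rate=alpha), category means come from
    the incomplete-gamma identity and are normalized to mean exactly 1.
    """
    if alpha <= 0:
        raise ValueError("gamma shape alpha must be positive")
    k = int(categories)
    if k < 1:
        raise ValueError("need at least one rate category")
    if k == 1:
        return np.ones(1)
    cuts = gamma_dist.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
    upper = np.concatenate([gammainc(alpha + 1, alpha * cuts), [1.0]])
    lower = np.concatenate([[0.0], gammainc(alpha + 1, alpha * cuts)])
    rates = k * (upper - lower)
    return rates / rates.mean()


class _EigenSystem:
    """Cached spectral decomposition of the normalized reversible rate matrix."""

    def __init__(self, model: SiteModelParams):
        pi = model.stationary_frequencies()
        s = _EXCHANGE_PRESETS[model.exchangeabilities]()
        q = s * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        # scale so the expected substitution rate at stationarity is 1
        q /= -(pi * np.diag(q)).sum()
        sqrt_pi = np.sqrt(pi)
        b = (q * sqrt_pi[:, None]) / sqrt_pi[None, :]
        w, v = np.linalg.eigh((b + b.T) / 2.0)
        self.pi = pi
        self.eigenvalues = w
        self.left = v.T * sqrt_pi[None, :]          # V^T D^{1/2}
        self.right = v / sqrt_pi[:, None]           # D^{-1/2} V

    def transition_matrices(self, lengths: np.ndarray) -> np.ndarray:
        """P(t) for an array of branch lengths; output (..., 20, 20)."""
        lengths = np.asarray(lengths, dtype=float)
        expwt = np.exp(np.multiply.outer(lengths, self.eigenvalues))
        # P = right @ diag(expwt) @ left, batched over leading axes
        p = np.matmul(self.right * expwt[..., None, :], self.left)
        return np.clip(p, 0.0, None)


_EIGEN_CACHE: dict[tuple, _EigenSystem] = {}


def _eigen_for(model: SiteModelParams) -> _EigenSystem:
    key = (model.exchangeabilities, model.frequencies)
    if key not in _EIGEN_CACHE:
        _EIGEN_CACHE[key] = _EigenSystem(model)
    return _EIGEN_CACHE[key]


def transition_matrix(model: SiteModelParams, length: float) -> np.ndarray:
    """20x20 stochastic matrix after ``length`` expected substitutions/site."""
    if length < 0:
        raise ValueError("branch length must be non-negative")
    p = _eigen_for(model).transition_matrices(np.array(length))
    return p / p.sum(axis=-1, keepdims=True)


class PruningEngine:
    """Felsenstein pruning for one alignment/topology pair.

    Precomputes leaf state codes and the eigen system once, then evaluates the
    log-likelihood for arbitrary branch-length vectors — the hot path of the
    MCMC.  Per-node, per-site rescaling keeps partials in range; the contract
    is only on the returned log value.
    """

    def __init__(self, aln: ProteinAlignment, topology: Topology,
                 model: SiteModelParams):
        missing = set(topology.leaf_labels) - set(aln.taxa)
        if missing:
            raise ValueError(f"taxa missing from alignment: {sorted(missing)}")
        self.topology = topology
        self.model = model
        self.eigen = _eigen_for(model)
        self.rates = discrete_gamma_rates(model.alpha, model.categories)
        self.n_sites = aln.n_sites
        self._leaf_codes = {
            leaf: aln.row(topology.labels[leaf]).astype(np.intp)
            for leaf in topology.leaves
        }

    def log_likelihood(self, branch_lengths: np.ndarray) -> float:
        """Log-likelihood given per-node branch lengths (subs/site).

        ``branch_lengths[i]`` is the length of the branch above node ``i``;
        the root entry is ignored.
        """
        topo = self.topology
        bl = np.asarray(branch_lengths, dtype=float)
        if bl.shape != (topo.n_nodes,):
            raise ValueError("branch_lengths must have one entry per node")
        if np.any(bl[:-1] < 0) or not np.all(np.isfinite(bl[:-1])):
            raise ValueError("branch lengths must be finite and non-negative")
        ncat = len(self.rates)
        ns = self.n_sites
        # transition matrices for every (branch, category) at once
        eff = np.multiply.outer(bl, self.rates)        # (n_nodes, ncat)
        pmats = self.eigen.transition_matrices(eff)    # (n_nodes, ncat, 20, 20)
        log_scale = np.zeros(ns)
        partials: dict[int, np.ndarray] = {}
        for node in topo.postorder():
            kids = topo.children[node]
            if not kids:
                continue
            acc: np.ndarray | None = None
            for child in kids:
                if topo.children[child]:
                    msg = np.matmul(pmats[child], partials.pop(child))
                else:
                    codes = self._leaf_codes[child]
                    obs = codes < GAP_CODE
                    if obs.all():
                        msg = pmats[child][:, :, codes]
                    else:
                        msg = np.ones((ncat, _N_STATES, ns))
                        msg[:, :, obs] = pmats[child][:, :, codes[obs]]
                acc = msg if acc is None else acc * msg
            top = acc.reshape(ncat * _N_STATES, ns).max(axis=0)
            np.maximum(top, 1e-300, out=top)
            acc /= top
            log_scale += np.log(top)
            partials[node] = acc
        root = partials[topo.root]
        site_like = np.einsum("i,cis->s", self.eigen.pi, root) / ncat
        return float(np.sum(np.log(site_like)) + np.sum(log_scale))

    # -- incremental evaluation (MCMC hot path) -----------------------------
    #
    # ``begin`` performs a full evaluation and caches per-node transition
    # matrices, partials and scaling vectors.  ``propose`` re-evaluates after
    # a sparse branch-length change, touching only the changed branches and
    # their ancestors; ``accept``/``reject`` commit or roll back.

    def _node_partial(self, node: int) -> tuple[np.ndarray, np.ndarray]:
        acc: np.ndarray | None = None
        for child in self.topology.children[node]:
            if self.topology.children[child]:
                msg = np.matmul(self._pmats[child], self._partials[child])
            else:
                codes = self._leaf_codes[child]
                obs = codes < GAP_CODE
                if obs.all():
                    msg = self._pmats[child][:, :, codes]
                else:
                    msg = np.ones((len(self.rates), _N_STATES, self.n_sites))
                    msg[:, :, obs] = self._pmats[child][:, :, codes[obs]]
            acc = msg if acc is None else acc * msg
        top = acc.reshape(-1, self.n_sites).max(axis=0)
        np.maximum(top, 1e-300, out=top)
        acc /= top
        return acc, np.log(top)

    def _root_loglik(self) -> float:
        root = self._partials[self.topology.root]
        site_like = (self.eigen.pi @ root.sum(axis=0)) / len(self.rates)
        return float(np.sum(np.log(site_like)) + self._scale_total.sum())

    def begin(self, branch_lengths: np.ndarray) -> float:
        """Initialize the incremental state; returns the log-likelihood."""
        topo = self.topology
        self._bl = np.asarray(branch_lengths, dtype=float).copy()
        eff = np.multiply.outer(self._bl, self.rates)
        self._pmats = self.eigen.transition_matrices(eff)
        self._partials = {}
        self._scales = {}
        self._scale_total = np.zeros(self.n_sites)
        for node in topo.postorder():
            if topo.children[node]:
                self._partials[node], self._scales[node] = \
                    self._node_partial(node)
                self._scale_total += self._scales[node]
        self._loglik = self._root_loglik()
        self._saved = None
        return self._loglik

    def propose(self, branch_lengths: np.ndarray) -> float:
        """Log-likelihood after a (typically sparse) branch-length change."""
        topo = self.topology
        bl = np.asarray(branch_lengths, dtype=float)
        changed = np.flatnonzero(bl != self._bl)
        saved_p = {}
        saved_partials = {}
        dirty: set[int] = set()
        for v in changed:
            saved_p[int(v)] = self._pmats[v].copy()
            self._pmats[v] = self.eigen.transition_matrices(
                bl[v] * self.rates)
            p = topo.parent[v]
            if p >= 0:
                dirty.add(int(p))
        for node in topo.postorder():
            if node in dirty and topo.children[node]:
                saved_partials[node] = (self._partials[node],
                                        self._scales[node])
                self._scale_total -= self._scales[node]
                self._partials[node], self._scales[node] = \
                    self._node_partial(node)
                self._scale_total += self._scales[node]
                p = topo.parent[node]
                if p >= 0:
                    dirty.add(int(p))
        self._saved = (saved_p, saved_partials, self._bl, self._loglik)
        self._bl = bl.copy()
        self._loglik = self._root_loglik()
        return self._loglik

    def accept(self) -> None:
        self._saved = None

    def reject(self) -> None:
        saved_p, saved_partials, bl, loglik = self._saved
        for v, pm in saved_p.items():
            self._pmats[v] = pm
        for node, (part, scale) in saved_partials.items():
            self._scale_total += scale - self._scales[node]
            self._partials[node] = part
            self._scales[node] = scale
        self._bl = bl
        self._loglik = loglik
        self._saved = None


def tree_log_likelihood(aln: ProteinAlignment, topology: Topology,
                        branch_lengths: np.ndarray | dict[int, float],
                        model: SiteModelParams) -> float:
    """Pruning log-likelihood of ``aln`` on ``topology``.

    ``branch_lengths`` maps each non-root node id to the length (expected
    substitutions/site) of the branch above it, either as a dict or as an
    array indexed by node id.  Gaps and 'X' are missing data.
    """
    if isinstance(branch_lengths, dict):
        bl = np.zeros(topology.n_nodes)
        for node, length in branch_lengths.items():
            bl[node] = length
    else:
        bl = np.asarray(branch_lengths, dtype=float)
    return PruningEngine(aln, topology, model).log_likelihood(bl)
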