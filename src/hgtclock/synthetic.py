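"""Synthetic inputs with the statistical structure the dating analysis
assumes: birth-death chronograms, relaxed-clock amino-acid alignments, and
the standard "HGT fixture".

The fixture emulates a horizontally transferred gene family: a calibrated
*donor* subtree (nested hard windows analogous to a fungal root, a deep
Dikarya-like split and two crown groups) joined by one long reticulating
branch to an uncalibrated *recipient* subtree whose nodes are dated only by
propagation of the donor calibrations through the clock.  Truth files record
every true age and parameter so recovery can be scored without access to the
generator.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
from dendropy.simulate import treesim

from .alignment import AA_ALPHABET, ProteinAlignment, write_protein_fasta
from .calibrations import (Calibration, CalibrationSet, RelativeConstraint,
                           write_calibration_tsv)
from .clocks import (ClockParams, branch_effective_lengths, ln_autocorr_sample,
                     ugam_sample)
from .substitution import SiteModelParams, _eigen_for, discrete_gamma_rates
from .trees import (Chronogram, Topology, mrca, parse_newick_chronogram,
                    write_newick)

__all__ = [
    "FixtureSpec",
    "HgtFixture",
    "simulate_bd_chronogram",
    "simulate_relaxed_clock_data",
    "make_hgt_fixture",
    "true_ages_for",
]


def simulate_bd_chronogram(n_tips: int, lam: float, mu: float,
                           seed: int, labels: list[str] | None = None,
                           max_attempts: int = 1000) -> Chronogram:
    """Simulate an ultrametric birth-death chronogram with ``n_tips`` extant
    leaves (conditioned on survival by retry), ages in Ma.

    ``lam`` (birth) must exceed ``mu`` (death >= 0).  Extinct lineages are
    pruned.  Leaf labels default to ``T1..Tn``.
    """
    if n_tips < 2:
        raise ValueError("need at least two tips")
    if not (lam > mu >= 0):
        raise ValueError("require lambda > mu >= 0")
    rng = random.Random(seed)
    # the general sampling approach draws a uniform time while the process
    # has exactly n_tips extant lineages, so pendant branches are never zero
    tree = treesim.birth_death_tree(
        birth_rate=lam, death_rate=mu, num_extant_tips=n_tips,
        gsa_ntax=n_tips + 2, rng=rng, repeat_until_success=True)
    return _chronogram_from_dendropy(tree, labels)


def _chronogram_from_dendropy(tree: dendropy.Tree,
                              labels: list[str] | None) -> Chronogram:
    tree.suppress_unifurcations()
    nodes = list(tree.postorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    n = len(nodes)
    parent = np.full(n, -1, dtype=int)
    children: list[tuple[int, ...]] = [()] * n
    out_labels: list[str | None] = [None] * n
    depth = np.zeros(n)
    leaf_counter = 0
    for nd in reversed(nodes):                     # preorder: root first
        i = index[id(nd)]
        kids = nd.child_nodes()
        children[i] = tuple(index[id(c)] for c in kids)
        for c in kids:
            j = index[id(c)]
            parent[j] = i
            depth[j] = depth[i] + (c.edge.length or 0.0)
    for nd in nodes:
        if not nd.child_nodes():
            i = index[id(nd)]
            if labels is not None:
                out_labels[i] = labels[leaf_counter]
            else:
                out_labels[i] = (nd.taxon.label if nd.taxon is not None
                                 else f"T{leaf_counter + 1}")
            leaf_counter += 1
    height = depth.max()
    ages = height - depth
    ages[[i for i, k in enumerate(children) if not k]] = 0.0   # snap leaves
    topo = Topology(parent=parent, children=tuple(children),
                    labels=tuple(out_labels))
    return Chronogram(topology=topo, ages=ages)


def rescale_to_crown_age(chron: Chronogram, crown_age: float) -> Chronogram:
    """Linearly rescale all ages so the root (crown) age equals ``crown_age``."""
    if crown_age <= 0:
        raise ValueError("crown age must be positive")
    return Chronogram(topology=chron.topology,
                      ages=chron.ages * (crown_age / chron.root_age))


def uniform_order_ages(topology: Topology, crown_age: float,
                       rng: np.random.Generator,
                       max_attempts: int = 2_000_000) -> Chronogram:
    """Chronogram with the crown pinned at ``crown_age`` and the remaining
    internal ages i.i.d. uniform(0, crown_age) conditioned on parent>child
    ordering — the uniform node-age process assumed by the dating prior.

    Exact rejection sampling; practical for subtrees up to ~10 tips.
    """
    root = topology.root
    inner = np.array([v for v in topology.internal_nodes if v != root],
                     dtype=int)
    ages = np.zeros(topology.n_nodes)
    ages[root] = crown_age
    if inner.size == 0:
        return Chronogram(topology=topology, ages=ages)
    parent = topology.parent
    nonroot = np.flatnonzero(parent >= 0)
    for _ in range(max_attempts):
        ages[inner] = rng.uniform(0.0, crown_age, size=inner.size)
        if np.all(ages[parent[nonroot]] > ages[nonroot]):
            return Chronogram(topology=topology, ages=ages.copy())
    raise RuntimeError("could not draw order-compatible uniform ages; "
                       "subtree too large for rejection sampling")


def simulate_relaxed_clock_data(chron: Chronogram, clock: ClockParams,
                                site_model: SiteModelParams, n_sites: int,
                                seed: int) -> ProteinAlignment:
    """Evolve amino-acid sequences root→tips under the relaxed clock.

    Branch rates are drawn from the configured clock model, converted to
    expected substitutions/site, and sequences simulated with the site
    model's transition matrices; each site carries one of the discrete gamma
    rate categories.
    """
    if n_sites < 1:
        raise ValueError("need at least one site")
    rng = np.random.default_rng(seed)
    topo = chron.topology
    if clock.model == "ugam":
        rates = ugam_sample(topo, clock.nu, rng)
    else:
        rates = ln_autocorr_sample(chron, clock.nu, clock.mu_r, rng)
    lengths = branch_effective_lengths(chron, rates, clock)
    eigen = _eigen_for(site_model)
    cat_rates = discrete_gamma_rates(site_model.alpha, site_model.categories)
    cats = rng.integers(len(cat_rates), size=n_sites)
    states: dict[int, np.ndarray] = {
        topo.root: rng.choice(20, p=eigen.pi, size=n_sites)}
    for node in reversed(range(topo.n_nodes - 1)):            # preorder
        p = topo.parent[node]
        pmats = eigen.transition_matrices(lengths[node] * cat_rates)
        pmats /= pmats.sum(axis=-1, keepdims=True)
        probs = pmats[cats, states[p], :]                     # (n_sites, 20)
        u = rng.random(n_sites)[:, None]
        states[node] = (probs.cumsum(axis=1) > u).argmax(axis=1)
    seqs = [(topo.labels[leaf],
             "".join(AA_ALPHABET[c] for c in states[leaf]))
            for leaf in topo.leaves]
    return ProteinAlignment.from_sequences(seqs)


# ---------------------------------------------------------------------------
# the HGT fixture
# ---------------------------------------------------------------------------

# the study-style hard calibration windows (Ma) emitted by the default fixture
DEFAULT_WINDOWS = {
    "root": (738.0, 1145.0),
    "ab_split": (518.0, 830.0),
    "asco_crown": (408.0, 715.0),
    "basidio_crown": (400.0, 655.0),
    "fossil_ab": (405.0, 830.0),
}


@dataclass(frozen=True)
class FixtureSpec:
    """Defaults: 12 donor + 8 recipient tips, 300 sites, UGAM clock, the
    study-style calibration windows, and true ages well inside them."""

    donor_tips: int = 12
    recipient_tips: int = 8
    root_age: float = 900.0            # Ma; true age of the calibrated root
    ab_split_age: float = 820.0        # donor crown ("AB split" analog)
    a_crown_age: float = 560.0
    b_crown_age: float = 520.0
    recipient_crown_age: float = 400.0 # end of the long reticulating branch
    clock: ClockParams = field(
        default_factory=lambda: ClockParams(model="ugam", mu_r=1e-3, nu=0.1))
    site_model: SiteModelParams = field(
        default_factory=lambda: SiteModelParams(exchangeabilities="LG",
                                                alpha=1.0, categories=4))
    n_sites: int = 300
    seed: int = 0
    sim_lambda: float = 0.01           # shape simulator, per Ma
    sim_mu: float = 0.002
    windows: dict = field(default_factory=lambda: dict(DEFAULT_WINDOWS))

    def __post_init__(self) -> None:
        if self.donor_tips < 4 or self.recipient_tips < 2:
            raise ValueError("fixture needs >= 4 donor and >= 2 recipient tips")
        truths = {"root": self.root_age, "ab_split": self.ab_split_age,
                  "asco_crown": self.a_crown_age,
                  "basidio_crown": self.b_crown_age,
                  "fossil_ab": self.ab_split_age}
        for name, age in truths.items():
            lo, hi = self.windows[name]
            if not (lo <= age <= hi):
                raise ValueError(
                    f"true age {age} of {name!r} violates its own "
                    f"calibration window ({lo}, {hi})")
        if not (self.root_age > self.ab_split_age
                > max(self.a_crown_age, self.b_crown_age)
                and self.root_age > self.recipient_crown_age):
            raise ValueError("true ages do not respect the fixture topology")


@dataclass
class HgtFixture:
    chronogram: Chronogram
    alignment: ProteinAlignment
    calibrations: CalibrationSet
    truth: dict
    spec: FixtureSpec

    @property
    def topology(self) -> Topology:
        return self.chronogram.topology

    def calibration_structure(self, structure: int = 2) -> CalibrationSet:
        """The calibration table restricted to one grid structure (1-4).

        The full table carries both ``ab_split`` and its fossil-minimum
        variant on the same node, so it must be subset before resolution.
        """
        from .assessment import CALIBRATION_STRUCTURES
        return self.calibrations.subset(
            list(CALIBRATION_STRUCTURES[structure]))


def _clade_key(topology: Topology, node: int) -> str:
    return "|".join(sorted(topology.clade_leafset(node)))


def _spanning_pair(topology: Topology, node: int) -> tuple[str, str]:
    """Two leaf labels whose MRCA is exactly ``node``."""
    kids = topology.children[node]
    return (sorted(topology.clade_leafset(kids[0]))[0],
            sorted(topology.clade_leafset(kids[1]))[0])


def _subtree_newick(chron: Chronogram) -> str:
    return write_newick(chron.topology, chron).rstrip(";")


def make_hgt_fixture(spec: FixtureSpec = FixtureSpec(),
                     out_dir: str | Path | None = None) -> HgtFixture:
    """Build (and optionally write) the synthetic HGT dataset.

    Writes ``tree.nwk`` (true chronogram), ``alignment.fasta``,
    ``calibrations.tsv``, ``relative_constraints.tsv`` and ``truth.json``
    when ``out_dir`` is given.  Bit-reproducible under a fixed seed.
    """
    n_a = spec.donor_tips // 2
    n_b = spec.donor_tips - n_a
    sub_seed = np.random.SeedSequence(spec.seed).generate_state(5)
    age_rng = np.random.default_rng(int(sub_seed[4]))
    # subtree *shapes* come from the birth-death simulator; their free node
    # ages are then redrawn from the uniform-order process with the crown
    # pinned, matching the node-age prior the dating model assumes
    a = uniform_order_ages(simulate_bd_chronogram(
        n_a, spec.sim_lambda, spec.sim_mu, int(sub_seed[0]),
        labels=[f"AscA{i+1:02d}" for i in range(n_a)]).topology,
        spec.a_crown_age, age_rng)
    b = uniform_order_ages(simulate_bd_chronogram(
        n_b, spec.sim_lambda, spec.sim_mu, int(sub_seed[1]),
        labels=[f"BasB{i+1:02d}" for i in range(n_b)]).topology,
        spec.b_crown_age, age_rng)
    rec = uniform_order_ages(simulate_bd_chronogram(
        spec.recipient_tips, spec.sim_lambda, spec.sim_mu, int(sub_seed[2]),
        labels=[f"BacR{i+1:02d}" for i in range(spec.recipient_tips)]).topology,
        spec.recipient_crown_age, age_rng)
    newick = "((%s:%g,%s:%g):%g,%s:%g);" % (
        _subtree_newick(a), spec.ab_split_age - spec.a_crown_age,
        _subtree_newick(b), spec.ab_split_age - spec.b_crown_age,
        spec.root_age - spec.ab_split_age,
        _subtree_newick(rec), spec.root_age - spec.recipient_crown_age)
    chron = parse_newick_chronogram(newick)
    topo = chron.topology

    ab_node = mrca(topo, "AscA01", "BasB01")
    a_node = mrca(topo, "AscA01", f"AscA{n_a:02d}")
    b_node = mrca(topo, "BasB01", f"BasB{n_b:02d}")
    rec_node = mrca(topo, "BacR01", f"BacR{spec.recipient_tips:02d}")

    cals = []
    for name, node in (("root", topo.root), ("ab_split", ab_node),
                       ("asco_crown", a_node), ("basidio_crown", b_node)):
        ta, tb = _spanning_pair(topo, node)
        lo, hi = spec.windows[name]
        cals.append(Calibration(name=name, taxon_a=ta, taxon_b=tb,
                                lower=lo, upper=hi))
    ta, tb = _spanning_pair(topo, ab_node)
    lo, hi = spec.windows["fossil_ab"]
    cals.append(Calibration(name="fossil_ab", taxon_a=ta, taxon_b=tb,
                            lower=lo, upper=hi))
    older = _spanning_pair(topo, ab_node)
    younger = _spanning_pair(topo, rec_node)
    calset = CalibrationSet(
        root=cals[0], internal=tuple(cals[1:]),
        relative=(RelativeConstraint(older_a=older[0], older_b=older[1],
                                     younger_a=younger[0], younger_b=younger[1]),))

    aln = simulate_relaxed_clock_data(chron, spec.clock, spec.site_model,
                                      spec.n_sites, int(sub_seed[3]))
    truth = {
        "seed": spec.seed,
        "n_sites": spec.n_sites,
        "clock": {"model": spec.clock.model, "mu_r": spec.clock.mu_r,
                  "nu": spec.clock.nu},
        "site_model": {"exchangeabilities": spec.site_model.exchangeabilities,
                       "alpha": spec.site_model.alpha,
                       "categories": spec.site_model.categories},
        "node_ages": {_clade_key(topo, n): float(chron.ages[n])
                      for n in topo.internal_nodes},
        "calibrated_nodes": {
            "root": spec.root_age, "ab_split": spec.ab_split_age,
            "asco_crown": spec.a_crown_age, "basidio_crown": spec.b_crown_age,
            "recipient_crown": spec.recipient_crown_age},
    }
    fixture = HgtFixture(chronogram=chron, alignment=aln, calibrations=calset,
                         truth=truth, spec=spec)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "tree.nwk", "w") as fh:
            fh.write(write_newick(topo, chron) + "\n")
        write_protein_fasta(aln, out / "alignment.fasta")
        write_calibration_tsv(calset, out / "calibrations.tsv",
                              out / "relative_constraints.tsv")
        with open(out / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)
    return fixture


def true_ages_for(topology: Topology, truth: dict) -> dict[int, float]:
    """Map internal node ids of ``topology`` to true ages from a truth record
    (keyed by sorted '|'-joined clade leaf sets)."""
    ages = truth["node_ages"]
    out = {}
    for node in topology.internal_nodes:
        key = _clade_key(topology, node)
        if key in ages:
            out[node] = float(ages[key])
    return out
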