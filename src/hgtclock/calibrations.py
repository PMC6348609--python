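"""Node-age calibrations: hard uniform bounds and relative (older-than)
constraints, resolved to nodes via MRCA of taxon pairs.

Calibrations are keyed by two leaf labels whose most recent common ancestor
receives the bound — the same convention the dating software's command line
uses.  All bounds are uniform with sharp truncation ("hard"), deliberately
avoiding false precision; an HGT event additionally polarizes time between
donor and recipient clades, expressed here as a relative constraint (donor
node strictly older than recipient node).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .trees import Topology, mrca

__all__ = [
    "Calibration",
    "RelativeConstraint",
    "CalibrationSet",
    "ResolvedCalibrations",
    "CalibrationError",
    "load_calibration_table",
    "read_calibration_tsv",
    "read_relative_constraint_tsv",
    "calibration_log_prior",
]

ROOT_NAME = "root"                    # case-insensitive row name marking the root


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class Calibration:
    """Uniform hard age bound (Ma) on the MRCA of two leaf labels."""

    name: str
    taxon_a: str
    taxon_b: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (0 < self.lower < self.upper):
            raise CalibrationError(
                f"calibration {self.name!r}: need 0 < lower < upper, "
                f"got ({self.lower}, {self.upper})")


@dataclass(frozen=True)
class RelativeConstraint:
    """Require MRCA(older pair) strictly older than MRCA(younger pair)."""

    older_a: str
    older_b: str
    younger_a: str
    younger_b: str


@dataclass(frozen=True)
class CalibrationSet:
    """A root calibration (mandatory), internal calibrations, and relative
    constraints, all still expressed as taxon pairs."""

    root: Calibration
    internal: tuple[Calibration, ...] = ()
    relative: tuple[RelativeConstraint, ...] = ()

    def __post_init__(self) -> None:
        names = [self.root.name] + [c.name for c in self.internal]
        if len(set(names)) != len(names):
            raise CalibrationError(f"duplicate calibration names in {names}")

    def subset(self, names: list[str]) -> "CalibrationSet":
        """Keep only the named internal calibrations (root always kept)."""
        by_name = {c.name: c for c in self.internal}
        missing = [n for n in names if n not in by_name]
        if missing:
            raise CalibrationError(f"unknown calibration names: {missing}")
        return CalibrationSet(root=self.root,
                              internal=tuple(by_name[n] for n in names),
                              relative=self.relative)

    def resolve(self, topology: Topology) -> "ResolvedCalibrations":
        """Map every calibration to its node; duplicate targets are an error."""
        root_node = mrca(topology, self.root.taxon_a, self.root.taxon_b)
        if root_node != topology.root:
            raise CalibrationError(
                f"root calibration taxa ({self.root.taxon_a!r}, "
                f"{self.root.taxon_b!r}) resolve to an internal node, not "
                "the tree root")
        assignments: dict[int, Calibration] = {root_node: self.root}
        for cal in self.internal:
            node = mrca(topology, cal.taxon_a, cal.taxon_b)
            if node in assignments:
                raise CalibrationError(
                    f"calibrations {assignments[node].name!r} and "
                    f"{cal.name!r} both resolve to node {node}")
            assignments[node] = cal
        rel_pairs = []
        for rc in self.relative:
            older = mrca(topology, rc.older_a, rc.older_b)
            younger = mrca(topology, rc.younger_a, rc.younger_b)
            if older == younger:
                raise CalibrationError(
                    "relative constraint resolves both ends to the same node")
            rel_pairs.append((older, younger))
        lower = np.zeros(topology.n_nodes)
        upper = np.full(topology.n_nodes, np.inf)
        for node, cal in assignments.items():
            lower[node] = cal.lower
            upper[node] = cal.upper
        return ResolvedCalibrations(
            topology=topology, node_of={c.name: n for n, c in assignments.items()},
            calibration_of={n: c for n, c in assignments.items()},
            root_node=root_node, lower=lower, upper=upper,
            relative_pairs=tuple(rel_pairs))


@dataclass(frozen=True)
class ResolvedCalibrations:
    """Calibrations mapped onto a concrete topology (vectorized bounds)."""

    topology: Topology
    node_of: dict[str, int]
    calibration_of: dict[int, Calibration]
    root_node: int
    lower: np.ndarray
    upper: np.ndarray
    relative_pairs: tuple[tuple[int, int], ...]

    @property
    def root_bounds(self) -> tuple[float, float]:
        return float(self.lower[self.root_node]), float(self.upper[self.root_node])

    def satisfied(self, ages: np.ndarray) -> bool:
        if np.any(ages < self.lower) or np.any(ages > self.upper):
            return False
        return all(ages[o] > ages[y] for o, y in self.relative_pairs)


def calibration_log_prior(chron_or_ages, resolved: ResolvedCalibrations) -> float:
    """0 when every hard bound and relative constraint holds, else ``-inf``."""
    ages = getattr(chron_or_ages, "ages", chron_or_ages)
    return 0.0 if resolved.satisfied(np.asarray(ages, dtype=float)) else -np.inf


def load_calibration_table(rows, relative_rows=()) -> CalibrationSet:
    """Build a :class:`CalibrationSet` from (name, taxonA, taxonB, lower,
    upper) rows; the row named "Root" (case-insensitive) is mandatory.

    A root lower bound of 739 Ma is accepted but flagged: the calibration
    table and the prose of its source disagree by one Ma, and 738 is the
    tabulated convention.
    """
    root = None
    internal: list[Calibration] = []
    for name, ta, tb, lo, hi in rows:
        cal = Calibration(name=str(name), taxon_a=str(ta), taxon_b=str(tb),
                          lower=float(lo), upper=float(hi))
        if str(name).strip().lower() == ROOT_NAME:
            if root is not None:
                raise CalibrationError("multiple root calibration rows")
            if cal.lower == 739.0:
                warnings.warn(
                    "root lower bound given as 739 Ma; the tabulated "
                    "calibration uses 738 Ma (known 738-vs-739 discrepancy)",
                    stacklevel=2)
            root = cal
        else:
            internal.append(cal)
    if root is None:
        raise CalibrationError("a calibration row named 'Root' is required")
    relative = tuple(RelativeConstraint(*map(str, r)) for r in relative_rows)
    return CalibrationSet(root=root, internal=tuple(internal), relative=relative)


def read_calibration_tsv(path: str | Path,
                         relative_path: str | Path | None = None
                         ) -> CalibrationSet:
    """Read calibrations from TSV (header: name taxon1 taxon2 min_age max_age)
    and optionally relative constraints (header: older_taxon1 older_taxon2
    younger_taxon1 younger_taxon2)."""
    rows = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"name", "taxon1", "taxon2", "min_age", "max_age"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise CalibrationError(
                f"calibration TSV must have columns {sorted(required)}")
        for rec in reader:
            rows.append((rec["name"], rec["taxon1"], rec["taxon2"],
                         rec["min_age"], rec["max_age"]))
    relative_rows = []
    if relative_path is not None:
        relative_rows = read_relative_constraint_tsv(relative_path)
    return load_calibration_table(rows, relative_rows)


def read_relative_constraint_tsv(path: str | Path) -> list[tuple[str, str, str, str]]:
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"older_taxon1", "older_taxon2", "younger_taxon1",
                    "younger_taxon2"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise CalibrationError(
                f"relative-constraint TSV must have columns {sorted(required)}")
        for rec in reader:
            out.append((rec["older_taxon1"], rec["older_taxon2"],
                        rec["younger_taxon1"], rec["younger_taxon2"]))
    return out


def write_calibration_tsv(calset: CalibrationSet, path: str | Path,
                          relative_path: str | Path | None = None) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["name", "taxon1", "taxon2", "min_age", "max_age"])
        for cal in (calset.root,) + calset.internal:
            w.writerow([cal.name, cal.taxon_a, cal.taxon_b,
                        "%g" % cal.lower, "%g" % cal.upper])
    if relative_path is not None and calset.relative:
        with open(relative_path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["older_taxon1", "older_taxon2",
                        "younger_taxon1", "younger_taxon2"])
            for rc in calset.relative:
                w.writerow([rc.older_a, rc.older_b, rc.younger_a, rc.younger_b])
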