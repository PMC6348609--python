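"""Protein alignment container, FASTA I/O, and composite-site assembly."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._lg_data import LG_ALPHABET

__all__ = [
    "ProteinAlignment",
    "AlignmentError",
    "read_protein_fasta",
    "write_protein_fasta",
    "extract_and_concatenate_sites",
    "AA_ALPHABET",
    "GAP_CODE",
]

AA_ALPHABET = LG_ALPHABET            # "ARNDCQEGHILKMFPSTWYV"
GAP_CODE = 20                        # shared code for gap '-' and ambiguity 'X'
_CODE = {aa: i for i, aa in enumerate(AA_ALPHABET)}
_CODE["-"] = GAP_CODE
_CODE["X"] = GAP_CODE


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class ProteinAlignment:
    """Amino-acid alignment: rows are taxa, columns are homologous sites.

    States are stored as integer codes 0..19 over ``AA_ALPHABET``; gaps ('-')
    and ambiguities ('X') share the missing-data code ``GAP_CODE`` and are
    treated as missing in the likelihood.
    """

    taxa: tuple[str, ...]
    codes: np.ndarray                  # (n_taxa, n_sites) uint8

    def __post_init__(self) -> None:
        if len(set(self.taxa)) != len(self.taxa):
            raise AlignmentError("duplicate taxon names in alignment")
        if self.codes.ndim != 2 or self.codes.shape[0] != len(self.taxa):
            raise AlignmentError("codes must be (n_taxa, n_sites)")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return int(self.codes.shape[1])

    def row(self, taxon: str) -> np.ndarray:
        try:
            return self.codes[self.taxa.index(taxon)]
        except ValueError:
            raise AlignmentError(f"taxon {taxon!r} not in alignment") from None

    def sequence(self, taxon: str) -> str:
        symbols = AA_ALPHABET + "-"
        return "".join(symbols[c] for c in self.row(taxon))

    def empirical_frequencies(self, pseudocount: float = 0.0) -> np.ndarray:
        """Observed amino-acid frequencies over non-missing cells."""
        counts = np.bincount(self.codes[self.codes < 20].ravel(), minlength=20)
        counts = counts.astype(float) + pseudocount
        if counts.sum() == 0:
            raise AlignmentError("alignment contains no observed residues")
        return counts / counts.sum()

    @classmethod
    def from_sequences(cls, records: dict[str, str] | list[tuple[str, str]]
                       ) -> "ProteinAlignment":
        items = list(records.items()) if isinstance(records, dict) else list(records)
        if not items:
            raise AlignmentError("empty alignment")
        lengths = {len(s) for _, s in items}
        if len(lengths) != 1:
            raise AlignmentError(f"ragged alignment rows (lengths {sorted(lengths)})")
        taxa = tuple(n for n, _ in items)
        n_sites = lengths.pop()
        codes = np.empty((len(items), n_sites), dtype=np.uint8)
        for r, (name, seq) in enumerate(items):
            for c, ch in enumerate(seq.upper()):
                try:
                    codes[r, c] = _CODE[ch]
                except KeyError:
                    raise AlignmentError(
                        f"illegal character {ch!r} in sequence {name!r}"
                    ) from None
        return cls(taxa=taxa, codes=codes)


def read_protein_fasta(path: str | Path) -> ProteinAlignment:
    """Read a protein FASTA alignment; headers truncate at first whitespace."""
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise AlignmentError(f"no FASTA records found in {path}")
    return ProteinAlignment.from_sequences(records)


def write_protein_fasta(aln: ProteinAlignment, path: str | Path) -> None:
    recs = [SeqRecord(Seq(aln.sequence(t)), id=t, description="") for t in aln.taxa]
    SeqIO.write(recs, str(path), "fasta")


def extract_and_concatenate_sites(aln: ProteinAlignment,
                                  ranges: list[tuple[int, int]]
                                  ) -> ProteinAlignment:
    """Build a composite alignment by concatenating 1-based inclusive site
    intervals (e.g. ``[(1844, 2470)]`` keeps 627 columns).

    Intervals must be in ascending order, non-overlapping and within
    ``1..n_sites``.
    """
    if not ranges:
        raise AlignmentError("at least one site range is required")
    prev_end = 0
    pieces = []
    for lo, hi in ranges:
        if lo > hi:
            raise AlignmentError(f"inverted site range ({lo}, {hi})")
        if lo < 1 or hi > aln.n_sites:
            raise AlignmentError(
                f"site range ({lo}, {hi}) outside 1..{aln.n_sites}")
        if lo <= prev_end:
            raise AlignmentError("site ranges must be ascending and disjoint")
        prev_end = hi
        pieces.append(aln.codes[:, lo - 1:hi])
    return ProteinAlignment(taxa=aln.taxa, codes=np.concatenate(pieces, axis=1))
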