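"""Nucleotide alignments and species-partition tables.

Every downstream stage (distances, saturation, barcode-gap binning, tree
likelihoods) consumes the :class:`Alignment` defined here: an equal-length
block of nucleotide rows keyed by unique taxon labels, plus a boolean
column-inclusion mask used to prune non-alignable regions before analysis.
Species assignments come in as a two-column taxon->species table
(:class:`SpeciesPartition`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# Alphabet after normalisation (lowercase -> uppercase, U -> T).
VALID_CHARS = frozenset(b"ACGTN-?")
# '-' and '?' are both treated as gap/missing downstream.
MISSING_CHARS = frozenset(b"N-?")
BASES = b"ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}


class AlignmentError(ValueError):
    """Raised for malformed alignments or partition tables."""


@dataclass
class Alignment:
    """Equal-length nucleotide rows with a column-inclusion mask.

    Attributes
    ----------
    taxa:
        Ordered, unique, non-empty labels, one per row.
    rows:
        ``(n_taxa, length)`` byte array (dtype ``S1``) over ``A C G T N - ?``.
    included_columns:
        Boolean mask, one flag per column; excluded columns are ignored by
        every analysis that honours the mask (``masked_rows``).
    """

    taxa: list[str]
    rows: np.ndarray
    included_columns: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype="S1")
        if self.rows.ndim != 2:
            raise AlignmentError("rows must be a 2-D character block")
        if len(self.taxa) != self.rows.shape[0]:
            raise AlignmentError("one taxon label required per row")
        if len(set(self.taxa)) != len(self.taxa):
            dup = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise AlignmentError(f"duplicate taxon label(s): {', '.join(dup)}")
        if any(not t for t in self.taxa):
            raise AlignmentError("empty taxon label")
        if self.included_columns is None:
            self.included_columns = np.ones(self.rows.shape[1], dtype=bool)
        self.included_columns = np.asarray(self.included_columns, dtype=bool)
        if self.included_columns.shape != (self.rows.shape[1],):
            raise AlignmentError("mask length must equal alignment length")
        bad = set(self.rows.tobytes()) - {c for c in VALID_CHARS}
        if bad:
            chars = ", ".join(chr(c) for c in sorted(bad))
            raise AlignmentError(
                f"unsupported character(s) in alignment: {chars} "
                "(ambiguity codes beyond N are rejected)"
            )

    # -- basic geometry -------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def length(self) -> int:
        return int(self.rows.shape[1])

    @property
    def masked_length(self) -> int:
        return int(self.included_columns.sum())

    def masked_rows(self) -> np.ndarray:
        """Rows restricted to included columns (a copy)."""
        return self.rows[:, self.included_columns]

    def row(self, taxon: str) -> np.ndarray:
        """Masked sequence row for ``taxon``."""
        try:
            i = self.taxa.index(taxon)
        except ValueError:
            raise AlignmentError(f"unknown taxon: {taxon}") from None
        return self.rows[i, self.included_columns]

    def subset(self, taxa: Sequence[str]) -> "Alignment":
        idx = [self.taxa.index(t) for t in taxa]
        return Alignment(list(taxa), self.rows[idx].copy(), self.included_columns.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Alignment):
            return NotImplemented
        return (
            self.taxa == other.taxa
            and self.rows.shape == other.rows.shape
            and bool((self.rows == other.rows).all())
            and bool((self.included_columns == other.included_columns).all())
        )


def _normalise(seq: str) -> bytes:
    return seq.upper().replace("U", "T").encode("ascii")


def alignment_from_dict(data: Mapping[str, str]) -> Alignment:
    """Build an :class:`Alignment` from ``{taxon: sequence}`` (test helper)."""
    taxa = list(data)
    rows = [_normalise(data[t]) for t in taxa]
    lengths = {len(r) for r in rows}
    if len(lengths) > 1:
        raise AlignmentError(f"ragged alignment: row lengths {sorted(lengths)}")
    arr = np.frombuffer(b"".join(rows), dtype="S1").reshape(len(taxa), -1)
    return Alignment(taxa, arr.copy())


def read_alignment(path: str | Path, format: str = "fasta") -> Alignment:
    """Read a FASTA alignment; lowercase and U are normalised, mask all-true.

    Raises :class:`AlignmentError` on ragged rows, duplicate labels, fewer
    than two records or characters outside ``A C G T U N - ?``.
    """
    if format != "fasta":
        raise AlignmentError(f"unsupported alignment format: {format}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 2:
        raise AlignmentError(f"{path}: need at least 2 sequences, found {len(records)}")
    taxa: list[str] = []
    rows: list[bytes] = []
    for rec in records:
        if rec.id in taxa:
            raise AlignmentError(f"{path}: duplicate taxon label: {rec.id}")
        taxa.append(rec.id)
        rows.append(_normalise(str(rec.seq)))
    lengths = {len(r) for r in rows}
    if len(lengths) > 1:
        raise AlignmentError(
            f"{path}: ragged alignment, row lengths {sorted(lengths)}"
        )
    arr = np.frombuffer(b"".join(rows), dtype="S1").reshape(len(taxa), -1)
    return Alignment(taxa, arr.copy())


def write_alignment(aln: Alignment, path: str | Path, wrap: int = 70) -> None:
    """Write the full (unmasked) alignment as wrapped FASTA."""
    records = [
        SeqRecord(Seq(aln.rows[i].tobytes().decode("ascii")), id=t, description="")
        for i, t in enumerate(aln.taxa)
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(records)


def apply_column_mask(
    aln: Alignment, excluded_ranges: Iterable[tuple[int, int]]
) -> Alignment:
    """Exclude 1-based closed column intervals from the alignment mask.

    Intervals may overlap; the union is excluded. Masking is applied on top
    of any existing exclusions and is idempotent.
    """
    mask = aln.included_columns.copy()
    for lo, hi in excluded_ranges:
        if not (1 <= lo <= hi <= aln.length):
            raise AlignmentError(
                f"interval [{lo},{hi}] out of bounds for length {aln.length}"
            )
        mask[lo - 1 : hi] = False
    return Alignment(list(aln.taxa), aln.rows.copy(), mask)


def read_mask_intervals(path: str | Path) -> list[tuple[int, int]]:
    """Sidecar mask file: one ``lo<TAB>hi`` (1-based closed) interval per line."""
    out: list[tuple[int, int]] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        lo, hi = line.split()[:2]
        out.append((int(lo), int(hi)))
    return out


@dataclass
class SpeciesPartition:
    """Mapping taxon label -> species identifier."""

    assignments: dict[str, str]

    @property
    def species(self) -> dict[str, list[str]]:
        """Species identifier -> member taxa (insertion-ordered)."""
        out: dict[str, list[str]] = {}
        for taxon, sp in self.assignments.items():
            out.setdefault(sp, []).append(taxon)
        return out

    @property
    def sizes(self) -> dict[str, int]:
        return {sp: len(members) for sp, members in self.species.items()}

    @property
    def n_species(self) -> int:
        return len(self.species)

    def species_of(self, taxon: str) -> str | None:
        return self.assignments.get(taxon)

    def unassigned(self, taxa: Iterable[str]) -> list[str]:
        return [t for t in taxa if t not in self.assignments]

    def intraspecific_pair_count(self) -> int:
        return sum(n * (n - 1) // 2 for n in self.sizes.values())


def read_species_partition(path: str | Path) -> SpeciesPartition:
    """Read a two-column ``taxon TAB species`` table; '#' lines are comments.

    A taxon listed twice with conflicting species raises; repeated identical
    rows are tolerated. Taxa absent from the table are simply unassigned.
    """
    assignments: dict[str, str] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split("\t") if "\t" in stripped else stripped.split()
        if len(parts) < 2:
            raise AlignmentError(f"{path}:{ln}: expected 'taxon<TAB>species'")
        taxon, sp = parts[0], parts[1]
        if taxon in assignments and assignments[taxon] != sp:
            raise AlignmentError(
                f"{path}:{ln}: taxon {taxon} assigned to both "
                f"{assignments[taxon]} and {sp}"
            )
        assignments[taxon] = sp
    return SpeciesPartition(assignments)


def write_species_partition(part: SpeciesPartition, path: str | Path) -> None:
    with open(path, "w") as fh:
        for taxon, sp in part.assignments.items():
            fh.write(f"{taxon}\t{sp}\n")
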