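"""Protein sequence sets: FASTA ingest, validation, gap stripping.

The pipeline is alignment-free, so aligned FASTA input is legal: gap
characters (``-``, ``.``) are stripped on ingest and every record is
treated as an unaligned protein sequence.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
#: tolerated on input: ambiguity codes and selenocysteine; never perturbed
AMBIGUOUS_AA = "BZXU"
VALID_AA = set(STANDARD_AA + AMBIGUOUS_AA)
GAP_CHARS = "-."

#: characters unsafe inside Newick labels, replaced by "_" on ingest
_NEWICK_UNSAFE = re.compile(r"[\s()\[\]:;,']")


class SequenceError(ValueError):
    """Invalid sequence input (bad residues, duplicate ids, empty sets)."""


@dataclass(frozen=True)
class ProteinSequence:
    """A single protein sequence with a unique identifier.

    ``residues`` is upper-case, gap-free, and restricted to the 20
    standard amino-acid letters plus the tolerated codes B, Z, X, U.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("sequence id must be non-empty")
        if not self.residues:
            raise SequenceError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - VALID_AA
        if bad:
            raise SequenceError(
                f"sequence {self.id!r} contains invalid characters: "
                f"{''.join(sorted(bad))}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class SequenceSet:
    """An ordered collection of uniquely-identified protein sequences."""

    sequences: list[ProteinSequence] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.sequences]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise SequenceError(f"duplicate sequence ids: {sorted(dupes)}")

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.sequences]

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self) -> Iterator[ProteinSequence]:
        return iter(self.sequences)

    def __getitem__(self, key: int | str) -> ProteinSequence:
        if isinstance(key, str):
            for s in self.sequences:
                if s.id == key:
                    return s
            raise KeyError(key)
        return self.sequences[key]

    def require_min_taxa(self, n: int = 4) -> None:
        """Raise unless the set holds at least ``n`` sequences.

        Tree inference needs at least 4 taxa for a non-trivial unrooted
        topology.
        """
        if len(self) < n:
            raise SequenceError(
                f"fewer than {n} sequences ({len(self)}); "
                "tree inference requires at least 4"
            )


def sanitize_id(raw: str) -> str:
    """Replace Newick-unsafe characters (spaces, parens, colons...) by '_'."""
    return _NEWICK_UNSAFE.sub("_", raw)


def strip_gaps(residues: str) -> str:
    out = residues
    for g in GAP_CHARS:
        out = out.replace(g, "")
    return out


def read_fasta(path: str | Path, id_map_path: str | Path | None = None) -> SequenceSet:
    """Read a multi-record FASTA file into a :class:`SequenceSet`.

    Gap characters are stripped, residues upper-cased, and ids taken as
    the header up to the first whitespace with Newick-unsafe characters
    replaced by underscores.  If any id was rewritten and
    ``id_map_path`` is given, an original->sanitized mapping table is
    written there.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    seqs = []
    remapped: list[tuple[str, str]] = []
    for rec in records:
        raw_id = rec.id
        clean_id = sanitize_id(raw_id)
        if clean_id != raw_id:
            remapped.append((raw_id, clean_id))
        residues = strip_gaps(str(rec.seq).upper())
        if not residues:
            raise SequenceError(f"record {raw_id!r} is empty after gap stripping")
        seqs.append(ProteinSequence(clean_id, residues))
    if remapped:
        logger.warning(
            "sanitized %d sequence id(s) containing Newick-unsafe characters",
            len(remapped),
        )
        if id_map_path is not None:
            with open(id_map_path, "w") as fh:
                fh.write("original\tsanitized\n")
                for orig, clean in remapped:
                    fh.write(f"{orig}\t{clean}\n")
    return SequenceSet(seqs)


def write_fasta(seqs: SequenceSet | Iterable[ProteinSequence], path: str | Path,
                width: int = 80) -> None:
    """Write sequences as wrapped FASTA; round-trips through read_fasta."""
    seq_list = list(seqs)
    if not seq_list:
        raise SequenceError("refusing to write an empty sequence set")
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in seq_list
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)
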