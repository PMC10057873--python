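"""Protein and peptide sequence records, FASTA I/O, and the rice storage
proteins reconstructed from their published digestion-fragment lists.

The two study substrates — rice prolamin and rice glutelin — are shipped as
plain-text fragment lists (one hydrolysis product per line, in digestion
order).  Concatenating the fragments in order restores the parent sequence,
so the package is self-contained: no database download is needed to run the
full screening pipeline.

Coordinates are 0-based, half-open throughout.  Only the 20 canonical
one-letter residue codes are accepted; ambiguity codes (B/Z/X) and
non-standard residues (U/O) are rejected because the cleavage rules and the
physicochemical contribution tables are defined only for canonical residues.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

__all__ = [
    "CANONICAL_RESIDUES",
    "ProteinRecord",
    "PeptideFragment",
    "read_fasta",
    "write_fasta",
    "reconstruct_from_fragments",
    "load_fragment_list",
    "rice_prolamin",
    "rice_glutelin",
    "study_proteins",
]


class SequenceError(ValueError):
    """Raised for malformed sequence input (illegal residue, empty record)."""


def validate_residues(sequence: str, *, context: str = "sequence") -> str:
    """Uppercase *sequence* and reject any character outside the 20
    canonical one-letter codes, reporting the 1-based offending position."""
    seq = sequence.upper()
    for pos, ch in enumerate(seq, start=1):
        if ch not in CANONICAL_RESIDUES:
            raise SequenceError(
                f"illegal residue {ch!r} at position {pos} in {context}"
            )
    return seq


@dataclass(frozen=True)
class ProteinRecord:
    """A named amino-acid sequence with provenance.

    Parameters
    ----------
    id:
        Short identifier, unique within a collection.
    sequence:
        Uppercase one-letter amino-acid string (canonical residues only).
    name:
        Free-text description.
    source:
        Provenance note, e.g. ``"reconstructed from published fragment list"``.
    """

    id: str
    sequence: str
    name: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("record id must be non-empty")
        if not self.sequence:
            raise SequenceError(f"record {self.id!r} has an empty sequence")
        object.__setattr__(
            self, "sequence", validate_residues(self.sequence, context=f"record {self.id!r}")
        )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PeptideFragment:
    """A digest product located in its parent protein.

    ``start``/``end`` are 0-based half-open offsets into the parent, so
    ``parent.sequence[start:end] == sequence`` and
    ``end - start == len(sequence)``.
    """

    sequence: str
    parent_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.sequence:
            raise SequenceError("fragment sequence must be non-empty")
        if self.end - self.start != len(self.sequence):
            raise SequenceError(
                f"fragment coordinates [{self.start}, {self.end}) do not match "
                f"sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a multi-record FASTA file into :class:`ProteinRecord` objects.

    Sequences are uppercased; any character outside the canonical 20 is
    rejected with its position.  An empty or record-less file is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise SequenceError(f"duplicate record id {entry.id!r} in {path}")
        seen.add(entry.id)
        records.append(
            ProteinRecord(
                id=entry.id,
                sequence=str(entry.seq),
                name=entry.description,
                source=str(path),
            )
        )
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Sequence[ProteinRecord], path: str | Path, *, width: int = 80) -> None:
    """Write records as wrapped FASTA; round-trips id and sequence exactly."""
    if not records:
        raise SequenceError("refusing to write an empty record list")
    seqrecords = [
        SeqRecord(Seq(rec.sequence), id=rec.id, description=rec.name or "")
        for rec in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seqrecords)


def reconstruct_from_fragments(
    fragments: Iterable[str],
    id: str,
    *,
    name: str = "",
    source: str = "reconstructed from fragment list",
) -> ProteinRecord:
    """Rebuild a parent protein by concatenating digestion fragments in order.

    The published hydrolysis tables list every released fragment in
    N-to-C order, so in-order concatenation restores the substrate exactly;
    the resulting length equals the sum of the fragment lengths.
    """
    frags = [validate_residues(f, context=f"fragment {i}") for i, f in enumerate(fragments, 1)]
    if not frags:
        raise SequenceError("fragment list is empty")
    if any(not f for f in frags):
        raise SequenceError("fragments must be non-empty")
    return ProteinRecord(id=id, sequence="".join(frags), name=name, source=source)


def _data_path(filename: str):
    return importlib.resources.files("oryzapep.data").joinpath(filename)


def load_fragment_list(path_or_name: str | Path) -> list[str]:
    """Read a plain-text fragment list (one fragment per line, ``#`` comments).

    *path_or_name* may be a filesystem path or the bare name of a packaged
    fixture (``"prolamin_fragments.txt"``, ``"glutelin_fragments.txt"``).
    """
    p = Path(path_or_name)
    if p.exists():
        text = p.read_text()
    else:
        resource = _data_path(str(path_or_name))
        if not resource.is_file():
            raise FileNotFoundError(path_or_name)
        text = resource.read_text()
    frags = [
        line.strip() for line in text.splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    ]
    if not frags:
        raise SequenceError(f"no fragments found in {path_or_name}")
    return frags


def rice_prolamin() -> ProteinRecord:
    """Rice prolamin (BIOPEP UWM entry 1153), reconstructed from the packaged
    digestion-fragment list."""
    return reconstruct_from_fragments(
        load_fragment_list("prolamin_fragments.txt"),
        id="prolamin",
        name="rice prolamin storage protein",
        source="reconstructed from packaged hydrolysis fragment list (BIOPEP UWM 1153)",
    )


def rice_glutelin() -> ProteinRecord:
    """Rice glutelin (BIOPEP UWM entry 1536), reconstructed from the packaged
    digestion-fragment list."""
    return reconstruct_from_fragments(
        load_fragment_list("glutelin_fragments.txt"),
        id="glutelin",
        name="rice glutelin storage protein",
        source="reconstructed from packaged hydrolysis fragment list (BIOPEP UWM 1536)",
    )


def study_proteins() -> list[ProteinRecord]:
    """Both rice storage-protein substrates of the screening study."""
    return [rice_glutelin(), rice_prolamin()]
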