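"""Canonical residue numbering on the human βIII coordinate system.

β-tubulins are highly similar (>90% identity through position ~424), so every
input sequence can be placed on a single shared coordinate system by pairwise
global alignment against one reference. All positions used elsewhere in this
package (signature positions, the 124–129 cysteine cluster, the 237–240 window,
tail landmarks 436/437/444) are 1-based positions on that reference.

The bundled reference is a *synthetic* 450-residue βIII-like sequence: every
landmark residue is planted from the curated signature scheme, the rest is
fixed filler (see ``data/betaIII_reference_synthetic.fasta``). It defines the
coordinate system; it is not the database accession.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from functools import cached_property
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: the 20 standard residues plus X (unknown)
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
VALID_LETTERS = AMINO_ACIDS | {"X"}

#: first canonical position of the hypervariable C-terminal tail
TAIL_START = 425

_REFERENCE_RESOURCE = "betaIII_reference_synthetic.fasta"


class FastaParseError(ValueError):
    """Raised when a FASTA file cannot be parsed into valid records."""


class NotHomologError(ValueError):
    """Raised when a query is too diverged for canonical numbering to be meaningful."""


@dataclass(frozen=True)
class SequenceRecord:
    """One amino-acid sequence with identifying metadata."""

    id: str
    residues: str
    species: str = ""
    isotype_label: str = "unknown"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.residues:
            raise ValueError(f"{self.id}: residue string must be non-empty")
        bad = set(self.residues) - VALID_LETTERS
        if bad:
            raise ValueError(
                f"{self.id}: illegal residue letters {sorted(bad)} "
                "(expected the 20 standard amino acids or X)"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ReferenceSequence:
    """The canonical reference fixing the coordinate system."""

    residues: str
    name: str = "betaIII-reference"

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class NumberingMap:
    """Correspondence between a query's residue indices and canonical positions.

    ``pairs`` holds (sequence_index, canonical_position), both 1-based and each
    strictly increasing. ``insertions`` are runs of query residues with no
    canonical home, recorded as (after_canonical_position, length); a leading
    overhang is recorded after position 0. ``unmapped_canonical`` are reference
    positions with no query residue.
    """

    pairs: tuple[tuple[int, int], ...]
    insertions: tuple[tuple[int, int], ...]
    unmapped_canonical: frozenset[int]
    identity: float = field(default=0.0, compare=False)

    @cached_property
    def _by_canonical(self) -> dict[int, int]:
        return {canon: seq for seq, canon in self.pairs}

    def sequence_index(self, canonical_position: int) -> int | None:
        """1-based query index mapped to a canonical position, or None."""
        if canonical_position < 1:
            raise ValueError(f"canonical positions are 1-based, got {canonical_position}")
        return self._by_canonical.get(canonical_position)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sequence_index\tcanonical_position\n")
            for seq, canon in self.pairs:
                fh.write(f"{seq}\t{canon}\n")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (possibly empty) multi-record FASTA file into SequenceRecords.

    The header token before the first whitespace becomes the record id, the
    remainder of the header the species field. Sequences are uppercased.
    Illegal residue letters or duplicate ids raise :class:`FastaParseError`
    naming the offending entry and line.
    """
    path = Path(path)
    text = path.read_text()
    # pre-scan for line numbers so parse errors can name the line
    header_lines: dict[str, int] = {}
    current_id = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            token = line[1:].split()[0] if line[1:].split() else ""
            if not token:
                raise FastaParseError(f"{path}:{lineno}: malformed FASTA header {line!r}")
            if token in header_lines:
                raise FastaParseError(
                    f"{path}:{lineno}: duplicate record id {token!r} "
                    f"(first seen at line {header_lines[token]})"
                )
            header_lines[token] = lineno
            current_id = token
        elif current_id is None:
            raise FastaParseError(f"{path}:{lineno}: sequence data before any FASTA header")
        else:
            bad = set(line.upper()) - VALID_LETTERS
            if bad:
                raise FastaParseError(
                    f"{path}:{lineno}: illegal residue letters {sorted(bad)} in {current_id!r}"
                )

    records = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        description = rec.description[len(rec.id):].strip()
        records.append(
            SequenceRecord(id=rec.id, residues=str(rec.seq).upper(), species=description)
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    seqrecords = [
        SeqRecord(Seq(r.residues), id=r.id, description=r.species) for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(seqrecords, fh, "fasta")


def load_reference() -> ReferenceSequence:
    """Load the bundled synthetic βIII-like reference (450 residues)."""
    data = resources.files("tubsig.data").joinpath(_REFERENCE_RESOURCE).read_text()
    rec = next(SeqIO.parse(io.StringIO(data), "fasta"))
    return ReferenceSequence(residues=str(rec.seq), name=rec.id)


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    # end gaps on the C-terminal side are free: tails vary wildly in length
    aligner.open_right_insertion_score = 0.0
    aligner.extend_right_insertion_score = 0.0
    aligner.open_right_deletion_score = 0.0
    aligner.extend_right_deletion_score = 0.0
    return aligner


def build_numbering_map(
    query: str,
    reference: str,
    *,
    min_identity: float = 0.4,
) -> NumberingMap:
    """Globally align ``query`` to ``reference`` and derive the numbering map.

    Aligned (non-gap) columns become pairs; query residues aligned to
    reference gaps become insertion records. Alignments below ``min_identity``
    (identical / aligned columns) raise :class:`NotHomologError`, since
    canonical numbering is meaningless for a non-homolog.
    """
    if not query or not reference:
        raise ValueError("query and reference must be non-empty")
    query = query.upper()
    alignment = _make_aligner().align(reference, query)[0]

    counts = alignment.counts()
    identity = counts.identities / counts.aligned if counts.aligned else 0.0
    if identity < min_identity:
        raise NotHomologError(
            f"alignment identity {identity:.2f} below floor {min_identity:.2f}; "
            "query does not look like a tubulin homolog of the reference"
        )

    ref_blocks, qry_blocks = alignment.aligned
    pairs: list[tuple[int, int]] = []
    insertions: list[tuple[int, int]] = []
    prev_ref_end = 0
    prev_qry_end = 0
    for (rstart, rend), (qstart, qend) in zip(ref_blocks.tolist(), qry_blocks.tolist()):
        if qstart > prev_qry_end:  # query residues with no reference column
            insertions.append((prev_ref_end, qstart - prev_qry_end))
        for offset in range(rend - rstart):
            pairs.append((qstart + offset + 1, rstart + offset + 1))
        prev_ref_end, prev_qry_end = rend, qend
    if len(query) > prev_qry_end:  # trailing overhang past the reference end
        insertions.append((prev_ref_end, len(query) - prev_qry_end))

    mapped = {canon for _, canon in pairs}
    unmapped = frozenset(range(1, len(reference) + 1)) - mapped
    return NumberingMap(
        pairs=tuple(pairs),
        insertions=tuple(insertions),
        unmapped_canonical=frozenset(unmapped),
        identity=identity,
    )


def residue_at(
    record: SequenceRecord, numbering: NumberingMap, canonical_position: int
) -> str | None:
    """Query residue at a canonical position, or None where unmapped."""
    idx = numbering.sequence_index(canonical_position)
    if idx is None:
        return None
    return record.residues[idx - 1]


def split_tail(
    record: SequenceRecord, numbering: NumberingMap, tail_start: int = TAIL_START
) -> tuple[str, str]:
    """Split a sequence into (core, C-terminal tail) at a canonical boundary.

    The tail runs from the first residue mapped at or past ``tail_start``
    through the end of the query, so insertion residues past the last mapped
    pair stay with the tail. A sequence ending before ``tail_start`` yields an
    empty tail. ``core + tail`` always reconstructs the original residues.
    """
    if tail_start < 1:
        raise ValueError(f"tail_start must be >= 1, got {tail_start}")
    in_tail = [seq for seq, canon in numbering.pairs if canon >= tail_start]
    if in_tail:
        cut = min(in_tail) - 1
    elif numbering.pairs:
        cut = max(seq for seq, _ in numbering.pairs)
    else:
        cut = len(record.residues)
    return record.residues[:cut], record.residues[cut:]
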