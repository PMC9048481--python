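"""The 25-position βIII residue signature and match counting.

Vertebrate βIII-tubulin differs from the βI/βII/βIV isotypes at 25 canonical
positions that are strongly conserved across vertebrate βIII sequences. Three
curated subsets matter downstream: the eight positions conserved in every
vertebrate βIII examined and distinct from βI/βII/βIV (``universal8``); the
twelve positions where human βV carries the βIII residue (``betaV12``); and
the seventeen positions hit by toward-βIII mutations in breast tumors
(``cancer_mutated17``).

Reference residue matrices for the vertebrate isotypes, the βVI comparison
panel, and the invertebrate comparison panel ship as versioned tab-separated
fixtures (``table1``/``table2``/``table3``). Each fixture carries its own βIII
reference column as printed in its source; comparisons against a fixture use
that column (the fixtures disagree at position 189 — I in the vertebrate
matrix, L in the invertebrate one — and match counts are only reproducible
with the per-table column).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

from .numbering import NumberingMap, SequenceRecord, residue_at

#: the 25 canonical signature positions, in table order
SIGNATURE_POSITIONS: tuple[int, ...] = (
    33, 35, 37, 48, 55, 56, 57, 80, 83, 84, 91, 124, 126, 155, 189, 218,
    239, 275, 315, 332, 333, 335, 351, 364, 365,
)

#: conserved in every vertebrate βIII examined, distinct from βI/βII/βIV
UNIVERSAL8 = frozenset({35, 56, 84, 124, 189, 239, 275, 351})

#: positions where human βV is identical to human βIII
BETAV12 = frozenset({37, 55, 56, 91, 124, 239, 315, 332, 333, 335, 351, 365})

#: signature positions mutated toward βIII in breast cancer patients
CANCER_MUTATED17 = frozenset(
    {33, 35, 48, 124, 126, 155, 189, 218, 239, 275, 315, 332, 333, 335, 351, 364, 365}
)

#: extra positions the motif module needs (cysteine-cluster window 124–129 and
#: the 237–240 window around position 239)
MOTIF_POSITIONS: tuple[int, ...] = (125, 127, 128, 129, 237, 238, 240)

#: everything a profile carries
PROFILE_POSITIONS: tuple[int, ...] = tuple(
    sorted(set(SIGNATURE_POSITIONS) | set(MOTIF_POSITIONS))
)

_FIXTURES = {"table1", "table2", "table3"}
_TABLE_REFERENCE_COLUMN = {"table1": "betaIII_Hs", "table2": "betaIII_Hs", "table3": "betaIII"}


class FixtureIntegrityError(ValueError):
    """A bundled fixture is missing required rows; fixtures are never silently patched."""


@dataclass(frozen=True)
class ResidueProfile:
    """One sequence's residues at the signature (and motif) positions."""

    sequence_id: str
    residues: Mapping[int, str | None]

    def get(self, position: int) -> str | None:
        return self.residues.get(position)


@dataclass(frozen=True)
class SignatureScheme:
    """The ordered signature positions, per-isotype reference residues, and subsets."""

    positions: tuple[int, ...]
    reference_profiles: Mapping[str, ResidueProfile]
    subsets: Mapping[str, frozenset[int]]
    structure_note: Mapping[int, str] = field(default_factory=dict)

    def reference_residue(self, isotype_label: str, position: int) -> str | None:
        return self.reference_profiles[isotype_label].get(position)


@dataclass(frozen=True)
class MatchReport:
    """Per-sequence twin of one comparison-table row: three match counts plus motifs."""

    sequence_id: str
    match_flags: Mapping[int, bool]
    count_all: int
    count_betaV12: int
    count_universal8: int
    cluster_present: bool
    cluster_hexamer: str
    region239_tetramer: str


def load_fixture_matrix(table_name: str) -> dict[str, ResidueProfile]:
    """Load one bundled residue matrix as {column label -> ResidueProfile}.

    Rows are canonical positions; '-' cells mean the residue is not recorded.
    A fixture missing any of the 25 signature positions raises
    :class:`FixtureIntegrityError`.
    """
    if table_name not in _FIXTURES:
        raise ValueError(f"unknown fixture {table_name!r}; expected one of {sorted(_FIXTURES)}")
    text = resources.files("tubsig.data").joinpath(f"{table_name}.tsv").read_text()
    lines = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    header = lines[0].split("\t")
    labels = header[1:]
    columns: dict[str, dict[int, str | None]] = {lab: {} for lab in labels}
    for ln in lines[1:]:
        cells = ln.split("\t")
        pos = int(cells[0])
        for lab, cell in zip(labels, cells[1:]):
            columns[lab][pos] = None if cell == "-" else cell
    for lab, col in columns.items():
        missing = set(SIGNATURE_POSITIONS) - set(col)
        if missing:
            raise FixtureIntegrityError(
                f"{table_name}: column {lab!r} missing positions {sorted(missing)}"
            )
    return {lab: ResidueProfile(sequence_id=lab, residues=col) for lab, col in columns.items()}


def table_reference_profile(table_name: str) -> ResidueProfile:
    """The βIII reference column of a fixture, as printed in that table."""
    return load_fixture_matrix(table_name)[_TABLE_REFERENCE_COLUMN[table_name]]


def _load_structure_notes() -> dict[int, str]:
    text = resources.files("tubsig.data").joinpath("structure_notes.tsv").read_text()
    notes = {}
    for ln in text.splitlines()[1:]:
        pos, loc, chemo = ln.split("\t")
        notes[int(pos)] = loc if chemo == "-" else f"{loc} (chemo: {chemo})"
    return notes


def default_scheme() -> SignatureScheme:
    """The curated scheme: vertebrate-isotype reference profiles plus HMBG βIII.

    ``HMBG-betaIII`` is the βIII profile shared by human, mouse, bovine, and
    chicken, taken from the invertebrate comparison table as printed there.
    """
    table1 = load_fixture_matrix("table1")
    profiles = {
        "betaIII": table1["betaIII_Hs"],
        "betaI": table1["betaI"],
        "betaIIA": table1["betaIIA"],
        "betaIIB": table1["betaIIB"],
        "betaIVA": table1["betaIVA"],
        "betaIVB": table1["betaIVB"],
        "betaV": table1["betaV"],
        "betaVI": table1["betaVI"],
        "HMBG-betaIII": load_fixture_matrix("table3")["betaIII"],
    }
    return SignatureScheme(
        positions=SIGNATURE_POSITIONS,
        reference_profiles=profiles,
        subsets={
            "universal8": UNIVERSAL8,
            "betaV12": BETAV12,
            "cancer_mutated17": CANCER_MUTATED17,
            "all25": frozenset(SIGNATURE_POSITIONS),
        },
        structure_note=_load_structure_notes(),
    )


def extract_profile(
    record: SequenceRecord, numbering: NumberingMap, scheme: SignatureScheme
) -> ResidueProfile:
    """Read the query residue at every scheme and motif position (None where unmapped)."""
    wanted = sorted(set(scheme.positions) | set(MOTIF_POSITIONS))
    residues = {pos: residue_at(record, numbering, pos) for pos in wanted}
    return ResidueProfile(sequence_id=record.id, residues=residues)


def _residues_match(a: str | None, b: str | None) -> bool:
    # X and absent never match, even against themselves
    return a is not None and b is not None and a == b and a != "X"


def match_count(
    profile: ResidueProfile,
    reference_profile: ResidueProfile,
    subset: Iterable[int],
) -> int:
    """Count subset positions where the profile equals the reference residue."""
    return sum(
        1 for pos in subset if _residues_match(profile.get(pos), reference_profile.get(pos))
    )


def identical_positions(
    profile_a: ResidueProfile,
    profile_b: ResidueProfile,
    positions: Iterable[int],
) -> frozenset[int]:
    """Positions where both profiles carry the same (present) residue."""
    return frozenset(
        pos for pos in positions if _residues_match(profile_a.get(pos), profile_b.get(pos))
    )


def conserved_distinct_positions(
    focal: Sequence[ResidueProfile],
    contrast: Sequence[ResidueProfile],
    positions: Iterable[int],
    rule: str = "strict_all",
) -> frozenset[int]:
    """Positions where all focal profiles agree and that residue is distinct
    from the contrast profiles.

    Under ``strict_all`` the shared focal residue must differ from every
    contrast profile's residue; under ``majority`` from more than half of them.
    """
    if not focal or not contrast:
        raise ValueError("focal and contrast profile sets must be non-empty")
    if rule not in {"strict_all", "majority"}:
        raise ValueError(f"unknown rule {rule!r}")
    out = set()
    for pos in positions:
        focal_residues = {p.get(pos) for p in focal}
        if len(focal_residues) != 1:
            continue
        (shared,) = focal_residues
        if shared is None or shared == "X":
            continue
        different = sum(1 for p in contrast if p.get(pos) != shared)
        if rule == "strict_all" and different == len(contrast):
            out.add(pos)
        elif rule == "majority" and different > len(contrast) / 2:
            out.add(pos)
    return frozenset(out)


def subset_overlap(set_a: Iterable[int], set_b: Iterable[int]) -> int:
    """Size of the intersection of two position sets."""
    return len(frozenset(set_a) & frozenset(set_b))
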