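"""Cysteine-cluster and position-239 motifs, and C-terminal tail features.

Two positional motifs distinguish βIII-like tubulins: the CXXCXC cysteine
cluster anchored at canonical 124–129 (CENCDC in human βIII) and serine rather
than cysteine at position 239, reported here as the 237–240 tetramer (TTSL in
βIII vs TTCL in βI/βII/βIV). Both are read at fixed canonical positions, not
scanned: the biology is positional.

The hypervariable C-terminal tail (canonical ≥425) is summarized by overall
features rather than position-by-position identity: length, terminal residue
and its basicity (K/R only), the count of acidic residues, and the three βIII
landmarks M436, Y437 and the phosphorylatable S444.
"""

from __future__ import annotations

from dataclasses import dataclass

from .numbering import NumberingMap, SequenceRecord, TAIL_START, residue_at
from .signature import ResidueProfile

CLUSTER_POSITIONS: tuple[int, ...] = (124, 125, 126, 127, 128, 129)
#: offsets within the hexamer that must be cysteine (canonical 124, 127, 129)
CLUSTER_CYS_OFFSETS: tuple[int, ...] = (0, 3, 5)
REGION239_POSITIONS: tuple[int, ...] = (237, 238, 239, 240)
BASIC_RESIDUES = frozenset("KR")
ACIDIC_RESIDUES = frozenset("DE")

#: canonical positions of the tail landmarks
M_LANDMARK, Y_LANDMARK, S_LANDMARK = 436, 437, 444


@dataclass(frozen=True)
class ClusterCall:
    present: bool
    hexamer: str  # canonical 124-129, '-' placeholder where absent


@dataclass(frozen=True)
class CTerminalFeatures:
    tail: str
    length: int
    terminal_residue: str | None
    terminal_basic: bool
    acidic_count: int
    has_M436: bool
    has_Y437: bool
    has_S444: bool


def _window(profile: ResidueProfile, positions: tuple[int, ...]) -> str:
    return "".join(profile.get(p) or "-" for p in positions)


def call_cluster(profile: ResidueProfile) -> ClusterCall:
    """Assemble the 124–129 hexamer and test the C-at-124/127/129 rule."""
    hexamer = _window(profile, CLUSTER_POSITIONS)
    present = all(hexamer[off] == "C" for off in CLUSTER_CYS_OFFSETS)
    return ClusterCall(present=present, hexamer=hexamer)


def region239(profile: ResidueProfile) -> str:
    """The canonical 237–240 tetramer ('-' placeholder where absent)."""
    return _window(profile, REGION239_POSITIONS)


def cterminal_features(
    tail: str,
    numbering: NumberingMap | None = None,
    record: SequenceRecord | None = None,
    tail_start: int = TAIL_START,
) -> CTerminalFeatures:
    """Compute tail features; landmark flags use the numbering map when given.

    With a map (and its record), M436/Y437/S444 are read at their canonical
    positions, so indels inside the tail do not break detection. Without a map
    — e.g. for fixture tails stored as bare strings — the tail is assumed to
    start at ``tail_start`` and landmarks are read by offset.
    """
    if numbering is not None and record is not None:
        landmarks = {p: residue_at(record, numbering, p) for p in (M_LANDMARK, Y_LANDMARK, S_LANDMARK)}
    else:
        def by_offset(pos: int) -> str | None:
            off = pos - tail_start
            return tail[off] if 0 <= off < len(tail) else None

        landmarks = {p: by_offset(p) for p in (M_LANDMARK, Y_LANDMARK, S_LANDMARK)}

    terminal = tail[-1] if tail else None
    return CTerminalFeatures(
        tail=tail,
        length=len(tail),
        terminal_residue=terminal,
        terminal_basic=terminal in BASIC_RESIDUES if terminal else False,
        acidic_count=sum(1 for c in tail if c in ACIDIC_RESIDUES),
        has_M436=landmarks[M_LANDMARK] == "M",
        has_Y437=landmarks[Y_LANDMARK] == "Y",
        has_S444=landmarks[S_LANDMARK] == "S",
    )


def load_tail_fixture() -> list[tuple[str, str, str]]:
    """The bundled C-terminal tail table as (group, label, tail) rows."""
    from importlib import resources

    text = resources.files("tubsig.data").joinpath("table4_tails.tsv").read_text()
    lines = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    rows = []
    for ln in lines[1:]:
        group, label, tail = ln.split("\t")
        rows.append((group, label, tail))
    return rows
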