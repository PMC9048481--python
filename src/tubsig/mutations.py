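"""Classification of isotype substitutions as toward-βIII (convergent) or not.

In breast tumors, clones of βI, βIIA, or βIVB frequently carry substitutions
whose observed residue equals the βIII residue at that canonical position —
the convergent class this module identifies. Events are pre-called (sample,
isotype, position, reference residue, observed residue, plus free-text grade
and chemotherapy annotations); no variant calling happens here, and grade and
chemo labels are tallied, not tested, because the source data report the
grade correlation qualitatively.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .numbering import VALID_LETTERS
from .signature import SignatureScheme


class MutationClassification(str, enum.Enum):
    TOWARD_BETAIII = "toward_betaIII"
    OTHER_SUBSTITUTION = "other_substitution"
    NO_CHANGE = "no_change"
    OFF_SIGNATURE = "off_signature"


@dataclass(frozen=True)
class MutationEvent:
    sample_id: str
    isotype_label: str
    canonical_position: int
    reference_residue: str
    observed_residue: str
    grade_label: str = "unknown"
    chemo_label: str = "unknown"

    def __post_init__(self) -> None:
        if self.canonical_position < 1:
            raise ValueError(f"canonical positions are 1-based, got {self.canonical_position}")
        for name in ("reference_residue", "observed_residue"):
            r = getattr(self, name)
            if r not in VALID_LETTERS:
                raise ValueError(f"{name} {r!r} is not a valid amino-acid letter")


@dataclass(frozen=True)
class MutationSummary:
    n_events: int
    classification_counts: Mapping[str, int]
    toward_by_position: Mapping[int, int]
    distinct_toward_positions: frozenset[int]
    overlap_universal8: int
    overlap_betaV12: int
    toward_by_grade: Mapping[str, int]
    toward_by_chemo: Mapping[str, int]


def classify_mutation(event: MutationEvent, scheme: SignatureScheme) -> MutationClassification:
    """Classify one substitution event against the signature scheme.

    ``toward_betaIII`` requires the position to be a signature position, the
    observed residue to equal the βIII reference residue there, and a real
    change (observed ≠ reference). Positions outside the signature — including
    everything past the C-terminal boundary, which the source mutation survey
    excluded — are ``off_signature``.
    """
    if event.isotype_label not in scheme.reference_profiles:
        raise ValueError(
            f"unknown isotype label {event.isotype_label!r}; "
            f"expected one of {sorted(scheme.reference_profiles)}"
        )
    if event.observed_residue == event.reference_residue:
        return MutationClassification.NO_CHANGE
    if event.canonical_position not in scheme.positions:
        return MutationClassification.OFF_SIGNATURE
    expected_ref = scheme.reference_residue(event.isotype_label, event.canonical_position)
    if expected_ref is not None and expected_ref != event.reference_residue:
        raise ValueError(
            f"{event.sample_id}: reference residue {event.reference_residue!r} at position "
            f"{event.canonical_position} does not match the {event.isotype_label} "
            f"scheme residue {expected_ref!r}"
        )
    if event.observed_residue == scheme.reference_residue("betaIII", event.canonical_position):
        return MutationClassification.TOWARD_BETAIII
    return MutationClassification.OTHER_SUBSTITUTION


def summarize_events(
    events: Sequence[MutationEvent], scheme: SignatureScheme
) -> MutationSummary:
    """Tally classifications; pure counts, no statistics."""
    class_counts: Counter[str] = Counter()
    toward_pos: Counter[int] = Counter()
    by_grade: Counter[str] = Counter()
    by_chemo: Counter[str] = Counter()
    for event in events:
        cls = classify_mutation(event, scheme)
        class_counts[cls.value] += 1
        if cls is MutationClassification.TOWARD_BETAIII:
            toward_pos[event.canonical_position] += 1
            by_grade[event.grade_label] += 1
            by_chemo[event.chemo_label] += 1
    distinct = frozenset(toward_pos)
    return MutationSummary(
        n_events=len(events),
        classification_counts=dict(class_counts),
        toward_by_position=dict(toward_pos),
        distinct_toward_positions=distinct,
        overlap_universal8=len(distinct & scheme.subsets["universal8"]),
        overlap_betaV12=len(distinct & scheme.subsets["betaV12"]),
        toward_by_grade=dict(by_grade),
        toward_by_chemo=dict(by_chemo),
    )


def read_events(path: str | Path) -> list[MutationEvent]:
    """Read a tab-separated event file (sample_id, isotype, position, ref, obs, grade, chemo)."""
    lines = Path(path).read_text().splitlines()
    return _parse_events(lines, str(path))


def load_fixture_events() -> list[MutationEvent]:
    """The bundled breast-cancer patient event list."""
    text = resources.files("tubsig.data").joinpath("cancer_mutations.tsv").read_text()
    return _parse_events(text.splitlines(), "cancer_mutations.tsv")


def _parse_events(lines: Sequence[str], source: str) -> list[MutationEvent]:
    lines = [ln for ln in lines if ln and not ln.startswith("#")]
    if not lines:
        return []
    header = lines[0].split("\t")
    expected = ["sample_id", "isotype", "position", "reference", "observed", "grade", "chemo"]
    if header != expected:
        raise ValueError(f"{source}: expected header {expected}, got {header}")
    events = []
    for ln in lines[1:]:
        if not ln.strip():
            continue
        sid, iso, pos, ref, obs, grade, chemo = ln.split("\t")
        events.append(
            MutationEvent(
                sample_id=sid,
                isotype_label=iso,
                canonical_position=int(pos),
                reference_residue=ref,
                observed_residue=obs,
                grade_label=grade,
                chemo_label=chemo,
            )
        )
    return events
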