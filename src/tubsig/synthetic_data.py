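"""Seeded generator of tubulin-like sequences with ground-truth manifests.

Records start from the bundled 450-residue βIII-like reference, impose a
planted residue profile at chosen canonical positions, optionally splice
insertions (emulating the 5–6-residue insect insertions in the 55–60 region),
apply i.i.d. substitution noise, and optionally replace the C-terminal tail.
By default noise never touches signature or motif positions, so the expected
signature extraction, match counts, motif calls and tail features are exact
and are recorded in a manifest computed at generation time — before any
pipeline run — enabling exact parameter-recovery tests with no downloads.

A ``signature_noise_rate`` > 0 additionally flips planted signature positions
(manifest updated accordingly) for robustness testing. Noise is i.i.d. by
design; there is no phylogenetic substitution model here.

One caveat on insertions: the manifest records truth in generation-time
coordinates, but downstream extraction recovers residues by alignment, and
gap placement at an insertion is inherently ambiguous when the residues
flanking the insertion site diverge from the reference (a randomly inserted
residue can mimic the reference where the planted flank does not). Insertions
spliced into conserved stretches — which is where they occur in the insect
sequences this emulates — are always recovered exactly; insertions placed
immediately next to divergent planted signature positions may not be.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import motifs
from .numbering import AMINO_ACIDS, SequenceRecord, TAIL_START, load_reference, write_fasta
from .signature import (
    BETAV12,
    PROFILE_POSITIONS,
    SIGNATURE_POSITIONS,
    UNIVERSAL8,
    ResidueProfile,
    SignatureScheme,
    default_scheme,
    match_count,
)

_ALPHABET = tuple(sorted(AMINO_ACIDS))
#: positions shielded from background substitution noise
_PROTECTED = frozenset(PROFILE_POSITIONS)


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic record."""

    planted_profile: Mapping[int, str] = field(default_factory=dict)
    insertions: tuple[tuple[int, int], ...] = ()  # (after_canonical_position, length)
    substitution_rate: float = 0.0
    signature_noise_rate: float = 0.0
    tail_override: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.substitution_rate <= 1.0:
            raise ValueError(f"substitution_rate must be in [0, 1], got {self.substitution_rate}")
        if not 0.0 <= self.signature_noise_rate <= 1.0:
            raise ValueError(f"signature_noise_rate must be in [0, 1]")
        for pos, res in self.planted_profile.items():
            if res not in _ALPHABET:
                raise ValueError(f"planted residue {res!r} at {pos} is not a valid amino acid")
        for after, length in self.insertions:
            if after < 0 or length < 1:
                raise ValueError(f"bad insertion spec (after={after}, length={length})")


@dataclass(frozen=True)
class ManifestEntry:
    """Generation-time ground truth for one record."""

    record_id: str
    planted: Mapping[int, str]  # residues at the 25 signature positions
    count_all25: int
    count_betaV12: int
    count_universal8: int
    cluster_present: bool
    cluster_hexamer: str
    region239_tetramer: str
    tail: str
    terminal_basic: bool
    acidic_count: int
    has_M436: bool
    has_Y437: bool
    has_S444: bool


def _mutate_away(rng: np.random.Generator, residue: str) -> str:
    choices = [a for a in _ALPHABET if a != residue]
    return choices[rng.integers(0, len(choices))]


def generate_record(
    spec: SyntheticSpec,
    record_id: str = "synth1",
    scheme: SignatureScheme | None = None,
) -> tuple[SequenceRecord, ManifestEntry]:
    """Build one record and its manifest entry (seeded, reproducible)."""
    scheme = scheme or default_scheme()
    rng = np.random.default_rng(spec.seed)
    reference = load_reference().residues
    arr = list(reference)

    for pos, res in spec.planted_profile.items():
        arr[pos - 1] = res

    if spec.tail_override is not None:
        arr = arr[: TAIL_START - 1] + list(spec.tail_override)

    if spec.substitution_rate > 0:
        eligible = [
            p for p in range(1, min(TAIL_START - 1, len(arr)) + 1) if p not in _PROTECTED
        ]
        hits = np.asarray(eligible)[rng.random(len(eligible)) < spec.substitution_rate]
        for pos in hits:
            arr[pos - 1] = _mutate_away(rng, arr[pos - 1])

    if spec.signature_noise_rate > 0:
        for pos in SIGNATURE_POSITIONS:
            if rng.random() < spec.signature_noise_rate:
                arr[pos - 1] = _mutate_away(rng, arr[pos - 1])

    # ground truth from canonical coordinates, before insertions blur them
    profile = ResidueProfile(
        sequence_id=record_id,
        residues={p: arr[p - 1] for p in PROFILE_POSITIONS if p <= len(arr)},
    )
    betaIII = scheme.reference_profiles["betaIII"]
    cluster = motifs.call_cluster(profile)
    tail = "".join(arr[TAIL_START - 1 :])
    feats = motifs.cterminal_features(tail)
    entry = ManifestEntry(
        record_id=record_id,
        planted={p: arr[p - 1] for p in SIGNATURE_POSITIONS},
        count_all25=match_count(profile, betaIII, SIGNATURE_POSITIONS),
        count_betaV12=match_count(profile, betaIII, BETAV12),
        count_universal8=match_count(profile, betaIII, UNIVERSAL8),
        cluster_present=cluster.present,
        cluster_hexamer=cluster.hexamer,
        region239_tetramer=motifs.region239(profile),
        tail=tail,
        terminal_basic=feats.terminal_basic,
        acidic_count=feats.acidic_count,
        has_M436=feats.has_M436,
        has_Y437=feats.has_Y437,
        has_S444=feats.has_S444,
    )

    # splice insertions last, highest site first, so canonical coordinates hold
    for after, length in sorted(spec.insertions, reverse=True):
        inserted = "".join(_ALPHABET[i] for i in rng.integers(0, len(_ALPHABET), length))
        arr[after:after] = list(inserted)

    record = SequenceRecord(
        id=record_id, residues="".join(arr), species="synthetic", isotype_label="synthetic"
    )
    return record, entry


def generate_cohort(
    n: int,
    template: SyntheticSpec | Sequence[SyntheticSpec],
    seed: int,
    fasta_path: str | Path | None = None,
    manifest_path: str | Path | None = None,
    scheme: SignatureScheme | None = None,
) -> tuple[list[SequenceRecord], list[ManifestEntry]]:
    """Generate ``n`` records with per-record seeds derived from one master seed.

    ``template`` is either one spec (replicated) or a sequence of ``n`` specs.
    The same master seed yields byte-identical FASTA and manifest files.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if isinstance(template, SyntheticSpec):
        specs = [template] * n
    else:
        specs = list(template)
        if len(specs) != n:
            raise ValueError(f"expected {n} specs, got {len(specs)}")
    scheme = scheme or default_scheme()
    master = np.random.default_rng(seed)
    child_seeds = master.integers(0, 2**31, size=n)
    records, entries = [], []
    for i, (spec, child) in enumerate(zip(specs, child_seeds), start=1):
        rec, entry = generate_record(
            replace(spec, seed=int(child)), record_id=f"synth{i:04d}", scheme=scheme
        )
        records.append(rec)
        entries.append(entry)
    if fasta_path is not None:
        write_fasta(records, fasta_path)
    if manifest_path is not None:
        manifest_frame(entries).to_csv(manifest_path, sep="\t", index=False)
    return records, entries


def manifest_frame(entries: Sequence[ManifestEntry]) -> pd.DataFrame:
    """Flatten manifest entries to a DataFrame (planted residues as pos_NNN columns)."""
    rows = []
    for e in entries:
        row = {
            "record_id": e.record_id,
            "count_all25": e.count_all25,
            "count_betaV12": e.count_betaV12,
            "count_universal8": e.count_universal8,
            "cluster_present": e.cluster_present,
            "cluster_hexamer": e.cluster_hexamer,
            "region239_tetramer": e.region239_tetramer,
            "tail": e.tail,
            "terminal_basic": e.terminal_basic,
            "acidic_count": e.acidic_count,
            "has_M436": e.has_M436,
            "has_Y437": e.has_Y437,
            "has_S444": e.has_S444,
        }
        row.update({f"pos_{p}": r for p, r in sorted(e.planted.items())})
        rows.append(row)
    return pd.DataFrame(rows)
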