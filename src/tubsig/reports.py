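"""End-to-end pipeline orchestration: comparison, C-termini and mutation reports.

Each ``run_*`` function takes a :class:`RunConfig`, resolves its single input
source (a FASTA file or a bundled fixture table), runs the library and returns
a DataFrame whose rows follow input order. ``write_table`` writes atomically
(temp file + rename) so a failed run never leaves a partial output behind.

``run_compare`` mirrors the five columns of the published comparison summary:
match counts over all 25 signature positions, over the βIII∩βV set, and over
the universal set, plus the cysteine-cluster call and the 237–240 tetramer.
"""

from __future__ import annotations

import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import motifs, mutations, signature
from .numbering import build_numbering_map, load_reference, read_fasta, split_tail

logger = logging.getLogger("tubsig")

_FIXTURE_TABLES = {"table1", "table2", "table3", "table4"}


@dataclass(frozen=True)
class RunConfig:
    """One run's input source and knobs; exactly one of input/fixture is set."""

    input: str | None = None  # FASTA (compare/ctermini) or event TSV (mutations)
    fixture: str | None = None  # table1 | table2 | table3 | table4
    reference: str = "table"  # 'table' = the fixture's own βIII column
    rule: str = "strict_all"
    tail_start: int = 425
    out: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.input is None) == (self.fixture is None):
            raise ValueError("exactly one input source (input or fixture) per run")
        if self.fixture is not None and self.fixture not in _FIXTURE_TABLES:
            raise ValueError(f"unknown fixture {self.fixture!r}")
        if self.tail_start < 1:
            raise ValueError("tail_start must be >= 1")


def config_from_file(path: str | Path, **overrides) -> RunConfig:
    """Build a RunConfig from a YAML key-value file; keyword overrides win."""
    loaded = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(loaded, dict):
        raise ValueError(f"{path}: config file must be a key-value mapping")
    merged = {**loaded, **{k: v for k, v in overrides.items() if v is not None}}
    return RunConfig(**merged)


def _profiles_from_config(
    config: RunConfig, scheme: signature.SignatureScheme
) -> tuple[dict[str, signature.ResidueProfile], signature.ResidueProfile]:
    """Resolve (profiles in input order, reference profile to compare against)."""
    if config.fixture is not None:
        if config.fixture == "table4":
            raise ValueError("table4 holds C-terminal tails; use run_ctermini")
        profiles = signature.load_fixture_matrix(config.fixture)
        if config.reference == "table":
            ref = signature.table_reference_profile(config.fixture)
        else:
            ref = scheme.reference_profiles[config.reference]
        return profiles, ref

    reference_seq = load_reference()
    profiles = {}
    for record in read_fasta(config.input):
        numbering = build_numbering_map(record.residues, reference_seq.residues)
        profiles[record.id] = signature.extract_profile(record, numbering, scheme)
    ref_name = "betaIII" if config.reference == "table" else config.reference
    return profiles, scheme.reference_profiles[ref_name]


def build_match_report(
    profile: signature.ResidueProfile,
    reference_profile: signature.ResidueProfile,
    scheme: signature.SignatureScheme,
) -> signature.MatchReport:
    """Assemble the machine twin of one comparison-table row."""
    flags = {
        pos: signature.match_count(profile, reference_profile, (pos,)) == 1
        for pos in scheme.positions
    }
    cluster = motifs.call_cluster(profile)
    return signature.MatchReport(
        sequence_id=profile.sequence_id,
        match_flags=flags,
        count_all=sum(flags.values()),
        count_betaV12=sum(flags[p] for p in scheme.subsets["betaV12"]),
        count_universal8=sum(flags[p] for p in scheme.subsets["universal8"]),
        cluster_present=cluster.present,
        cluster_hexamer=cluster.hexamer,
        region239_tetramer=motifs.region239(profile),
    )


def run_compare(config: RunConfig, scheme: signature.SignatureScheme | None = None) -> pd.DataFrame:
    """One row per input sequence: three match counts plus motif columns."""
    scheme = scheme or signature.default_scheme()
    profiles, ref = _profiles_from_config(config, scheme)
    logger.info("compare: %d sequences against %s", len(profiles), ref.sequence_id)
    rows = []
    for label, profile in profiles.items():
        report = build_match_report(profile, ref, scheme)
        rows.append(
            {
                "sequence_id": label,
                "matches_all25": report.count_all,
                "matches_betaIII_and_betaV": report.count_betaV12,
                "matches_vert_betaIII": report.count_universal8,
                "cluster": "Yes" if report.cluster_present else "No",
                "cluster_hexamer": report.cluster_hexamer,
                "region_239": report.region239_tetramer,
            }
        )
    columns = [
        "sequence_id", "matches_all25", "matches_betaIII_and_betaV",
        "matches_vert_betaIII", "cluster", "cluster_hexamer", "region_239",
    ]
    return pd.DataFrame(rows, columns=columns)


def run_ctermini(config: RunConfig, scheme: signature.SignatureScheme | None = None) -> pd.DataFrame:
    """C-terminal tail features, from the tail fixture or from aligned FASTA input."""
    scheme = scheme or signature.default_scheme()
    rows = []
    if config.fixture is not None:
        if config.fixture != "table4":
            raise ValueError("C-terminal fixture analysis expects table4")
        for group, label, tail in motifs.load_tail_fixture():
            feats = motifs.cterminal_features(tail, tail_start=config.tail_start)
            rows.append((group, label, feats))
    else:
        reference_seq = load_reference()
        for record in read_fasta(config.input):
            numbering = build_numbering_map(record.residues, reference_seq.residues)
            _, tail = split_tail(record, numbering, tail_start=config.tail_start)
            feats = motifs.cterminal_features(tail, numbering, record, tail_start=config.tail_start)
            rows.append(("input", record.id, feats))
    frame_rows = [
        {
            "group": group,
            "label": label,
            "tail": f.tail,
            "length": f.length,
            "terminal_residue": f.terminal_residue or "-",
            "terminal_basic": f.terminal_basic,
            "acidic_count": f.acidic_count,
            "has_M436": f.has_M436,
            "has_Y437": f.has_Y437,
            "has_S444": f.has_S444,
        }
        for group, label, f in rows
    ]
    columns = ["group", "label", "tail", "length", "terminal_residue", "terminal_basic",
               "acidic_count", "has_M436", "has_Y437", "has_S444"]
    return pd.DataFrame(frame_rows, columns=columns)


def run_mutations(config: RunConfig, scheme: signature.SignatureScheme | None = None) -> pd.DataFrame:
    """Summarize a mutation-event table as long-format (field, value) rows."""
    scheme = scheme or signature.default_scheme()
    if config.fixture is not None:
        raise ValueError("mutation summaries take an event file via input=, not a fixture table")
    events = mutations.read_events(config.input)
    summary = mutations.summarize_events(events, scheme)
    return summary_frame(summary)


def summary_frame(summary: mutations.MutationSummary) -> pd.DataFrame:
    """Flatten a MutationSummary into deterministic (field, value) rows."""
    rows: list[tuple[str, object]] = [("n_events", summary.n_events)]
    for cls in mutations.MutationClassification:
        rows.append((cls.value, summary.classification_counts.get(cls.value, 0)))
    rows.append(("distinct_toward_positions", len(summary.distinct_toward_positions)))
    rows.append(
        ("toward_positions", ",".join(str(p) for p in sorted(summary.distinct_toward_positions)))
    )
    rows.append(("overlap_universal8", summary.overlap_universal8))
    rows.append(("overlap_betaV12", summary.overlap_betaV12))
    for pos in sorted(summary.toward_by_position):
        rows.append((f"toward_at_{pos}", summary.toward_by_position[pos]))
    for grade in sorted(summary.toward_by_grade):
        rows.append((f"toward_grade_{grade}", summary.toward_by_grade[grade]))
    for chemo in sorted(summary.toward_by_chemo):
        rows.append((f"toward_chemo_{chemo}", summary.toward_by_chemo[chemo]))
    return pd.DataFrame(rows, columns=["field", "value"])


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a TSV atomically: temp file in the target directory, then rename."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent or Path("."), suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            frame.to_csv(fh, sep="\t", index=False)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
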