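"""Differential conservation analysis of adenylation-domain specificity codes.

An NRPS adenylation (A) domain selects its amino-acid substrate through eight
binding-pocket residues — the Stachelhaus specificity code.  To find residues
that make a domain threonine-specific, aligned A-domain sequences labeled
T (threonine-specific) or NT (non-threonine) are first filtered on the
invariant catalytic aspartate anchor (the Asp190-equivalent column: any
sequence without Asp there is dropped for homogeneity), then per-code-position
residue frequencies are tabulated in each category, and a residue is called a
*key residue* when it is conserved in more than 90% of T domains while
appearing in fewer than 5% of NT domains (strict inequalities).

The upstream multiple alignment is consumed, never computed.  Gaps count in
the denominator: a gapped column dilutes conservation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "AMINO_ACIDS",
    "GAP",
    "LabeledSequenceSet",
    "CodePositionSet",
    "ConservationProfile",
    "KeyResidueCall",
    "load_labeled_alignment",
    "anchor_filter",
    "frequency_profile",
    "call_key_residues",
    "profile_report",
]

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")
GAP = "-"
CATEGORIES = ("T", "NT")


@dataclass(frozen=True)
class LabeledSequenceSet:
    """Equal-length aligned sequences, each labeled T or NT."""

    records: tuple[tuple[str, str, str], ...]  # (id, aligned sequence, category)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("sequence set is empty")
        length = len(self.records[0][1])
        seen: set[str] = set()
        for rec_id, seq, category in self.records:
            if rec_id in seen:
                raise ValueError(f"duplicate sequence id {rec_id!r}")
            seen.add(rec_id)
            if len(seq) != length:
                raise ValueError(
                    f"record {rec_id!r} has length {len(seq)}, expected {length}"
                )
            if category not in CATEGORIES:
                raise ValueError(
                    f"record {rec_id!r} has unknown category {category!r}"
                )

    @property
    def alignment_length(self) -> int:
        return len(self.records[0][1])

    def category_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CATEGORIES}
        for _, _, category in self.records:
            counts[category] += 1
        return counts

    def subset(self, categories: Iterable[str]) -> list[tuple[str, str, str]]:
        wanted = set(categories)
        return [r for r in self.records if r[2] in wanted]


@dataclass(frozen=True)
class CodePositionSet:
    """Alignment columns (1-based) of the 8 code positions and the Asp anchor."""

    code_columns: tuple[int, int, int, int, int, int, int, int]
    anchor_column: int

    def __post_init__(self) -> None:
        columns = (*self.code_columns, self.anchor_column)
        if len(set(columns)) != 9:
            raise ValueError("the 8 code columns and the anchor must be distinct")
        if any(c < 1 for c in columns):
            raise ValueError("columns are 1-based and must be >= 1")

    def validate_length(self, alignment_length: int) -> None:
        out = [c for c in (*self.code_columns, self.anchor_column) if c > alignment_length]
        if out:
            raise ValueError(
                f"columns {out} exceed the alignment length {alignment_length}"
            )


@dataclass(frozen=True)
class ConservationProfile:
    """Per-code-position residue frequencies in the T and NT categories.

    ``frequencies[category][i]`` maps residue symbol → frequency for code
    position i (1..8); frequencies at each position sum to 1 over the symbols
    observed (20 amino acids plus gap).
    """

    frequencies: Mapping[str, tuple[Mapping[str, float], ...]]
    category_counts: Mapping[str, int]
    code: CodePositionSet

    def frequency(self, category: str, position: int, residue: str) -> float:
        return self.frequencies[category][position - 1].get(residue, 0.0)


def load_labeled_alignment(
    fasta, labels: "Mapping[str, str] | str"
) -> LabeledSequenceSet:
    """Read an aligned FASTA plus an id→category label map.

    ``fasta`` is a path or handle; ``labels`` a mapping or a path to a
    two-column TSV (id, category).  Every record must be labeled and all
    sequences must have equal length; violations are rejected naming the
    offending record.
    """
    from Bio import SeqIO  # deferred: keeps import cost off the hot path

    if isinstance(labels, str):
        from .io import read_labels_tsv

        labels = read_labels_tsv(labels)
    records = []
    for record in SeqIO.parse(fasta, "fasta"):
        if record.id not in labels:
            raise ValueError(f"sequence {record.id!r} has no category label")
        records.append((record.id, str(record.seq).upper(), labels[record.id]))
    if not records:
        raise ValueError("no sequences found in the alignment")
    return LabeledSequenceSet(tuple(records))


def anchor_filter(
    sequences: LabeledSequenceSet,
    code: CodePositionSet,
    anchor_residue: str = "D",
) -> LabeledSequenceSet:
    """Drop sequences lacking the anchor residue (Asp) at the anchor column."""
    code.validate_length(sequences.alignment_length)
    col = code.anchor_column - 1
    kept = tuple(r for r in sequences.records if r[1][col] == anchor_residue)
    if not kept:
        raise ValueError("anchor filter removed every sequence")
    kept_set = LabeledSequenceSet(kept)
    for category, count in kept_set.category_counts().items():
        if count == 0:
            warnings.warn(
                f"anchor filter removed all {category} sequences", stacklevel=2
            )
    return kept_set


def frequency_profile(
    sequences: LabeledSequenceSet, code: CodePositionSet
) -> ConservationProfile:
    """Per-position residue frequencies at the 8 code columns, per category.

    Frequency = count / category size; gaps are a symbol of their own and
    stay in the denominator.
    """
    code.validate_length(sequences.alignment_length)
    counts = sequences.category_counts()
    for category in CATEGORIES:
        if counts[category] == 0:
            raise ValueError(f"category {category} is empty — cannot profile")
    freqs: dict[str, tuple[dict[str, float], ...]] = {}
    for category in CATEGORIES:
        seqs = [seq for _, seq, cat in sequences.records if cat == category]
        per_position = []
        for col in code.code_columns:
            tally: dict[str, int] = {}
            for seq in seqs:
                symbol = seq[col - 1]
                tally[symbol] = tally.get(symbol, 0) + 1
            per_position.append(
                {symbol: count / len(seqs) for symbol, count in tally.items()}
            )
        freqs[category] = tuple(per_position)
    return ConservationProfile(freqs, counts, code)


@dataclass(frozen=True)
class KeyResidueCall:
    """A thresholded key-residue verdict at one code position."""

    position: int  # 1..8 along the code
    residue: str
    f_t: float
    f_nt: float
    is_key: bool


def call_key_residues(
    profile: ConservationProfile,
    t_min: float = 0.90,
    nt_max: float = 0.05,
) -> list[KeyResidueCall]:
    """Key residues: conserved at > t_min in T and present at < nt_max in NT.

    Both inequalities are strict.  With t_min ≥ 0.5 each position can yield
    at most one key residue.
    """
    if not (0.0 < t_min <= 1.0):
        raise ValueError("t_min must be in (0, 1]")
    if not (0.0 <= nt_max < 1.0):
        raise ValueError("nt_max must be in [0, 1)")
    calls: list[KeyResidueCall] = []
    for position in range(1, 9):
        t_freqs = profile.frequencies["T"][position - 1]
        for residue, f_t in sorted(t_freqs.items()):
            if residue == GAP:
                continue
            f_nt = profile.frequency("NT", position, residue)
            if f_t > t_min and f_nt < nt_max:
                calls.append(KeyResidueCall(position, residue, f_t, f_nt, True))
    return calls


def profile_report(
    profile: ConservationProfile, calls: Sequence[KeyResidueCall] = ()
) -> pd.DataFrame:
    """Tabulate the profile: per position and residue, percent in T and NT.

    Frequencies are reported in percent to one decimal; key residues are
    flagged.  Only residues observed in at least one category appear.
    """
    key_cells = {(c.position, c.residue) for c in calls if c.is_key}
    rows = []
    for position in range(1, 9):
        symbols = sorted(
            set(profile.frequencies["T"][position - 1])
            | set(profile.frequencies["NT"][position - 1])
        )
        for residue in symbols:
            rows.append(
                {
                    "code_position": position,
                    "residue": residue,
                    "pct_T": round(100 * profile.frequency("T", position, residue), 1),
                    "pct_NT": round(100 * profile.frequency("NT", position, residue), 1),
                    "is_key": (position, residue) in key_cells,
                }
            )
    return pd.DataFrame(rows, columns=["code_position", "residue", "pct_T", "pct_NT", "is_key"])
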