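"""Peak matching, mass-shift substitution inference and MS/MS localization.

This module implements the variant-identification logic for PVD spectra: a
deterministic greedy matcher assigning observed peaks to theoretical ions, the
inference of an amino-acid substitution from an observed precursor mass shift
(reported both as an exact monoisotopic difference and as the nominal integer,
e.g. "-14 amu" for Ser-for-Thr), and the localization of the substitution
from which fragment ions shift and which do not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

from .fragmentation import FragmentIon
from .mass_core import (
    DEFAULT_CONSTANTS,
    PROTEINOGENIC_IDS,
    MassConstants,
    MassGroup,
    PrecursorIon,
    Registry,
    Scaffold,
    VariantPeptide,
    default_registry,
    enumerate_variants,
    ion_mz,
    mass_groups,
    neutral_mass,
    rda_companion,
)

__all__ = [
    "Peak",
    "PeakList",
    "DEFAULT_TOLERANCE",
    "Assignment",
    "MatchResult",
    "match_peaks",
    "SubstitutionCall",
    "infer_substitution",
    "localize_from_msms",
    "VariantReport",
    "annotate_spectrum",
]

#: Default matching tolerances (Da) per instrument mode: MALDI reflectron
#: spectra show cross-spectrum calibration offsets up to ~0.3 Da, ESI values
#: agree to a few mDa.
DEFAULT_TOLERANCE: Mapping[str, float] = {"MALDI": 0.3, "ESI": 0.02}

#: Tolerance for comparing peaks drawn from *different* MALDI spectra, whose
#: calibration offsets compound.
CROSS_SPECTRUM_TOLERANCE = 0.5


def cross_spectrum_shift(mz_a: float, mz_b: float) -> float:
    """Observed mass shift between peaks from two different spectra.

    Each MALDI spectrum carries its own calibration offset, so a shift taken
    across spectra is less trustworthy than one within a spectrum; pair the
    returned value with :data:`CROSS_SPECTRUM_TOLERANCE`.  A warning marks
    the comparison.
    """
    warnings.warn(
        "comparing peaks across spectra: calibration offsets compound, "
        f"use the widened tolerance of {CROSS_SPECTRUM_TOLERANCE} Da",
        stacklevel=2,
    )
    return mz_a - mz_b

_TIE_EPSILON = 1e-6  # Da; |error| ties below this are flagged ambiguous


class Peak(NamedTuple):
    mz: float
    intensity: float


@dataclass(frozen=True)
class PeakList:
    """Observed (m/z, intensity) pairs with instrument metadata.

    Peaks are stored sorted by m/z; ``mode`` ("MALDI" or "ESI") determines the
    default matching tolerance.
    """

    peaks: tuple[Peak, ...]
    mode: str = "MALDI"
    label: str = ""
    meta: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.mode not in DEFAULT_TOLERANCE:
            raise ValueError(f"unknown instrument mode {self.mode!r}")
        peaks = tuple(Peak(float(p[0]), float(p[1])) for p in self.peaks)
        for peak in peaks:
            if peak.mz <= 0:
                raise ValueError(f"non-positive m/z {peak.mz}")
            if peak.intensity < 0:
                raise ValueError(f"negative intensity {peak.intensity}")
        object.__setattr__(self, "peaks", tuple(sorted(peaks)))

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    @property
    def default_tolerance(self) -> float:
        return DEFAULT_TOLERANCE[self.mode]

    def nearest(self, mz: float) -> Peak | None:
        """The peak nearest to ``mz``, or None for an empty list."""
        if not self.peaks:
            return None
        return min(self.peaks, key=lambda p: abs(p.mz - mz))


def _candidate_mz(candidate) -> float:
    if hasattr(candidate, "mz"):
        return candidate.mz
    return float(candidate)


@dataclass(frozen=True)
class Assignment:
    peak: Peak
    candidate: object
    error: float  # observed - theoretical, Da
    ambiguous: bool = False


@dataclass(frozen=True)
class MatchResult:
    assignments: tuple[Assignment, ...]
    unmatched_peaks: tuple[Peak, ...]
    unmatched_candidates: tuple[object, ...]

    def candidate_for(self, peak: Peak):
        for a in self.assignments:
            if a.peak == peak:
                return a.candidate
        return None

    def assignment_for_candidate(self, candidate) -> Assignment | None:
        for a in self.assignments:
            if a.candidate is candidate:
                return a
        return None


def match_peaks(obs: PeakList, candidates: Sequence, tol: float) -> MatchResult:
    """Greedy one-to-one nearest-mass assignment of peaks to candidate ions.

    Pairs within ``tol`` are assigned in order of increasing |error|, with
    ties broken by lower candidate m/z, then lower peak m/z — fully
    deterministic.  A peak whose best |error| is attained by more than one
    candidate (within 1e-6 Da) keeps its assignment but is flagged ambiguous.
    Candidates may be any objects with an ``mz`` attribute, or bare numbers.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    pairs = []
    for pi, peak in enumerate(obs.peaks):
        for ci, cand in enumerate(candidates):
            err = peak.mz - _candidate_mz(cand)
            if abs(err) <= tol:
                pairs.append((abs(err), _candidate_mz(cand), peak.mz, pi, ci, err))
    pairs.sort(key=lambda t: (t[0], t[1], t[2]))

    # best |error| per peak over all in-tolerance candidates, for tie flags
    best: dict[int, list[float]] = {}
    for abs_err, _, _, pi, _, _ in pairs:
        best.setdefault(pi, []).append(abs_err)

    used_peaks: set[int] = set()
    used_cands: set[int] = set()
    assignments: list[Assignment] = []
    for abs_err, _, _, pi, ci, err in pairs:
        if pi in used_peaks or ci in used_cands:
            continue
        used_peaks.add(pi)
        used_cands.add(ci)
        ties = [e for e in best[pi] if abs(e - abs_err) < _TIE_EPSILON]
        assignments.append(
            Assignment(obs.peaks[pi], candidates[ci], err, ambiguous=len(ties) > 1)
        )
    unmatched_peaks = tuple(p for i, p in enumerate(obs.peaks) if i not in used_peaks)
    unmatched_cands = tuple(c for i, c in enumerate(candidates) if i not in used_cands)
    return MatchResult(tuple(assignments), unmatched_peaks, unmatched_cands)


@dataclass(frozen=True)
class SubstitutionCall:
    """An inferred substitution: candidate blocks, shifts and position window.

    ``window`` is the tuple of candidate 1-based positions (None when the
    inference is position-agnostic or the fragment evidence is inconsistent).
    ``candidates`` may hold several ids when they are isobaric.  ``nominal_shift``
    is the theoretical shift rounded to the nearest integer, mirroring the
    "-14 amu" style of reporting.
    """

    reference: str
    candidates: tuple[str, ...]
    observed_shift: float
    theoretical_shift: float
    nominal_shift: int
    window: tuple[int, ...] | None = None
    ambiguous: bool = False
    alternatives: tuple[tuple[int, ...], ...] = ()
    nearest_misses: tuple[tuple[str, float], ...] = ()

    @property
    def is_identity(self) -> bool:
        return bool(self.candidates) and self.nominal_shift == 0 and all(
            c == self.reference for c in self.candidates
        )

    @property
    def is_empty(self) -> bool:
        return not self.candidates


def infer_substitution(
    observed_shift: float,
    reference: str,
    alphabet: Iterable[str] = PROTEINOGENIC_IDS,
    tol: float = 0.15,
    registry: Registry | None = None,
) -> SubstitutionCall:
    """Which building blocks explain an observed precursor mass shift.

    Returns every alphabet block whose residue-mass difference to the
    reference block lies within ``tol`` of ``observed_shift``; isobaric blocks
    are returned together.  With no candidate in tolerance the call is empty
    and carries the three nearest misses as a diagnostic.  Candidates are
    ordered by closeness, never by biological plausibility.
    """
    registry = registry or default_registry()
    ref_mass = registry[reference].mono_mass
    deltas = sorted(
        ((registry[b].mono_mass - ref_mass, b) for b in alphabet),
        key=lambda db: (abs(db[0] - observed_shift), db[1]),
    )
    hits = [(d, b) for d, b in deltas if abs(d - observed_shift) <= tol]
    if not hits:
        misses = tuple((b, round(d, 5)) for d, b in deltas[:3])
        return SubstitutionCall(
            reference=reference,
            candidates=(),
            observed_shift=observed_shift,
            theoretical_shift=float("nan"),
            nominal_shift=round(observed_shift),
            nearest_misses=misses,
        )
    theoretical = hits[0][0]
    return SubstitutionCall(
        reference=reference,
        candidates=tuple(b for _, b in hits),
        observed_shift=observed_shift,
        theoretical_shift=theoretical,
        nominal_shift=round(theoretical),
    )


def _span_positions(span: tuple[int, int]) -> set[int]:
    return set(range(span[0], span[1] + 1))


def localize_from_msms(
    variant: VariantPeptide,
    ref_table: Sequence[FragmentIon],
    obs_shifts: Mapping[tuple[str, int], float],
    tol: float = 0.02,
    alphabet: Iterable[str] = PROTEINOGENIC_IDS,
    registry: Registry | None = None,
) -> SubstitutionCall:
    """Localize a substitution from per-fragment observed mass shifts.

    ``obs_shifts`` maps (series, n) of fragments in ``ref_table`` to observed
    shifts (Da) relative to the reference peptide.  A fragment is *shifted*
    when |shift| > tol.  The position window is the intersection of the spans
    of all shifted fragments minus the union of the spans of unshifted ones,
    then restricted to positions whose reference residue can yield the shift
    from the alphabet.  Inconsistent evidence (a shifted fragment nested
    inside an unshifted one empties the window) raises no error: the call is
    flagged ambiguous and carries both candidate windows.
    """
    registry = registry or default_registry()
    by_key = {(f.series, f.index): f for f in ref_table}
    shifted: list[tuple[FragmentIon, float]] = []
    unshifted: list[FragmentIon] = []
    for key, shift in obs_shifts.items():
        if key not in by_key:
            raise KeyError(f"fragment {key} not present in the reference table")
        if abs(shift) > tol:
            shifted.append((by_key[key], shift))
        else:
            unshifted.append(by_key[key])

    n_res = variant.scaffold.n_residues
    if not shifted:
        return SubstitutionCall(
            reference=".",
            candidates=(".",),
            observed_shift=0.0,
            theoretical_shift=0.0,
            nominal_shift=0,
            window=tuple(range(1, n_res + 1)),
        )

    observed = sum(s for _, s in shifted) / len(shifted)
    core = set.intersection(*[_span_positions(f.span) for f, _ in shifted])
    excluded = set().union(*[_span_positions(f.span) for f in unshifted]) if unshifted else set()
    window = core - excluded
    if not window:
        return SubstitutionCall(
            reference=".",
            candidates=(),
            observed_shift=observed,
            theoretical_shift=float("nan"),
            nominal_shift=round(observed),
            window=None,
            ambiguous=True,
            alternatives=(tuple(sorted(core)), tuple(sorted(core & excluded))),
        )

    residues = variant.residue_ids
    final_positions: list[int] = []
    candidate_blocks: list[str] = []
    theoretical = None
    for pos in sorted(window):
        call = infer_substitution(observed, residues[pos - 1], alphabet, tol=tol, registry=registry)
        if not call.is_empty:
            final_positions.append(pos)
            for c in call.candidates:
                if c not in candidate_blocks:
                    candidate_blocks.append(c)
            if theoretical is None:
                theoretical = call.theoretical_shift
    if not final_positions:
        return SubstitutionCall(
            reference=";".join(sorted({residues[p - 1] for p in sorted(window)})),
            candidates=(),
            observed_shift=observed,
            theoretical_shift=float("nan"),
            nominal_shift=round(observed),
            window=tuple(sorted(window)),
        )
    refs = sorted({residues[p - 1] for p in final_positions})
    return SubstitutionCall(
        reference=";".join(refs),
        candidates=tuple(candidate_blocks),
        observed_shift=observed,
        theoretical_shift=theoretical,
        nominal_shift=round(theoretical),
        window=tuple(final_positions),
    )


@dataclass(frozen=True)
class VariantReport:
    """Per-mass-group annotation outcome for one spectrum."""

    group: MassGroup
    status: str  # "confirmed" | "companion_only"
    assignments: tuple[Assignment, ...]

    @property
    def label(self) -> str:
        return self.group.label


def annotate_spectrum(
    obs: PeakList,
    scaffold: Scaffold,
    positions: Iterable[int],
    alphabet: Iterable[str],
    tol: float | None = None,
    registry: Registry | None = None,
    constants: MassConstants = DEFAULT_CONSTANTS,
    charges: Sequence[int] | None = None,
) -> list[VariantReport]:
    """End-to-end spectrum annotation against an enumerated variant space.

    Enumerates variants over ``positions`` × ``alphabet``, collapses isobaric
    variants into mass groups, predicts protonated precursors (and z=1 RDA
    companions) and matches them against the peak list.  A group is
    *confirmed* only when a main (non-RDA) precursor peak matches; a group
    supported solely by its RDA companion is reported as ``companion_only``,
    never as an identification.  Charges default to (1,) for MALDI and (1, 2)
    for ESI.
    """
    registry = registry or default_registry()
    if tol is None:
        tol = obs.default_tolerance
    if charges is None:
        charges = (1,) if obs.mode == "MALDI" else (1, 2)

    variants = enumerate_variants(scaffold, positions, alphabet, registry)
    groups = mass_groups(variants, registry)
    candidates: list[PrecursorIon] = []
    owner: dict[int, MassGroup] = {}
    for group in groups:
        rep = group.members[0]
        for z in charges:
            ion = PrecursorIon(rep, z, ion_mz(group.mass, z, constants))
            owner[len(candidates)] = group
            candidates.append(ion)
        if 1 in charges:
            ion = PrecursorIon(
                rep, 1, rda_companion(ion_mz(group.mass, 1, constants), 1, constants),
                is_rda_companion=True,
            )
            owner[len(candidates)] = group
            candidates.append(ion)

    result = match_peaks(obs, candidates, tol)
    by_group: dict[int, list[Assignment]] = {}
    for assignment in result.assignments:
        idx = candidates.index(assignment.candidate)
        gid = id(owner[idx])
        by_group.setdefault(gid, []).append(assignment)

    reports: list[VariantReport] = []
    for group in groups:
        assigned = by_group.get(id(group), [])
        if not assigned:
            continue
        main = [a for a in assigned if not a.candidate.is_rda_companion]
        status = "confirmed" if main else "companion_only"
        reports.append(VariantReport(group, status, tuple(assigned)))
    return reports
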