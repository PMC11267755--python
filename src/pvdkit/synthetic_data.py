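"""Seeded generators for every input the pipeline consumes.

Two families of synthetic data, shaped like the study's real inputs:

* labeled, aligned A-domain code-position sequence sets with planted
  per-category conservation frequencies and an Asp anchor column, and
* centroided MALDI/ESI peak lists with Poisson-shaped isotope envelopes,
  retro-Diels-Alder companion envelopes, species abundances, and m/z and
  intensity noise — plus titration series of such peak lists.

All randomness flows from one explicit integer seed through
``numpy.random.default_rng``; identical spec + seed gives bit-identical
output.  These generators are first-class, tested code: they define the
conditions under which the pipeline's statistical behaviour is asserted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .annotation import Peak, PeakList
from .mass_core import (
    DEFAULT_CONSTANTS,
    MassConstants,
    Registry,
    VariantPeptide,
    default_registry,
    neutral_mass,
)
from .specificity_code import (
    AMINO_ACIDS,
    CodePositionSet,
    LabeledSequenceSet,
)

__all__ = [
    "PlantedKey",
    "SequenceSimSpec",
    "gen_sequence_set",
    "SpectrumSimSpec",
    "gen_peaklist",
    "gen_titration",
]


@dataclass(frozen=True)
class PlantedKey:
    """A residue planted at a code position with set per-category frequencies."""

    position: int  # 1..8 along the code
    residue: str
    f_t: float
    f_nt: float

    def __post_init__(self) -> None:
        if not (1 <= self.position <= 8):
            raise ValueError("code position must be in 1..8")
        if self.residue not in AMINO_ACIDS:
            raise ValueError(f"unknown residue {self.residue!r}")
        for name in ("f_t", "f_nt"):
            f = getattr(self, name)
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {f}")


@dataclass(frozen=True)
class SequenceSimSpec:
    """Recipe for a labeled code-position sequence set.

    The default sizes mirror the scale of a curated A-domain collection split
    into a small substrate-specific category and a large background (tens of
    T vs ~1500 NT sequences).  ``anchor_asp_fraction`` sets, per category,
    the fraction of sequences carrying Asp at the anchor column; the rest get
    a random non-Asp residue.  Background cells draw uniformly from the 20
    amino acids (renormalized to exclude a planted residue at planted cells,
    so planted frequencies are exact Bernoulli rates).
    """

    n_t: int = 39
    n_nt: int = 1507
    planted: tuple[PlantedKey, ...] = ()
    anchor_asp_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"T": 0.97, "NT": 0.79}
    )
    background: Mapping[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_t < 1 or self.n_nt < 1:
            raise ValueError("category counts must be >= 1")
        for cat, f in self.anchor_asp_fraction.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"anchor fraction for {cat} must be in [0, 1]")
        positions = [p.position for p in self.planted]
        if len(positions) != len(set(positions)):
            raise ValueError("at most one planted key per code position")


# Generated alignment layout: column 1 = Asp anchor, columns 2..9 = the eight
# code positions, column 10 = unconstrained filler.
_GENERATED_CODE = CodePositionSet(code_columns=(2, 3, 4, 5, 6, 7, 8, 9), anchor_column=1)
_ALIGNMENT_LENGTH = 10


def generated_code_positions() -> CodePositionSet:
    """The column map every generated sequence set uses."""
    return _GENERATED_CODE


def _background_draw(rng, background: Mapping[str, float] | None, exclude: str | None, size: int):
    symbols = list(background) if background else list(AMINO_ACIDS)
    probs = np.array(
        [background[s] for s in symbols] if background else [1.0] * len(symbols),
        dtype=float,
    )
    if exclude is not None and exclude in symbols:
        probs[symbols.index(exclude)] = 0.0
    total = probs.sum()
    if total <= 0:
        raise ValueError("background distribution has no mass after exclusion")
    return rng.choice(symbols, size=size, p=probs / total)


def gen_sequence_set(spec: SequenceSimSpec) -> LabeledSequenceSet:
    """Draw a labeled sequence set; planted cells are per-category Bernoulli."""
    rng = np.random.default_rng(spec.seed)
    planted_by_pos = {p.position: p for p in spec.planted}
    records: list[tuple[str, str, str]] = []
    for category, count in (("T", spec.n_t), ("NT", spec.n_nt)):
        asp_fraction = spec.anchor_asp_fraction.get(category, 1.0)
        anchor_is_asp = rng.random(count) < asp_fraction
        non_asp = [a for a in AMINO_ACIDS if a != "D"]
        columns = np.empty((count, _ALIGNMENT_LENGTH), dtype="<U1")
        columns[:, 0] = np.where(
            anchor_is_asp, "D", rng.choice(non_asp, size=count)
        )
        for code_pos in range(1, 9):
            col = _GENERATED_CODE.code_columns[code_pos - 1] - 1
            planted = planted_by_pos.get(code_pos)
            if planted is None:
                columns[:, col] = _background_draw(rng, spec.background, None, count)
            else:
                f = planted.f_t if category == "T" else planted.f_nt
                hit = rng.random(count) < f
                fill = _background_draw(rng, spec.background, planted.residue, count)
                columns[:, col] = np.where(hit, planted.residue, fill)
        columns[:, 9] = _background_draw(rng, spec.background, None, count)
        for i in range(count):
            records.append((f"{category}_{i:04d}", "".join(columns[i]), category))
    return LabeledSequenceSet(tuple(records))


@dataclass(frozen=True)
class SpectrumSimSpec:
    """Recipe for a centroided peak list.

    ``species`` pairs each variant with a relative abundance (the total
    intensity of its main envelope).  Isotopologue weights follow a Poisson
    distribution with mean ``lam_per_kda × M/1000`` — a one-parameter
    carbon-count proxy adequate for a pipeline that sums envelopes and never
    fits their shape.  ``rda_fraction`` scales a companion envelope at the
    chromophore's retro-Diels-Alder offset below each z=1 precursor.  m/z
    values are jittered with Gaussian noise of σ ``mz_sigma``; intensities
    get multiplicative log-normal noise of coefficient of variation
    ``intensity_cv``.
    """

    species: tuple[tuple[VariantPeptide, float], ...]
    lam_per_kda: float = 0.65
    k_max: int = 4
    rda_fraction: float = 0.3
    mz_sigma: float = 0.0
    intensity_cv: float = 0.0
    mode: str = "MALDI"
    charges: tuple[int, ...] = (1,)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("at least one species is required")
        for _, abundance in self.species:
            if abundance <= 0:
                raise ValueError("species abundances must be positive")
        if not (0.0 <= self.rda_fraction <= 1.0):
            raise ValueError("rda_fraction must be in [0, 1]")
        if self.mz_sigma < 0 or self.intensity_cv < 0:
            raise ValueError("noise parameters must be non-negative")
        if self.k_max < 0:
            raise ValueError("k_max must be >= 0")


def _envelope_weights(mass: float, lam_per_kda: float, k_max: int) -> np.ndarray:
    lam = lam_per_kda * mass / 1000.0
    weights = stats.poisson.pmf(np.arange(k_max + 1), lam)
    return weights / weights.sum()


def gen_peaklist(
    spec: SpectrumSimSpec,
    registry: Registry | None = None,
    constants: MassConstants = DEFAULT_CONSTANTS,
    label: str = "",
) -> PeakList:
    """Simulate one centroided spectrum from a species mixture.

    Species whose envelopes would overlap within the m/z jitter are still
    generated, but the overlap is flagged in the peak-list metadata.
    """
    registry = registry or default_registry()
    rng = np.random.default_rng(spec.seed)
    sigma_ln = float(np.sqrt(np.log1p(spec.intensity_cv**2)))

    def noisy_intensity(value: float) -> float:
        if spec.intensity_cv == 0:
            return value
        # unit-mean log-normal multiplicative noise
        return value * float(rng.lognormal(-0.5 * sigma_ln**2, sigma_ln))

    peaks: list[Peak] = []
    roots: list[float] = []
    for variant, abundance in spec.species:
        mass = neutral_mass(variant, registry)
        weights = _envelope_weights(mass, spec.lam_per_kda, spec.k_max)
        for z in spec.charges:
            mono = (mass + z * constants.proton) / z
            envelopes = [(mono, abundance)]
            if z == 1 and spec.rda_fraction > 0:
                envelopes.append(
                    (mono - constants.rda_loss, abundance * spec.rda_fraction)
                )
            for root, total in envelopes:
                roots.append(root)
                for k, weight in enumerate(weights):
                    mz = root + k * constants.isotope_spacing / z
                    if spec.mz_sigma > 0:
                        mz += float(rng.normal(0.0, spec.mz_sigma))
                    peaks.append(Peak(mz, noisy_intensity(total * weight)))

    roots.sort()
    overlap = any(
        b - a < max(3 * spec.mz_sigma, 1e-9) for a, b in zip(roots, roots[1:])
    )
    meta = (("overlapping_species", str(overlap).lower()),)
    return PeakList(tuple(peaks), mode=spec.mode, label=label, meta=meta)


def gen_titration(
    ratios: Sequence[float],
    response_factor: float,
    template: SpectrumSimSpec,
    seed: int = 0,
) -> list[tuple[float, PeakList]]:
    """One peak list per known mixing ratio of species A to species B.

    ``template.species`` must hold exactly (A, B); for each known ratio the
    abundance of A is set to ratio × response_factor × abundance(B), so a
    calibration of measured on known ratios recovers ``response_factor`` as
    its slope.  Per-point seeds are derived deterministically from ``seed``.
    """
    if len(ratios) == 0:
        raise ValueError("at least one ratio is required")
    if any(r <= 0 for r in ratios):
        raise ValueError("ratios must be positive")
    if len(template.species) != 2:
        raise ValueError("the titration template needs exactly two species (A, B)")
    (species_a, _), (species_b, abundance_b) = template.species
    out: list[tuple[float, PeakList]] = []
    children = np.random.SeedSequence(seed).spawn(len(ratios))
    for i, ratio in enumerate(ratios):
        child_seed = int(children[i].generate_state(1)[0] % (2**31))
        point = replace(
            template,
            species=(
                (species_a, ratio * response_factor * abundance_b),
                (species_b, abundance_b),
            ),
            seed=child_seed,
        )
        out.append((float(ratio), gen_peaklist(point, label=f"titration_{i}")))
    return out


#: Known-ratio design of the default titration series: five geometric steps
#: bracketing the minor-species regime the calibration is inverted in
#: (a 10% admixture up to a 2:1 excess).
DEFAULT_TITRATION_RATIOS: tuple[float, ...] = (0.1, 0.25, 0.5, 1.0, 2.0)
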