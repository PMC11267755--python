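"""Building blocks, elemental-formula arithmetic and precursor ions for pyoverdine.

Pyoverdine (PVD) of *Pseudomonas aeruginosa* PAO1 is a non-ribosomal peptide:
a dihydroxyquinoline-type chromophore carrying a succinamide (or succinate)
side chain, acylating an 8-residue peptide whose last four residues
(Lys-fOHOrn-Thr-Thr) are closed into a macrolactam.  All mass bookkeeping in
this package is monoisotopic and uses *residue* masses (amino acid minus
water); the N-acylation by the chromophore and the C-terminal macrolactam
closure together consume the terminal water, so the neutral mass of a cyclized
species is simply the chromophore-acyl mass plus the residue-mass sum, with no
+H2O term.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ATOMIC_MONO_MASS",
    "WATER_MASS",
    "MassConstants",
    "DEFAULT_CONSTANTS",
    "ElementalFormula",
    "formula_mass",
    "BuildingBlock",
    "Registry",
    "default_registry",
    "PROTEINOGENIC_IDS",
    "Scaffold",
    "pao1_scaffold",
    "VariantPeptide",
    "neutral_mass",
    "ion_mz",
    "PrecursorIon",
    "precursor_ions",
    "rda_companion",
    "enumerate_variants",
    "MassGroup",
    "mass_groups",
]

#: Standard monoisotopic atomic masses (Da) for the elements occurring in
#: PVD building blocks.
ATOMIC_MONO_MASS: Mapping[str, float] = MappingProxyType(
    {
        "C": 12.000000,
        "H": 1.0078250319,
        "N": 14.0030740052,
        "O": 15.9949146221,
        "S": 31.97207069,
    }
)

WATER_MASS = 2 * ATOMIC_MONO_MASS["H"] + ATOMIC_MONO_MASS["O"]  # 18.01056


@dataclass(frozen=True)
class MassConstants:
    """Physical constants used in ion arithmetic.

    proton
        Mass added per protonation, Da.
    isotope_spacing
        Average spacing of isotopologue peaks, Da.
    rda_loss
        Neutral loss of the in-source retro-Diels-Alder rearrangement of the
        PVD chromophore, Da.  The rearrangement is well documented but its
        composition is not; the default is the difference of the observed
        native precursor/companion pair and is configurable.
    """

    proton: float = 1.00728
    isotope_spacing: float = 1.00335
    rda_loss: float = 303.13

    def __post_init__(self) -> None:
        for name in ("proton", "isotope_spacing", "rda_loss"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


DEFAULT_CONSTANTS = MassConstants()

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalFormula:
    """An elemental composition over C, H, N, O, S with positive counts."""

    counts: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValueError("formula must contain at least one element")
        seen = set()
        for element, count in self.counts:
            if element not in ATOMIC_MONO_MASS:
                raise ValueError(f"unsupported element symbol: {element!r}")
            if element in seen:
                raise ValueError(f"duplicate element symbol: {element!r}")
            if count <= 0 or int(count) != count:
                raise ValueError(f"count for {element} must be a positive integer")
            seen.add(element)

    @classmethod
    def from_mapping(cls, counts: Mapping[str, int]) -> "ElementalFormula":
        return cls(tuple(sorted((str(k), int(v)) for k, v in counts.items())))

    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        """Parse a Hill-style formula string such as ``C6H10N2O3``."""
        text = text.strip()
        if not text:
            raise ValueError("empty formula string")
        counts: dict[str, int] = {}
        pos = 0
        for match in _FORMULA_TOKEN.finditer(text):
            if match.start() != pos or not match.group(1):
                raise ValueError(f"cannot parse formula {text!r}")
            element = match.group(1)
            counts[element] = counts.get(element, 0) + int(match.group(2) or 1)
            pos = match.end()
        if pos != len(text):
            raise ValueError(f"cannot parse formula {text!r}")
        return cls.from_mapping(counts)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    @property
    def mass(self) -> float:
        return sum(ATOMIC_MONO_MASS[el] * n for el, n in self.counts)

    def __str__(self) -> str:
        # Hill order: C, H, then alphabetical.
        order = {"C": 0, "H": 1}
        items = sorted(self.counts, key=lambda kv: (order.get(kv[0], 2), kv[0]))
        return "".join(f"{el}{n if n != 1 else ''}" for el, n in items)


def formula_mass(formula: "ElementalFormula | str | Mapping[str, int]") -> float:
    """Monoisotopic mass (Da) of an elemental formula.

    Accepts an :class:`ElementalFormula`, a formula string, or an
    element→count mapping.
    """
    if isinstance(formula, str):
        formula = ElementalFormula.parse(formula)
    elif isinstance(formula, Mapping):
        formula = ElementalFormula.from_mapping(formula)
    return formula.mass


@dataclass(frozen=True)
class BuildingBlock:
    """A named mass unit: an amino-acid residue or the chromophore-acyl group.

    ``mono_mass`` is the residue mass for amino acids (amino acid minus
    water).  When a formula is given it must agree with ``mono_mass`` to
    within 0.1 mDa.
    """

    id: str
    name: str
    role: str  # "residue" | "chromophore_acyl"
    mono_mass: float
    formula: ElementalFormula | None = None

    def __post_init__(self) -> None:
        if self.role not in ("residue", "chromophore_acyl"):
            raise ValueError(f"unknown role {self.role!r} for block {self.id!r}")
        if self.mono_mass <= 0:
            raise ValueError(f"mono_mass of {self.id!r} must be positive")
        if self.formula is not None and abs(self.mono_mass - self.formula.mass) >= 1e-4:
            raise ValueError(
                f"block {self.id!r}: mono_mass {self.mono_mass} disagrees with "
                f"formula mass {self.formula.mass:.5f}"
            )

    @property
    def nominal_mass(self) -> int:
        return round(self.mono_mass)


class Registry:
    """A lookup table of building blocks keyed by id. Duplicate ids are rejected."""

    def __init__(self, blocks: Iterable[BuildingBlock] = ()) -> None:
        self._blocks: dict[str, BuildingBlock] = {}
        for block in blocks:
            self.add(block)

    def add(self, block: BuildingBlock) -> None:
        if block.id in self._blocks:
            raise ValueError(f"duplicate building-block id {block.id!r}")
        self._blocks[block.id] = block

    def __getitem__(self, block_id: str) -> BuildingBlock:
        try:
            return self._blocks[block_id]
        except KeyError:
            raise KeyError(
                f"building block {block_id!r} not in registry "
                f"(known: {', '.join(sorted(self._blocks))})"
            ) from None

    def __contains__(self, block_id: str) -> bool:
        return block_id in self._blocks

    def __iter__(self):
        return iter(self._blocks.values())

    def __len__(self) -> int:
        return len(self._blocks)

    def ids(self) -> list[str]:
        return list(self._blocks)

    def mass(self, block_id: str) -> float:
        return self[block_id].mono_mass

    def residues(self) -> list[BuildingBlock]:
        return [b for b in self if b.role == "residue"]


# Residue compositions (amino acid minus water).  Leu and Ile are isobaric and
# indistinguishable by mass; they are one entry, as MS practice dictates.
_RESIDUE_FORMULAS: Mapping[str, tuple[str, str]] = {
    "Gly": ("glycine", "C2H3NO"),
    "Ala": ("alanine", "C3H5NO"),
    "Ser": ("serine", "C3H5NO2"),
    "Pro": ("proline", "C5H7NO"),
    "Val": ("valine", "C5H9NO"),
    "Thr": ("threonine", "C4H7NO2"),
    "Cys": ("cysteine", "C3H5NOS"),
    "Leu/Ile": ("leucine/isoleucine (isobaric)", "C6H11NO"),
    "Asn": ("asparagine", "C4H6N2O2"),
    "Asp": ("aspartate", "C4H5NO3"),
    "Gln": ("glutamine", "C5H8N2O2"),
    "Lys": ("lysine", "C6H12N2O"),
    "Glu": ("glutamate", "C5H7NO3"),
    "Met": ("methionine", "C5H9NOS"),
    "His": ("histidine", "C6H7N3O"),
    "Phe": ("phenylalanine", "C9H9NO"),
    "Arg": ("arginine", "C6H12N4O"),
    "Tyr": ("tyrosine", "C9H9NO2"),
    "Trp": ("tryptophan", "C11H10N2O"),
    "Orn": ("ornithine", "C5H10N2O"),
    "fOHOrn": ("L-N5-formyl-N5-hydroxy-ornithine", "C6H10N2O3"),
    "Dab": ("L-2,4-diaminobutyrate", "C4H8N2O"),
    "azHA": ("4-azido-L-homoalanine", "C4H6N4O"),
}

# Chromophore-acyl group of PAO1 pyoverdine including the side chain, as a
# single block under the no-terminal-water convention.  The succinamide and
# succinate forms differ by 0.98402 Da (amide vs acid).
_CHROMOPHORE_FORMULAS: Mapping[str, tuple[str, str]] = {
    "Chr-sa": ("PVD chromophore-acyl, succinamide side chain", "C17H15N3O6"),
    "Chr-sc": ("PVD chromophore-acyl, succinate side chain", "C17H14N2O7"),
}

#: The 19 mass-distinct proteinogenic residues (Leu/Ile merged).
PROTEINOGENIC_IDS: tuple[str, ...] = (
    "Gly", "Ala", "Ser", "Pro", "Val", "Thr", "Cys", "Leu/Ile", "Asn", "Asp",
    "Gln", "Lys", "Glu", "Met", "His", "Phe", "Arg", "Tyr", "Trp",
)


def default_registry() -> Registry:
    """The built-in building-block registry.

    Contains the 19 mass-distinct proteinogenic residues, the
    non-proteinogenic PVD residues (Orn, fOHOrn, Dab), the clickable
    4-azido-L-homoalanine, and the PAO1 chromophore-acyl in both side-chain
    forms.  All masses derive from elemental formulas.
    """
    registry = Registry()
    for block_id, (name, formula) in _RESIDUE_FORMULAS.items():
        f = ElementalFormula.parse(formula)
        registry.add(BuildingBlock(block_id, name, "residue", f.mass, f))
    for block_id, (name, formula) in _CHROMOPHORE_FORMULAS.items():
        f = ElementalFormula.parse(formula)
        registry.add(BuildingBlock(block_id, name, "chromophore_acyl", f.mass, f))
    return registry


@dataclass(frozen=True)
class Scaffold:
    """The PVD peptide scaffold: chromophore-acyl + ordered residues + macrocycle.

    ``cycle_span`` is an inclusive, 1-based position range closed
    side-chain-to-C-terminus (PAO1: 5..8); ``None`` denotes a linear scaffold,
    used for bookkeeping checks.
    """

    residues: tuple[str, ...]
    chromophore: str
    side_chain_form: str = "succinamide"
    cycle_span: tuple[int, int] | None = (5, 8)

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("scaffold needs at least one residue")
        if self.side_chain_form not in ("succinamide", "succinate"):
            raise ValueError(f"unknown side_chain_form {self.side_chain_form!r}")
        if self.cycle_span is not None:
            start, end = self.cycle_span
            if not (1 <= start <= end):
                raise ValueError("cycle_span must be a 1-based inclusive range")
            if end != len(self.residues):
                raise ValueError("cycle_span must end at the last residue")

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def cycle_size(self) -> int:
        if self.cycle_span is None:
            return 0
        return self.cycle_span[1] - self.cycle_span[0] + 1

    @property
    def cycle_start(self) -> int | None:
        return None if self.cycle_span is None else self.cycle_span[0]


#: Peptide sequence of PAO1 pyoverdine, N→C.
PAO1_RESIDUES: tuple[str, ...] = (
    "Ser", "Arg", "Ser", "fOHOrn", "Lys", "fOHOrn", "Thr", "Thr",
)


def pao1_scaffold(side_chain_form: str = "succinamide") -> Scaffold:
    """The PAO1 pyoverdine scaffold in the requested side-chain form."""
    chromophore = {"succinamide": "Chr-sa", "succinate": "Chr-sc"}.get(side_chain_form)
    if chromophore is None:
        raise ValueError(f"unknown side_chain_form {side_chain_form!r}")
    return Scaffold(PAO1_RESIDUES, chromophore, side_chain_form, (5, 8))


@dataclass(frozen=True)
class VariantPeptide:
    """A scaffold plus a position→building-block substitution map.

    No-op substitutions (a position substituted with its original block) are
    canonicalized away, so the identity variant always has an empty map.
    """

    scaffold: Scaffold
    substitutions: tuple[tuple[int, str], ...] = ()
    label: str = ""

    def __post_init__(self) -> None:
        seen = set()
        effective = []
        for pos, block_id in self.substitutions:
            if not (1 <= pos <= self.scaffold.n_residues):
                raise ValueError(f"substitution position {pos} outside scaffold")
            if pos in seen:
                raise ValueError(f"position {pos} substituted twice")
            seen.add(pos)
            if self.scaffold.residues[pos - 1] != block_id:
                effective.append((pos, block_id))
        object.__setattr__(self, "substitutions", tuple(sorted(effective)))
        if not self.label:
            object.__setattr__(self, "label", self.default_label())

    @classmethod
    def from_mapping(
        cls, scaffold: Scaffold, substitutions: Mapping[int, str] | None = None,
        label: str = "",
    ) -> "VariantPeptide":
        return cls(scaffold, tuple(sorted((substitutions or {}).items())), label)

    def default_label(self) -> str:
        if not self.substitutions:
            return "native"
        return "+".join(
            f"{self.scaffold.residues[pos - 1]}{pos}{block}"
            for pos, block in self.substitutions
        )

    @property
    def is_identity(self) -> bool:
        return not self.substitutions

    @property
    def residue_ids(self) -> tuple[str, ...]:
        ids = list(self.scaffold.residues)
        for pos, block_id in self.substitutions:
            ids[pos - 1] = block_id
        return tuple(ids)


def neutral_mass(variant: VariantPeptide, registry: Registry | None = None) -> float:
    """Neutral monoisotopic mass of a (macrocyclized) PVD variant.

    M = mass(chromophore-acyl) + Σ residue masses after substitution.  The
    macrolactam closure and the chromophore N-acylation cancel the terminal
    water, so no +18.01056 term appears; the same convention is applied to
    linear scaffolds, whose fragment arithmetic restores the water explicitly.
    """
    registry = registry or default_registry()
    chromophore = registry[variant.scaffold.chromophore]
    if chromophore.role != "chromophore_acyl":
        raise ValueError(
            f"scaffold chromophore {chromophore.id!r} does not have role "
            "'chromophore_acyl'"
        )
    total = chromophore.mono_mass
    for block_id in variant.residue_ids:
        total += registry[block_id].mono_mass
    return total


def ion_mz(mass: float, z: int, constants: MassConstants = DEFAULT_CONSTANTS) -> float:
    """m/z of the z-fold protonated ion of a neutral species of mass ``mass``."""
    if z < 1 or int(z) != z:
        raise ValueError(f"charge must be a positive integer, got {z}")
    return (mass + z * constants.proton) / z


@dataclass(frozen=True)
class PrecursorIon:
    """A protonated (possibly RDA-rearranged) molecular ion of a PVD variant."""

    species: VariantPeptide
    z: int
    mz: float
    is_rda_companion: bool = False

    def __post_init__(self) -> None:
        if self.z < 1:
            raise ValueError("charge must be >= 1")
        if self.mz <= 0:
            raise ValueError("m/z must be positive")


def rda_companion(
    mz: float, z: int = 1, constants: MassConstants = DEFAULT_CONSTANTS
) -> float:
    """m/z of the retro-Diels-Alder companion of a singly-charged precursor.

    The in-source rearrangement of the PVD chromophore sheds a fixed neutral
    (``constants.rda_loss``); companions are only defined on singly-charged
    species here.
    """
    if z != 1:
        raise ValueError("RDA companions are defined on singly-charged species")
    out = mz - constants.rda_loss
    if out <= 0:
        raise ValueError(f"RDA companion m/z would be non-positive ({out:.3f})")
    return out


def precursor_ions(
    variant: VariantPeptide,
    registry: Registry | None = None,
    charges: Sequence[int] = (1, 2),
    include_rda: bool = True,
    constants: MassConstants = DEFAULT_CONSTANTS,
) -> list[PrecursorIon]:
    """Protonated precursors at the requested charges, plus the z=1 RDA companion."""
    registry = registry or default_registry()
    mass = neutral_mass(variant, registry)
    ions = [PrecursorIon(variant, z, ion_mz(mass, z, constants)) for z in charges]
    if include_rda and 1 in charges:
        ions.append(
            PrecursorIon(
                variant, 1, rda_companion(ion_mz(mass, 1, constants), 1, constants),
                is_rda_companion=True,
            )
        )
    return ions


def enumerate_variants(
    scaffold: Scaffold,
    positions: Iterable[int],
    alphabet: Iterable[str],
    registry: Registry | None = None,
) -> list[VariantPeptide]:
    """All substitution combinations of ``alphabet`` over ``positions``.

    The identity variant is always included.  Distinct substitution maps that
    happen to be isobaric (e.g. Ser at position 7 vs position 8) remain
    distinct variants; use :func:`mass_groups` to collapse them into mass
    groups for matching.
    """
    registry = registry or default_registry()
    positions = sorted(set(positions))
    alphabet = list(dict.fromkeys(alphabet))
    if not alphabet:
        raise ValueError("alphabet must not be empty")
    for pos in positions:
        if not (1 <= pos <= scaffold.n_residues):
            raise ValueError(f"position {pos} outside scaffold")
    for block_id in alphabet:
        registry[block_id]  # raises on unresolvable ids
    variants: list[VariantPeptide] = []
    seen: set[tuple[tuple[int, str], ...]] = set()
    identity = VariantPeptide(scaffold)
    variants.append(identity)
    seen.add(identity.substitutions)
    for combo in itertools.product(alphabet, repeat=len(positions)):
        variant = VariantPeptide.from_mapping(scaffold, dict(zip(positions, combo)))
        if variant.substitutions not in seen:
            seen.add(variant.substitutions)
            variants.append(variant)
    return variants


@dataclass(frozen=True)
class MassGroup:
    """Variants indistinguishable by neutral mass (isobaric group)."""

    mass: float
    members: tuple[VariantPeptide, ...]

    @property
    def label(self) -> str:
        return " | ".join(m.label for m in self.members)

    @property
    def is_isobaric(self) -> bool:
        return len(self.members) > 1


def mass_groups(
    variants: Sequence[VariantPeptide],
    registry: Registry | None = None,
    tol: float = 1e-6,
) -> list[MassGroup]:
    """Group variants whose neutral masses agree within ``tol`` Da."""
    registry = registry or default_registry()
    weighed = sorted(
        ((neutral_mass(v, registry), v) for v in variants), key=lambda mv: mv[0]
    )
    groups: list[MassGroup] = []
    current: list[VariantPeptide] = []
    current_mass = None
    for mass, variant in weighed:
        if current and mass - current_mass > tol:
            groups.append(MassGroup(current_mass, tuple(current)))
            current = []
        if not current:
            current_mass = mass
        current.append(variant)
    if current:
        groups.append(MassGroup(current_mass, tuple(current)))
    return groups
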