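"""Theoretical b- and y-fragment ions for macrocyclized PVD variants.

The C-terminal macrolactam is treated as an uncleavable unit: a single
backbone cleavage cannot open the ring, so no fragment that would require two
cleavages is emitted.  Consequently y-ions smaller than the cycle do not
exist, and b-ions never cut inside the cycle.  Only b/y series are produced —
the series actually used to localize substitutions in PVD MS/MS spectra.

Mass conventions (see :mod:`pvdkit.mass_core`): cyclized y-ions carry no
terminal water (consumed by the macrolactam); linear toy scaffolds restore it,
so the textbook complement identity b_n + y_(N-n) = M + 2·proton + H2O holds
there and serves as an oracle for the bookkeeping.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Sequence

from .mass_core import (
    DEFAULT_CONSTANTS,
    WATER_MASS,
    MassConstants,
    Registry,
    VariantPeptide,
    default_registry,
)

__all__ = ["FragmentIon", "y_ion", "b_ion", "fragment_table", "fragment_table_to_tsv"]


@dataclass(frozen=True)
class FragmentIon:
    """A theoretical b- or y-series fragment ion.

    ``span`` is the inclusive 1-based residue range covered; b-ions
    additionally contain the chromophore-acyl group.  ``low_ce_only`` marks
    ring-containing y-ions, which survive only gentle collisional activation.
    """

    series: str  # "b" | "y"
    index: int
    z: int
    mz: float
    span: tuple[int, int]
    contains_cycle: bool
    low_ce_only: bool

    @property
    def name(self) -> str:
        charge = "+" * self.z
        return f"{self.series}{self.index}{charge if self.z > 1 else ''}"

    def covers(self, position: int) -> bool:
        return self.span[0] <= position <= self.span[1]


def y_ion(
    variant: VariantPeptide,
    n: int,
    z: int = 1,
    registry: Registry | None = None,
    constants: MassConstants = DEFAULT_CONSTANTS,
) -> FragmentIon:
    """The y_n ion: the C-terminal n residues, protonated z-fold.

    For a cyclized scaffold n must be at least the cycle size (the ring
    cannot be opened by one cleavage) and at most n_residues - 1 (the full
    length is the precursor, not a fragment).
    """
    registry = registry or default_registry()
    scaffold = variant.scaffold
    n_res = scaffold.n_residues
    cyclic = scaffold.cycle_span is not None
    min_n = scaffold.cycle_size if cyclic else 1
    if z < 1:
        raise ValueError("charge must be >= 1")
    if n >= n_res:
        raise ValueError(f"y{n} of a {n_res}-residue peptide is the precursor, not a fragment")
    if n < min_n:
        raise ValueError(
            f"y{n} does not exist: the C-terminal macrocycle spans "
            f"{scaffold.cycle_size} residues and a single backbone cleavage "
            "cannot open the ring"
        )
    span = (n_res - n + 1, n_res)
    residues = variant.residue_ids[span[0] - 1 :]
    mass = sum(registry[r].mono_mass for r in residues)
    if not cyclic:
        mass += WATER_MASS
    contains_cycle = cyclic and span[0] <= scaffold.cycle_span[0]
    return FragmentIon(
        series="y",
        index=n,
        z=z,
        mz=(mass + z * constants.proton) / z,
        span=span,
        contains_cycle=contains_cycle,
        low_ce_only=contains_cycle,
    )


def b_ion(
    variant: VariantPeptide,
    n: int,
    z: int = 1,
    registry: Registry | None = None,
    constants: MassConstants = DEFAULT_CONSTANTS,
) -> FragmentIon:
    """The b_n ion: chromophore-acyl plus the N-terminal n residues, protonated z-fold."""
    registry = registry or default_registry()
    scaffold = variant.scaffold
    cyclic = scaffold.cycle_span is not None
    max_n = (scaffold.cycle_start - 1) if cyclic else scaffold.n_residues - 1
    if z < 1:
        raise ValueError("charge must be >= 1")
    if n < 1:
        raise ValueError("b-ion index must be >= 1")
    if n > max_n:
        if cyclic:
            raise ValueError(
                f"b{n} would cut inside the macrocycle (positions "
                f"{scaffold.cycle_span[0]}..{scaffold.cycle_span[1]})"
            )
        raise ValueError(f"b{n} of a {scaffold.n_residues}-residue peptide is not a fragment")
    residues = variant.residue_ids[:n]
    mass = registry[scaffold.chromophore].mono_mass
    mass += sum(registry[r].mono_mass for r in residues)
    return FragmentIon(
        series="b",
        index=n,
        z=z,
        mz=(mass + z * constants.proton) / z,
        span=(1, n),
        contains_cycle=False,
        low_ce_only=False,
    )


def fragment_table(
    variant: VariantPeptide,
    z_list: Sequence[int] = (1,),
    registry: Registry | None = None,
    constants: MassConstants = DEFAULT_CONSTANTS,
) -> list[FragmentIon]:
    """All admissible b- and y-ions of a variant at the requested charges, sorted by m/z."""
    registry = registry or default_registry()
    scaffold = variant.scaffold
    cyclic = scaffold.cycle_span is not None
    ions: list[FragmentIon] = []
    b_max = (scaffold.cycle_start - 1) if cyclic else scaffold.n_residues - 1
    y_min = scaffold.cycle_size if cyclic else 1
    for z in z_list:
        for n in range(1, b_max + 1):
            ions.append(b_ion(variant, n, z, registry, constants))
        for n in range(y_min, scaffold.n_residues):
            ions.append(y_ion(variant, n, z, registry, constants))
    ions.sort(key=lambda ion: ion.mz)
    return ions


def fragment_table_to_tsv(ions: Iterable[FragmentIon], path) -> None:
    """Write a fragment table as TSV (series, n, z, mz, span, low_ce_only)."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["series", "n", "z", "mz", "span_start", "span_end", "low_ce_only"])
        for ion in ions:
            writer.writerow(
                [ion.series, ion.index, ion.z, f"{ion.mz:.3f}",
                 ion.span[0], ion.span[1], int(ion.low_ce_only)]
            )
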