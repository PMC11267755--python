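"""File formats: registry TSV, scaffold config, peak lists (CSV/MGF), labels.

Everything the pipeline reads or writes is plain text.  Peak lists travel as
two-column CSV (mz, intensity; ``#``-prefixed metadata comments) or as MGF
(one BEGIN IONS block; PEPMASS and CHARGE honored for ESI precursors).
Writers are atomic: output lands under a temporary name and is renamed into
place.
"""

from __future__ import annotations

import csv
import os
import tempfile
from contextlib import contextmanager
from typing import Iterable, Mapping

import yaml

from .annotation import Peak, PeakList
from .mass_core import (
    BuildingBlock,
    ElementalFormula,
    Registry,
    Scaffold,
)

__all__ = [
    "atomic_write",
    "read_registry_tsv",
    "write_registry_tsv",
    "packaged_registry_path",
    "read_scaffold_config",
    "write_scaffold_config",
    "packaged_scaffold_path",
    "read_peaklist_csv",
    "write_peaklist_csv",
    "read_peaklist_mgf",
    "write_peaklist_mgf",
    "read_labels_tsv",
    "write_labels_tsv",
]


@contextmanager
def atomic_write(path, mode: str = "w"):
    """Write to a temp file in the target directory, rename on success."""
    directory = os.path.dirname(os.fspath(path)) or "."
    fd, tmp = tempfile.mkstemp(dir=directory, suffix=".tmp")
    try:
        with os.fdopen(fd, mode, newline="") as handle:
            yield handle
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# -- building-block registry -------------------------------------------------

def read_registry_tsv(path) -> Registry:
    """Read a registry TSV with columns id, name, role, formula, mono_mass."""
    registry = Registry()
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        required = {"id", "name", "role", "formula", "mono_mass"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(
                f"registry {path} must have columns {sorted(required)}"
            )
        for row in reader:
            formula = (
                ElementalFormula.parse(row["formula"]) if row["formula"] else None
            )
            registry.add(
                BuildingBlock(
                    id=row["id"],
                    name=row["name"],
                    role=row["role"],
                    mono_mass=float(row["mono_mass"]),
                    formula=formula,
                )
            )
    return registry


def write_registry_tsv(registry: Registry, path) -> None:
    with atomic_write(path) as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["id", "name", "role", "formula", "mono_mass"])
        for block in registry:
            writer.writerow(
                [
                    block.id,
                    block.name,
                    block.role,
                    str(block.formula) if block.formula else "",
                    f"{block.mono_mass:.5f}",
                ]
            )


def _packaged(name: str) -> str:
    from importlib.resources import files

    return str(files("pvdkit").joinpath("data", name))


def packaged_registry_path() -> str:
    """Path of the registry TSV shipped with the package."""
    return _packaged("registry.tsv")


def packaged_scaffold_path() -> str:
    """Path of the PAO1 scaffold config shipped with the package."""
    return _packaged("scaffold_pao1.yaml")


# -- scaffold config ---------------------------------------------------------

def read_scaffold_config(path) -> Scaffold:
    """Read a scaffold from a human-editable YAML config."""
    with open(path) as handle:
        data = yaml.safe_load(handle)
    for key in ("residues", "chromophore", "side_chain_form"):
        if key not in data:
            raise ValueError(f"scaffold config {path} missing key {key!r}")
    cycle = data.get("cycle_span")
    return Scaffold(
        residues=tuple(data["residues"]),
        chromophore=data["chromophore"],
        side_chain_form=data["side_chain_form"],
        cycle_span=tuple(cycle) if cycle else None,
    )


def write_scaffold_config(scaffold: Scaffold, path) -> None:
    data = {
        "residues": list(scaffold.residues),
        "chromophore": scaffold.chromophore,
        "side_chain_form": scaffold.side_chain_form,
        "cycle_span": list(scaffold.cycle_span) if scaffold.cycle_span else None,
    }
    with atomic_write(path) as handle:
        yaml.safe_dump(data, handle, sort_keys=False)


# -- peak lists --------------------------------------------------------------

def read_peaklist_csv(path, mode: str | None = None, label: str = "") -> PeakList:
    """Read a peak list CSV (columns mz, intensity; ``# key: value`` comments)."""
    meta: dict[str, str] = {}
    rows: list[tuple[float, float]] = []
    with open(path, newline="") as handle:
        header_seen = False
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if ":" in line:
                    key, _, value = line.lstrip("#").partition(":")
                    meta[key.strip()] = value.strip()
                continue
            cells = [c.strip() for c in line.split(",")]
            if not header_seen:
                if cells[:2] != ["mz", "intensity"]:
                    raise ValueError(
                        f"{path}:{lineno}: expected header 'mz,intensity', got {line!r}"
                    )
                header_seen = True
                continue
            try:
                rows.append((float(cells[0]), float(cells[1])))
            except (ValueError, IndexError):
                raise ValueError(f"{path}:{lineno}: malformed peak row {line!r}") from None
    resolved_mode = mode or meta.pop("mode", "MALDI")
    resolved_label = label or meta.pop("label", "")
    return PeakList(
        tuple(Peak(*row) for row in rows),
        mode=resolved_mode,
        label=resolved_label,
        meta=tuple(sorted(meta.items())),
    )


def write_peaklist_csv(peaklist: PeakList, path) -> None:
    with atomic_write(path) as handle:
        handle.write(f"# mode: {peaklist.mode}\n")
        if peaklist.label:
            handle.write(f"# label: {peaklist.label}\n")
        for key, value in peaklist.meta:
            handle.write(f"# {key}: {value}\n")
        handle.write("mz,intensity\n")
        for peak in peaklist:
            handle.write(f"{peak.mz:.5f},{peak.intensity:.6g}\n")


def read_peaklist_mgf(path, mode: str = "ESI") -> PeakList:
    """Read the first BEGIN IONS block of an MGF file as a peak list."""
    from pyteomics import mgf

    with mgf.read(os.fspath(path)) as reader:
        try:
            spectrum = next(iter(reader))
        except StopIteration:
            raise ValueError(f"{path}: no spectrum block found") from None
    peaks = tuple(
        Peak(float(mz), float(i))
        for mz, i in zip(spectrum["m/z array"], spectrum["intensity array"])
    )
    params = spectrum.get("params", {})
    label = str(params.get("title", ""))
    meta = []
    if "pepmass" in params:
        meta.append(("pepmass", str(params["pepmass"][0])))
    if "charge" in params:
        meta.append(("charge", str(params["charge"][0])))
    return PeakList(peaks, mode=mode, label=label, meta=tuple(meta))


def write_peaklist_mgf(
    peaklist: PeakList,
    path,
    pepmass: float | None = None,
    charge: int | None = None,
) -> None:
    """Write a peak list as a single MGF spectrum block."""
    from pyteomics import mgf

    params: dict = {"title": peaklist.label or "pvdkit spectrum"}
    if pepmass is not None:
        params["pepmass"] = pepmass
    if charge is not None:
        params["charge"] = charge
    spectrum = {
        "params": params,
        "m/z array": [p.mz for p in peaklist],
        "intensity array": [p.intensity for p in peaklist],
    }
    with atomic_write(path) as handle:
        mgf.write([spectrum], handle)


# -- labels ------------------------------------------------------------------

def read_labels_tsv(path) -> dict[str, str]:
    """Read a two-column TSV (id, category) into a label map."""
    labels: dict[str, str] = {}
    with open(path, newline="") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cells = line.split("\t")
            if len(cells) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'id<TAB>category'")
            if cells[0] in labels:
                raise ValueError(f"{path}:{lineno}: duplicate id {cells[0]!r}")
            labels[cells[0]] = cells[1]
    return labels


def write_labels_tsv(labels: Mapping[str, str], path) -> None:
    with atomic_write(path) as handle:
        for rec_id, category in labels.items():
            handle.write(f"{rec_id}\t{category}\n")


def write_sequence_set_fasta(sequences, path) -> None:
    """Write a LabeledSequenceSet as aligned FASTA (labels travel separately)."""
    with atomic_write(path) as handle:
        for rec_id, seq, _ in sequences.records:
            handle.write(f">{rec_id}\n{seq}\n")
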