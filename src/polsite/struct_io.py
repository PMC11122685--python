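"""Structure, ensemble, mask and topology I/O.

Coordinate convention: ångström throughout, residue numbering 1-based,
residue-range selections inclusive of both endpoints.  Multi-model PDB is
the canonical trajectory interchange format; a whitespace XYZ dialect
(count / comment / element x y z) is accepted for synthetic ensembles.
Alternate locations: the first altloc encountered is kept; insertion codes
are treated as distinct residues by appending the code to the residue
number key.  Hydrogens are retained when present, but default masks select
heavy atoms or representative atoms (Cα / C1′) as stated per operation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "AtomRecord",
    "ConformationEnsemble",
    "SubdomainMask",
    "ToyTopology",
    "StructIOError",
    "PDBParseError",
    "PDBStructureError",
    "MaskConfigError",
    "TopologyConfigError",
    "read_pdb",
    "write_pdb",
    "read_xyz",
    "write_xyz",
    "load_mask_config",
    "resolve_masks",
    "load_topology",
    "write_topology",
]


class StructIOError(Exception):
    """Base error for structure I/O."""


class PDBParseError(StructIOError):
    """Malformed PDB record; message names the offending line number."""


class PDBStructureError(StructIOError):
    """Models disagree on atom count/order, or coordinates unwritable."""


class MaskConfigError(StructIOError):
    """Mask config empty, unresolvable or malformed."""


class TopologyConfigError(StructIOError):
    """Topology config inconsistent with its own atom list."""


@dataclass(frozen=True)
class AtomRecord:
    """Frame-invariant identity of one atom.

    ``residue_key`` (chain, resnum-with-icode) is the unit of residue-level
    bookkeeping for masks, RMSF profiles and energy decomposition.
    """

    serial: int
    name: str
    residue_name: str
    chain_id: str
    residue_number: int
    element: str
    insertion_code: str = ""

    @property
    def residue_key(self) -> tuple[str, str]:
        return (self.chain_id, f"{self.residue_number}{self.insertion_code}")


class ConformationEnsemble:
    """F frames × N atoms × 3 coordinates (Å) with shared atom metadata."""

    def __init__(
        self,
        atoms: Sequence[AtomRecord],
        frames: np.ndarray,
        frame_index: Sequence[int] | None = None,
    ):
        frames = np.asarray(frames, dtype=float)
        if frames.ndim == 2:
            frames = frames[None, :, :]
        if frames.ndim != 3 or frames.shape[2] != 3:
            raise ValueError(f"frames must be F×N×3, got shape {frames.shape}")
        if frames.shape[1] != len(atoms):
            raise ValueError(
                f"{len(atoms)} atom records but frames carry {frames.shape[1]} atoms"
            )
        if frames.shape[0] < 1:
            raise ValueError("ensemble needs at least one frame")
        if not np.all(np.isfinite(frames)):
            raise ValueError("non-finite coordinates")
        serials = [a.serial for a in atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("atom serials must be unique within a frame")
        self.atoms: tuple[AtomRecord, ...] = tuple(atoms)
        self.frames = frames
        self.frame_index = (
            np.asarray(frame_index, dtype=int)
            if frame_index is not None
            else np.arange(frames.shape[0])
        )
        if self.frame_index.shape[0] != frames.shape[0]:
            raise ValueError("frame_index length must match frame count")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def frame(self, i: int) -> np.ndarray:
        return self.frames[i]

    def subset(self, indices: Sequence[int]) -> "ConformationEnsemble":
        idx = np.asarray(indices, dtype=int)
        return ConformationEnsemble(
            [self.atoms[i] for i in idx], self.frames[:, idx, :], self.frame_index
        )

    def atom_index(
        self,
        name: str,
        chain_id: str | None = None,
        residue_number: int | None = None,
        residue_name: str | None = None,
    ) -> int:
        """Index of the unique atom matching the spec; error lists candidates."""
        hits = [
            i
            for i, a in enumerate(self.atoms)
            if a.name == name
            and (chain_id is None or a.chain_id == chain_id)
            and (residue_number is None or a.residue_number == residue_number)
            and (residue_name is None or a.residue_name == residue_name)
        ]
        if len(hits) == 1:
            return hits[0]
        spec = f"name={name!r} chain={chain_id!r} resnum={residue_number!r} resname={residue_name!r}"
        if not hits:
            raise KeyError(f"no atom matches {spec}")
        cands = ", ".join(
            f"{self.atoms[i].chain_id}/{self.atoms[i].residue_number}/{self.atoms[i].name}"
            for i in hits[:8]
        )
        raise KeyError(f"ambiguous atom spec {spec}: candidates {cands}")


@dataclass
class SubdomainMask:
    """Named atom selection restricting a metric to one subdomain.

    ``selection`` holds residue-level members as (chain_id, residue_number)
    pairs; ``atom_indices`` caches the resolved indices for one ensemble.
    """

    name: str
    selection: frozenset[tuple[str, int]]
    atom_indices: np.ndarray | None = None

    def resolve(
        self, ensemble: ConformationEnsemble, atom_names: Iterable[str] | None = None
    ) -> np.ndarray:
        """Atom indices of this mask in ``ensemble``.

        ``atom_names`` optionally restricts to representative atoms
        (e.g. {"CA", "C1'"}).  Unresolvable residues raise with a listing.
        """
        wanted = set(self.selection)
        seen: set[tuple[str, int]] = set()
        idx = []
        for i, a in enumerate(ensemble.atoms):
            key = (a.chain_id, a.residue_number)
            if key in wanted:
                seen.add(key)
                if atom_names is None or a.name in atom_names:
                    idx.append(i)
        missing = wanted - seen
        if missing:
            listing = ", ".join(f"{c}/{r}" for c, r in sorted(missing)[:10])
            raise MaskConfigError(
                f"mask {self.name!r}: residues absent from structure: {listing}"
            )
        if not idx:
            raise MaskConfigError(
                f"mask {self.name!r} selects no atoms"
                + (f" with names {sorted(atom_names)}" if atom_names else "")
            )
        return np.asarray(idx, dtype=int)


@dataclass
class ToyTopology:
    """Minimal non-bonded topology: charges, LJ parameters, bonds, residues.

    Charges in elementary-charge units, sigma in Å, epsilon in kcal/mol.
    ``residue_of`` maps atom index -> residue label; bond graph drives the
    1-2/1-3 exclusion and 1-4 scaling bookkeeping in energy decomposition.
    """

    charges: np.ndarray
    sigmas: np.ndarray
    epsilons: np.ndarray
    bonds: list[tuple[int, int]]
    residue_of: list[str]

    def __post_init__(self):
        self.charges = np.asarray(self.charges, dtype=float)
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        self.epsilons = np.asarray(self.epsilons, dtype=float)
        n = self.charges.shape[0]
        if not (self.sigmas.shape[0] == self.epsilons.shape[0] == len(self.residue_of) == n):
            raise TopologyConfigError("charge/sigma/epsilon/residue arrays disagree in length")
        if np.any(self.epsilons < 0):
            raise TopologyConfigError("epsilon must be >= 0")
        if np.any(self.sigmas <= 0):
            raise TopologyConfigError("sigma must be > 0")
        for a, b in self.bonds:
            if not (0 <= a < n and 0 <= b < n) or a == b:
                raise TopologyConfigError(f"bond ({a},{b}) references invalid atoms")

    @property
    def n_atoms(self) -> int:
        return self.charges.shape[0]

    def residues(self) -> list[str]:
        out = []
        for r in self.residue_of:
            if r not in out:
                out.append(r)
        return out

    def residue_atoms(self, label: str) -> np.ndarray:
        return np.asarray([i for i, r in enumerate(self.residue_of) if r == label], dtype=int)


# ---------------------------------------------------------------------------
# PDB

_REC_ATOM = ("ATOM  ", "HETATM")


def _parse_atom_line(line: str, lineno: int) -> tuple[AtomRecord, np.ndarray, str]:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16].strip()
        resname = line[17:21].strip()
        chain = line[21].strip() or "A"
        resnum = int(line[22:26])
        icode = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"malformed ATOM/HETATM record at line {lineno}: {exc}") from exc
    if not element:
        element = "".join(c for c in name if c.isalpha())[:1]
    rec = AtomRecord(serial, name, resname, chain, resnum, element, icode)
    return rec, np.array([x, y, z]), altloc


def read_pdb(path: str | Path) -> ConformationEnsemble:
    """Read a single- or multi-model PDB file into an ensemble.

    MODEL/ENDMDL blocks delimit frames; a file without MODEL records is one
    frame.  First altloc kept.  Models must agree in atom count and order.
    """
    path = Path(path)
    atoms: list[AtomRecord] = []
    frames: list[list[np.ndarray]] = []
    current: list[np.ndarray] = []
    current_atoms: list[AtomRecord] = []
    seen_altloc: set[tuple] = set()
    in_model = False
    any_model = False
    model_no = 0

    def close_model():
        nonlocal atoms
        if not current:
            return
        if not atoms:
            atoms = list(current_atoms)
        else:
            if len(current_atoms) != len(atoms):
                raise PDBStructureError(
                    f"model {model_no} has {len(current_atoms)} atoms, "
                    f"first model has {len(atoms)}"
                )
        frames.append(list(current))

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                any_model = True
                in_model = True
                model_no += 1
                current, current_atoms, seen_altloc = [], [], set()
            elif rec == "ENDMDL":
                close_model()
                in_model = False
                current, current_atoms = [], []
            elif rec in _REC_ATOM:
                atom, xyz, altloc = _parse_atom_line(line, lineno)
                if altloc:
                    key = (atom.chain_id, atom.residue_number, atom.insertion_code, atom.name)
                    if key in seen_altloc:
                        continue
                    seen_altloc.add(key)
                current_atoms.append(atom)
                current.append(xyz)
    if not any_model:
        model_no = 1
        close_model()
    elif in_model:
        close_model()  # tolerate missing final ENDMDL
    if not frames:
        raise PDBStructureError(f"{path}: no ATOM/HETATM records found")
    return ConformationEnsemble(atoms, np.asarray(frames))


def write_pdb(ensemble: ConformationEnsemble, path: str | Path) -> None:
    """Write fixed-column PDB; one MODEL block per frame when F > 1.

    A coordinate not representable in the 8.3 fixed field raises instead of
    silently truncating.
    """
    path = Path(path)
    lines: list[str] = []
    multi = ensemble.n_frames > 1
    for f in range(ensemble.n_frames):
        if multi:
            lines.append(f"MODEL     {f + 1:4d}")
        for a, xyz in zip(ensemble.atoms, ensemble.frames[f]):
            for c in xyz:
                if not (-999.999 <= c <= 9999.999):
                    raise PDBStructureError(
                        f"coordinate {c:.3f} for atom serial {a.serial} overflows "
                        "the PDB 8.3 field"
                    )
            name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
            lines.append(
                f"ATOM  {a.serial:5d} {name:<4.4s}{'':1s}{a.residue_name:<4.4s}"
                f"{a.chain_id:1.1s}{a.residue_number:4d}{a.insertion_code:<1.1s}   "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {a.element:>2.2s}"
            )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# XYZ trajectory dialect (count / comment / element x y z)


def read_xyz(path: str | Path) -> ConformationEnsemble:
    path = Path(path)
    text = path.read_text().splitlines()
    frames = []
    atoms: list[AtomRecord] = []
    i = 0
    lineno = 0
    while i < len(text):
        if not text[i].strip():
            i += 1
            continue
        try:
            n = int(text[i].strip())
        except ValueError as exc:
            raise PDBParseError(f"expected atom count at line {i + 1}") from exc
        block = text[i + 2 : i + 2 + n]
        if len(block) < n:
            raise PDBParseError(f"truncated XYZ frame starting at line {i + 1}")
        coords = []
        frame_atoms = []
        for j, row in enumerate(block):
            parts = row.split()
            if len(parts) < 4:
                raise PDBParseError(f"malformed XYZ row at line {i + 3 + j}")
            el = parts[0]
            coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
            frame_atoms.append(
                AtomRecord(j + 1, el, "UNK", "A", j + 1, el)
            )
        if not atoms:
            atoms = frame_atoms
        elif len(frame_atoms) != len(atoms):
            raise PDBStructureError("XYZ frames disagree in atom count")
        frames.append(coords)
        i += 2 + n
    if not frames:
        raise PDBStructureError(f"{path}: empty XYZ file")
    return ConformationEnsemble(atoms, np.asarray(frames, dtype=float))


def write_xyz(ensemble: ConformationEnsemble, path: str | Path, comment: str = "") -> None:
    out = []
    for f in range(ensemble.n_frames):
        out.append(str(ensemble.n_atoms))
        out.append(comment or f"frame {f}")
        for a, xyz in zip(ensemble.atoms, ensemble.frames[f]):
            out.append(f"{a.element or 'X':<2s} {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Mask config


def _parse_ranges(entry) -> list[tuple[str, int, int]]:
    """Normalize config residue ranges to (chain, lo, hi) inclusive triples."""
    if isinstance(entry, Mapping):
        entry = [entry]
    out = []
    for item in entry:
        chain = str(item["chain"])
        rng = item["residues"]
        if isinstance(rng, str):
            lo, hi = (int(t) for t in rng.replace("-", " ").split())
        elif isinstance(rng, (list, tuple)) and len(rng) == 2:
            lo, hi = int(rng[0]), int(rng[1])
        else:
            lo = hi = int(rng)
        if lo > hi:
            raise MaskConfigError(f"range {lo}-{hi} reversed")
        out.append((chain, lo, hi))
    return out


def load_mask_config(
    path: str | Path, reference: ConformationEnsemble | None = None
) -> list[SubdomainMask]:
    """Load named subdomain masks from a YAML config.

    Schema::

        masks:
          Palm:    {chain: A, residues: [815, 910]}
          Fingers: [{chain: A, residues: 911-1048}, {chain: A, residues: 1076-1095}]

    Overlapping masks are allowed by design (subdomain boundaries are a
    convention, not a partition).  If ``reference`` is given, each mask is
    resolved against it and unresolvable residues raise.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not raw or "masks" not in raw or not raw["masks"]:
        raise MaskConfigError(f"{path}: no masks defined")
    masks = []
    for name, entry in raw["masks"].items():
        sel: set[tuple[str, int]] = set()
        for chain, lo, hi in _parse_ranges(entry):
            sel.update((chain, r) for r in range(lo, hi + 1))
        if not sel:
            raise MaskConfigError(f"mask {name!r} selects nothing")
        masks.append(SubdomainMask(str(name), frozenset(sel)))
    if reference is not None:
        for m in masks:
            m.atom_indices = m.resolve(reference)
    return masks


def resolve_masks(
    masks: Sequence[SubdomainMask],
    ensemble: ConformationEnsemble,
    atom_names: Iterable[str] | None = None,
) -> dict[str, np.ndarray]:
    return {m.name: m.resolve(ensemble, atom_names) for m in masks}


# ---------------------------------------------------------------------------
# Topology config


def load_topology(path: str | Path) -> tuple[ToyTopology, np.ndarray | None]:
    """Load a toy topology (and optional coordinates) from YAML.

    Schema::

        atoms:
          - {residue: ARG1, charge: 0.5, sigma: 3.3, epsilon: 0.1, xyz: [0,0,0]}
        bonds: [[0, 1], [1, 2]]
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not raw or "atoms" not in raw:
        raise TopologyConfigError(f"{path}: no atoms defined")
    charges, sigmas, epsilons, residues, coords = [], [], [], [], []
    have_xyz = True
    for a in raw["atoms"]:
        charges.append(float(a["charge"]))
        sigmas.append(float(a["sigma"]))
        epsilons.append(float(a["epsilon"]))
        residues.append(str(a["residue"]))
        if "xyz" in a:
            coords.append([float(v) for v in a["xyz"]])
        else:
            have_xyz = False
    bonds = [tuple(int(v) for v in b) for b in raw.get("bonds", [])]
    topo = ToyTopology(
        np.asarray(charges), np.asarray(sigmas), np.asarray(epsilons), bonds, residues
    )
    return topo, (np.asarray(coords) if have_xyz and coords else None)


def write_topology(
    topology: ToyTopology, path: str | Path, coords: np.ndarray | None = None
) -> None:
    atoms = []
    for i in range(topology.n_atoms):
        entry = {
            "residue": topology.residue_of[i],
            "charge": float(topology.charges[i]),
            "sigma": float(topology.sigmas[i]),
            "epsilon": float(topology.epsilons[i]),
        }
        if coords is not None:
            entry["xyz"] = [float(v) for v in coords[i]]
        atoms.append(entry)
    Path(path).write_text(
        yaml.safe_dump({"atoms": atoms, "bonds": [list(b) for b in topology.bonds]})
    )
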