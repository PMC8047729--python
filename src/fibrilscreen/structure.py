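"""Fibril structure handling: PDB input, pocket selection, superposition.

Amyloid fibrils are stacks of near-identical β-strands; a binding site is a
shallow groove that runs along the fibril axis and is specified here as a set
of residues (author numbering) on one or more chains, with one residue acting
as the pocket anchor.  Superposition of pocket coordinates between two fibril
polymorphs uses the Kabsch algorithm and reports the backbone RMSD.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb


class EmptyStructureError(ValueError):
    """Raised when a PDB file contains no coordinate records."""


class PocketLookupError(KeyError):
    """Raised when a requested pocket residue is absent from a chain."""


@dataclass(frozen=True)
class AtomRecord:
    """One coordinate record (author numbering, Å)."""

    serial: int
    name: str
    element: str
    residue_number: int
    residue_name: str
    chain_id: str
    position: np.ndarray
    occupancy: float = 1.0

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.serial}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if not self.element:
            raise ValueError(f"atom {self.serial}: element must be non-empty")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.serial}: occupancy outside [0, 1]")


@dataclass
class FibrilStructure:
    """Ordered atom list plus a chain → residue-number index."""

    atoms: list[AtomRecord]
    id: str = ""
    chains: dict[str, list[int]] = field(init=False)

    def __post_init__(self):
        if not self.atoms:
            raise EmptyStructureError(f"structure {self.id!r} has no atoms")
        chains: dict[str, list[int]] = {}
        seen_keys = set()
        for atom in self.atoms:
            key = (atom.chain_id, atom.residue_number, atom.name)
            if key in seen_keys:
                raise ValueError(f"duplicate atom {key} in structure {self.id!r}")
            seen_keys.add(key)
            residues = chains.setdefault(atom.chain_id, [])
            if not residues or residues[-1] != atom.residue_number:
                if residues and atom.residue_number < residues[-1]:
                    raise ValueError(
                        f"residue numbers not increasing in chain {atom.chain_id}"
                    )
                if not residues or residues[-1] != atom.residue_number:
                    residues.append(atom.residue_number)
        self.chains = chains

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    def chain_ids(self) -> list[str]:
        return list(self.chains)

    def central_chain(self) -> str:
        """Middle chain in file order — the default 'central strand'."""
        ids = self.chain_ids()
        return ids[len(ids) // 2]


@dataclass(frozen=True)
class PocketSpec:
    """Named binding-site definition.

    ``numbering="author"`` addresses residues per chain (requires
    ``chain_selection``); ``numbering="serial"`` counts residues continuously
    across chains in file order (1-based), the alternative addressing mode.
    """

    site_label: str
    member_residues: tuple[int, ...]
    anchor_residue: int
    chain_selection: tuple[str, ...] = ()
    numbering: str = "author"

    def __post_init__(self):
        if not self.member_residues:
            raise ValueError("member_residues must be non-empty")
        if self.anchor_residue not in self.member_residues:
            raise ValueError("anchor_residue must be a member residue")
        if self.numbering not in ("author", "serial"):
            raise ValueError("numbering must be 'author' or 'serial'")
        object.__setattr__(self, "member_residues", tuple(self.member_residues))
        object.__setattr__(self, "chain_selection", tuple(self.chain_selection))


def load_pdb(path, structure_id: str | None = None) -> FibrilStructure:
    """Read ATOM/HETATM records from a PDB file.

    Alternate locations are collapsed to the highest-occupancy conformer
    (biotite ``altloc="occupancy"``).
    """
    pdb_file = pdb.PDBFile.read(str(path))
    try:
        array = pdb_file.get_structure(
            model=1, altloc="occupancy", extra_fields=["occupancy", "atom_id"]
        )
    except Exception as exc:
        raise EmptyStructureError(f"no coordinate records in {path}") from exc
    if array.array_length() == 0:
        raise EmptyStructureError(f"no coordinate records in {path}")
    atoms = []
    for i in range(array.array_length()):
        element = str(array.element[i]).strip() or str(array.atom_name[i])[0]
        atoms.append(
            AtomRecord(
                serial=int(array.atom_id[i]),
                name=str(array.atom_name[i]),
                element=element.capitalize(),
                residue_number=int(array.res_id[i]),
                residue_name=str(array.res_name[i]),
                chain_id=str(array.chain_id[i]),
                position=np.asarray(array.coord[i], dtype=float),
                occupancy=float(min(max(array.occupancy[i], 0.0), 1.0)),
            )
        )
    if structure_id is None:
        import os

        structure_id = os.path.splitext(os.path.basename(str(path)))[0]
    return FibrilStructure(atoms=atoms, id=structure_id)


def _serial_residue_keys(structure: FibrilStructure) -> list[tuple[str, int]]:
    """(chain, author residue) pairs in file order, one per residue."""
    keys: list[tuple[str, int]] = []
    for chain, residues in structure.chains.items():
        keys.extend((chain, r) for r in residues)
    return keys


def select_pocket(structure: FibrilStructure, spec: PocketSpec) -> list[AtomRecord]:
    """Atoms of the pocket's member residues, original order preserved."""
    if spec.numbering == "serial":
        keys = _serial_residue_keys(structure)
        wanted = set()
        for serial_index in spec.member_residues:
            if not 1 <= serial_index <= len(keys):
                raise PocketLookupError(
                    f"serial residue {serial_index} outside 1..{len(keys)}"
                )
            wanted.add(keys[serial_index - 1])
        return [a for a in structure.atoms if (a.chain_id, a.residue_number) in wanted]

    chains = spec.chain_selection or (structure.central_chain(),)
    for chain in chains:
        present = set(structure.chains.get(chain, ()))
        for res in spec.member_residues:
            if res not in present:
                raise PocketLookupError(
                    f"residue {res} not found in chain {chain!r}"
                )
    member = set(spec.member_residues)
    chain_set = set(chains)
    return [
        a
        for a in structure.atoms
        if a.chain_id in chain_set and a.residue_number in member
    ]


def anchor_centroid(structure: FibrilStructure, spec: PocketSpec) -> np.ndarray:
    """Centroid of the anchor residue's atoms on the selected chain(s)."""
    anchor_spec = replace(
        spec, member_residues=(spec.anchor_residue,), anchor_residue=spec.anchor_residue
    )
    atoms = select_pocket(structure, anchor_spec)
    return np.mean([a.position for a in atoms], axis=0)


def add_backbone_amide_hydrogens(structure: FibrilStructure) -> FibrilStructure:
    """Rebuild polar amide hydrogens on backbone N where absent.

    H is placed 1.01 Å from N along the outward bisector of the N–CA and
    N–C(previous residue) bonds — standard planar amide geometry.  Residues
    lacking a preceding carbonyl carbon (chain starts) are skipped, as are
    residues that already carry an amide H.
    """
    index: dict[tuple[str, int], dict[str, AtomRecord]] = {}
    for atom in structure.atoms:
        index.setdefault((atom.chain_id, atom.residue_number), {})[atom.name] = atom

    new_atoms = list(structure.atoms)
    serial = max(a.serial for a in structure.atoms)
    for chain, residues in structure.chains.items():
        for prev_res, res in zip(residues, residues[1:]):
            here = index.get((chain, res), {})
            if "H" in here or "N" not in here or "CA" not in here:
                continue
            prev = index.get((chain, prev_res), {})
            if "C" not in prev:
                continue
            n = here["N"].position
            v1 = here["CA"].position - n
            v2 = prev["C"].position - n
            v1 /= np.linalg.norm(v1)
            v2 /= np.linalg.norm(v2)
            direction = -(v1 + v2)
            norm = np.linalg.norm(direction)
            if norm < 1e-8:
                continue
            serial += 1
            new_atoms.append(
                AtomRecord(
                    serial=serial,
                    name="H",
                    element="H",
                    residue_number=res,
                    residue_name=here["N"].residue_name,
                    chain_id=chain,
                    position=n + 1.01 * direction / norm,
                )
            )
    # Keep author file order by chain/residue: re-sort hydrogens next to their residue
    order = {(a.chain_id, a.residue_number): i for i, a in enumerate(structure.atoms)}
    new_atoms.sort(key=lambda a: (order.get((a.chain_id, a.residue_number), 1 << 30), a.serial))
    return FibrilStructure(atoms=new_atoms, id=structure.id)


class SuperpositionError(ValueError):
    pass


def kabsch_superpose(mobile, reference) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``rotation @ x + translation`` maps mobile points onto the reference
    frame with minimal RMSD.  The rotation is proper (det = +1).
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise SuperpositionError(
            f"point sets must both be N×3, got {mob.shape} vs {ref.shape}"
        )
    n = mob.shape[0]
    if n < 3:
        raise SuperpositionError("need at least 3 points for superposition")
    cm, cr = mob.mean(axis=0), ref.mean(axis=0)
    a, b = mob - cm, ref - cr
    if np.linalg.matrix_rank(a, tol=1e-8) < 2:
        raise SuperpositionError("degenerate (collinear) point set")
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rotation = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    translation = cr - rotation @ cm
    moved = mob @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return rotation, translation, rmsd


def superpose_pockets(
    mobile_structure: FibrilStructure,
    mobile_spec: PocketSpec,
    reference_structure: FibrilStructure,
    reference_spec: PocketSpec,
    atom_names: tuple[str, ...] | None = ("CA",),
) -> dict:
    """Superpose one pocket onto another (CA atoms by default).

    The two selections must yield equally many atoms after name filtering.
    Returns a JSON-serializable report.
    """

    def pick(structure, spec):
        atoms = select_pocket(structure, spec)
        if atom_names is not None:
            atoms = [a for a in atoms if a.name in atom_names]
        return np.array([a.position for a in atoms])

    mob, ref = pick(mobile_structure, mobile_spec), pick(reference_structure, reference_spec)
    rotation, translation, rmsd = kabsch_superpose(mob, ref)
    return {
        "mobile": mobile_structure.id,
        "reference": reference_structure.id,
        "site_label": reference_spec.site_label,
        "n_atoms": int(mob.shape[0]),
        "rotation": rotation.tolist(),
        "translation": translation.tolist(),
        "rmsd": rmsd,
    }


def pocket_selection_report(
    structure: FibrilStructure, spec: PocketSpec, atoms: list[AtomRecord]
) -> str:
    return json.dumps(
        {
            "site_label": spec.site_label,
            "structure": structure.id,
            "chains": sorted({a.chain_id for a in atoms}),
            "residues": sorted({a.residue_number for a in atoms}),
            "atom_count": len(atoms),
        },
        indent=2,
        sort_keys=True,
    )
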