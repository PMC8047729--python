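"""Small-molecule library I/O (SMILES and SDF via RDKit)."""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem
from rdkit.Chem import Descriptors


@dataclass
class LibraryEntry:
    id: str
    mol: Chem.Mol
    mol_weight: float | None = None
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mol_weight is None and self.mol is not None:
            self.mol_weight = float(Descriptors.MolWt(self.mol))


def read_smiles(path) -> list[LibraryEntry]:
    """One molecule per line: ``SMILES [id]``; ids default to line position."""
    entries = []
    with open(path) as fh:
        for n, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            smiles = parts[0]
            mol_id = parts[1] if len(parts) > 1 else f"mol{n}"
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                continue
            mol.SetProp("_Name", mol_id)
            entries.append(LibraryEntry(id=mol_id, mol=mol))
    _check_unique(entries)
    return entries


def read_sdf(path) -> list[LibraryEntry]:
    """3-D SDF; the first conformer of each record is used."""
    entries = []
    supplier = Chem.SDMolSupplier(str(path), removeHs=True)
    for n, mol in enumerate(supplier, start=1):
        if mol is None:
            continue
        mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol{n}"
        entries.append(LibraryEntry(id=mol_id, mol=mol))
    _check_unique(entries)
    return entries


def read_library(path) -> list[LibraryEntry]:
    p = str(path)
    if p.endswith(".sdf"):
        return read_sdf(p)
    return read_smiles(p)


def write_sdf(entries_or_mols, path) -> None:
    writer = Chem.SDWriter(str(path))
    try:
        for item in entries_or_mols:
            mol = item.mol if isinstance(item, LibraryEntry) else item
            writer.write(mol)
    finally:
        writer.close()


def _check_unique(entries: list[LibraryEntry]) -> None:
    seen = set()
    for e in entries:
        if e.id in seen:
            raise ValueError(f"duplicate library id {e.id!r}")
        seen.add(e.id)
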