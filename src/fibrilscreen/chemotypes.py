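"""Shared pharmacophoric chemotype vocabulary.

Three interaction classes are distinguished on both the protein-complement
(exemplar) side and the ligand side: hydrophobic contact, hydrogen-bond
donor, and hydrogen-bond acceptor.
"""

from __future__ import annotations

from enum import Enum


class Chemotype(str, Enum):
    HYDROPHOBIC = "HYDROPHOBIC"
    DONOR = "DONOR"
    ACCEPTOR = "ACCEPTOR"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Thinning / conflict priority: polar chemotypes outrank hydrophobic,
#: donors break ties with acceptors so ordering is total and deterministic.
CHEMOTYPE_PRIORITY = {
    Chemotype.DONOR: 0,
    Chemotype.ACCEPTOR: 1,
    Chemotype.HYDROPHOBIC: 2,
}

#: Fixed element van der Waals radii (Å), chosen for reproducibility.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.10}
DEFAULT_VDW = 1.70

#: Apolar / polar heavy-element partition used throughout.
APOLAR_ELEMENTS = {"C", "S"}
POLAR_ELEMENTS = {"N", "O"}


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_VDW)
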