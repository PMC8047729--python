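"""Rigid-body pose scoring against a pocket and its exemplar.

This is a deliberately simple, fully documented scorer over three terms:
a soft-sphere steric repulsion, a Gaussian hydrogen-bond reward between
polar heavy atoms, and a pharmacophore-match reward proportional to the
Gaussian overlap between the ligand's feature model and the exemplar.
The receptor is held rigid; only the six rigid-body degrees of freedom of
the ligand are optimized.  The downstream free-energy correlation stage is
score-agnostic and accepts externally computed score tables instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .chemotypes import POLAR_ELEMENTS, vdw_radius
from .exemplar import Exemplar
from .pharmacophore import PharmacophoreModel, gaussian_overlap, model_from_exemplar
from .structure import AtomRecord


@dataclass(frozen=True)
class ScoreWeights:
    w_rep: float = 10.0
    w_hb: float = 2.0
    w_pm: float = 1.0
    d_opt: float = 2.9  # Å, ideal donor–acceptor separation
    sigma: float = 0.35  # Å, H-bond Gaussian width


@dataclass
class Pose:
    """Ligand atoms (element, position) in the receptor frame."""

    molecule_atoms: list[tuple[str, np.ndarray]]
    structure_id: str
    site_label: str
    transform: tuple[np.ndarray, np.ndarray] = field(
        default_factory=lambda: (np.eye(3), np.zeros(3))
    )
    pharmacophore: PharmacophoreModel | None = None

    def __post_init__(self):
        atoms = []
        for element, position in self.molecule_atoms:
            p = np.asarray(position, dtype=float)
            if not np.all(np.isfinite(p)):
                raise ValueError("pose positions must be finite")
            atoms.append((element, p))
        self.molecule_atoms = atoms

    def coords(self, heavy_only: bool = True) -> np.ndarray:
        sel = [
            p for e, p in self.molecule_atoms if not heavy_only or e.upper() != "H"
        ]
        return np.array(sel)

    def elements(self, heavy_only: bool = True) -> list[str]:
        return [e for e, _ in self.molecule_atoms if not heavy_only or e.upper() != "H"]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Pose":
        atoms = [(e, rotation @ p + translation) for e, p in self.molecule_atoms]
        r0, t0 = self.transform
        model = (
            self.pharmacophore.transformed(rotation, translation)
            if self.pharmacophore is not None
            else None
        )
        return Pose(
            molecule_atoms=atoms,
            structure_id=self.structure_id,
            site_label=self.site_label,
            transform=(rotation @ r0, rotation @ t0 + translation),
            pharmacophore=model,
        )


@dataclass(frozen=True)
class ScoreRecord:
    compound_id: str
    structure_id: str
    score: float  # arbitrary energy-like units, lower = better
    components: dict
    source: str = "INTERNAL"


class NumericalFailureError(RuntimeError):
    pass


def steric_term(
    pose: Pose, pocket_atoms: list[AtomRecord], weights: ScoreWeights | None = None
) -> float:
    """Soft-sphere clash penalty: Σ w_rep (1 − d/d0)² for d < d0 = r_i + r_j."""
    w = weights or ScoreWeights()
    lig = pose.coords()
    if lig.size == 0 or not pocket_atoms:
        return 0.0
    lig_r = np.array([vdw_radius(e) for e in pose.elements()])
    prot = np.array([a.position for a in pocket_atoms if a.element.upper() != "H"])
    prot_r = np.array(
        [vdw_radius(a.element) for a in pocket_atoms if a.element.upper() != "H"]
    )
    d = np.linalg.norm(lig[:, None, :] - prot[None, :, :], axis=-1)
    d0 = lig_r[:, None] + prot_r[None, :]
    clash = d < d0
    if not clash.any():
        return 0.0
    frac = 1.0 - d[clash] / d0[clash]
    return float(w.w_rep * np.sum(frac**2))


def interaction_terms(
    pose: Pose,
    pocket_atoms: list[AtomRecord],
    exemplar: Exemplar,
    weights: ScoreWeights | None = None,
) -> tuple[float, float]:
    """(hbond, pharm_match) attractive terms; both ≤ 0.

    hbond pairs every polar ligand heavy atom with every polar protein heavy
    atom via a Gaussian in distance around the ideal separation; pharm_match
    is minus the weighted Gaussian overlap between the ligand pharmacophore
    and the exemplar.
    """
    w = weights or ScoreWeights()
    lig_polar = np.array(
        [p for e, p in pose.molecule_atoms if e.upper() in POLAR_ELEMENTS]
    )
    hbond = 0.0
    if lig_polar.size:
        prot_polar = np.array(
            [a.position for a in pocket_atoms if a.element.upper() in POLAR_ELEMENTS]
        )
        if prot_polar.size:
            d = np.linalg.norm(lig_polar[:, None, :] - prot_polar[None, :, :], axis=-1)
            hbond = -w.w_hb * float(
                np.sum(np.exp(-((d - w.d_opt) ** 2) / (2 * w.sigma**2)))
            )
    pharm = 0.0
    if pose.pharmacophore is not None:
        pharm = -w.w_pm * gaussian_overlap(
            pose.pharmacophore, model_from_exemplar(exemplar)
        )
    return float(hbond), float(pharm)


def total_score(
    pose: Pose,
    pocket_atoms: list[AtomRecord],
    exemplar: Exemplar,
    weights: ScoreWeights | None = None,
) -> dict:
    w = weights or ScoreWeights()
    steric = steric_term(pose, pocket_atoms, w)
    hbond, pharm = interaction_terms(pose, pocket_atoms, exemplar, w)
    return {"steric": steric, "hbond": hbond, "pharm_match": pharm}


def minimize_pose(
    pose: Pose,
    pocket_atoms: list[AtomRecord],
    exemplar: Exemplar,
    max_iter: int = 200,
    seed: int = 0,
    weights: ScoreWeights | None = None,
    n_starts: int = 6,
    compound_id: str = "",
) -> tuple[Pose, ScoreRecord]:
    """Seeded multi-start local search over the 6 rigid DOF.

    The returned score never exceeds the starting score (the start pose is
    always a candidate).  Deterministic for a fixed seed.
    """
    w = weights or ScoreWeights()
    center = pose.coords(heavy_only=False).mean(axis=0)

    def apply(x) -> Pose:
        rot = Rotation.from_rotvec(x[:3]).as_matrix()
        # rotate about the ligand centroid, then translate
        trans = x[3:] + center - rot @ center
        return pose.transformed(rot, trans)

    def objective(x) -> float:
        comp = total_score(apply(x), pocket_atoms, exemplar, w)
        val = sum(comp.values())
        if not np.isfinite(val):
            raise NumericalFailureError("non-finite score during optimization")
        return val

    rng = np.random.default_rng(seed)
    starts = [np.zeros(6)]
    for _ in range(max(0, n_starts - 1)):
        starts.append(
            np.concatenate([rng.normal(0, 0.1, 3), rng.normal(0, 0.25, 3)])
        )

    best_x, best_val = np.zeros(6), objective(np.zeros(6))
    for x0 in starts:
        res = minimize(
            objective,
            x0,
            method="Powell",
            options={"maxiter": max_iter, "xtol": 1e-6, "ftol": 1e-9},
        )
        if res.fun < best_val:
            best_val, best_x = float(res.fun), res.x

    final = apply(best_x)
    comp = total_score(final, pocket_atoms, exemplar, w)
    record = ScoreRecord(
        compound_id=compound_id,
        structure_id=pose.structure_id,
        score=float(sum(comp.values())),
        components=comp,
        source="INTERNAL",
    )
    return final, record


def pose_from_rdkit(mol, structure_id: str, site_label: str, pharmacophore=None) -> Pose:
    conf = mol.GetConformer()
    atoms = [
        (atom.GetSymbol(), np.array(conf.GetAtomPosition(atom.GetIdx())))
        for atom in mol.GetAtoms()
    ]
    return Pose(
        molecule_atoms=atoms,
        structure_id=structure_id,
        site_label=site_label,
        pharmacophore=pharmacophore,
    )


def read_scores_csv(path) -> list[ScoreRecord]:
    """External score ingestion: compound_id, structure_id, score[, source_label]."""
    df = pd.read_csv(path)
    required = {"compound_id", "structure_id", "score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"score CSV missing columns: {sorted(missing)}")
    out = []
    for r in df.itertuples():
        label = getattr(r, "source_label", "EXTERNAL")
        out.append(
            ScoreRecord(
                compound_id=str(r.compound_id),
                structure_id=str(r.structure_id),
                score=float(r.score),
                components={},
                source=str(label) if isinstance(label, str) else "EXTERNAL",
            )
        )
    return out
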