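"""Gaussian-volume pharmacophore models, overlap Tanimoto, rigid alignment.

A molecule or exemplar is reduced to a set of spherical Gaussian features
(hydrophobic, donor, acceptor).  The overlap volume between two models sums
Grant–Pickup pair integrals over features of matching kind,

    V_AB = Σ_ij h_i h_j (π/(α_i+α_j))^{3/2} exp(−α_i α_j ‖c_i−c_j‖² / (α_i+α_j)),

and the volumetric Tanimoto T = V_AB / (V_AA + V_BB − V_AB) scores how well
two models agree both in feature composition and 3-D arrangement.  Alignment
maximizes T over rigid transforms with deterministic multi-start local
optimization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from rdkit import Chem
from rdkit.Chem import AllChem

from .chemotypes import APOLAR_ELEMENTS, Chemotype
from .exemplar import Exemplar

DEFAULT_ALPHA = 0.7  # Gaussian width (Å⁻²): single sharpness knob
DEFAULT_HEIGHT = 1.0
EMBED_SEED = 1234  # fixed conformer-embedding seed for SMILES inputs


class FeaturelessMoleculeError(ValueError):
    """Molecule yields no pharmacophore feature under the rules."""


class DegenerateVolumeError(ArithmeticError):
    pass


@dataclass(frozen=True)
class PharmacophoreFeature:
    kind: Chemotype
    center: np.ndarray
    alpha: float = DEFAULT_ALPHA
    height: float = DEFAULT_HEIGHT

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if self.alpha <= 0 or self.height <= 0:
            raise ValueError("alpha and height must be positive")


@dataclass
class PharmacophoreModel:
    id: str
    features: list[PharmacophoreFeature]
    source: str = "MOLECULE"  # MOLECULE or EXEMPLAR

    def __post_init__(self):
        if not self.features:
            raise FeaturelessMoleculeError(f"model {self.id!r} has no features")

    def centers(self) -> np.ndarray:
        return np.array([f.center for f in self.features])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "PharmacophoreModel":
        feats = [
            replace(f, center=rotation @ f.center + translation) for f in self.features
        ]
        return PharmacophoreModel(id=self.id, features=feats, source=self.source)


@dataclass(frozen=True)
class AlignmentResult:
    rotation: np.ndarray
    translation: np.ndarray
    tanimoto: float
    overlap_volume: float


def model_from_exemplar(
    exemplar: Exemplar, alpha: float = DEFAULT_ALPHA
) -> PharmacophoreModel:
    """Exemplar point weights map to Gaussian heights."""
    feats = [
        PharmacophoreFeature(kind=p.chemotype, center=p.position, alpha=alpha, height=p.weight)
        for p in exemplar.points
    ]
    return PharmacophoreModel(id=exemplar.site_label, features=feats, source="EXEMPLAR")


# ---------------------------------------------------------------------------
# Molecule featurization (RDKit)
# ---------------------------------------------------------------------------

def _is_amide_nitrogen(atom) -> bool:
    for nb in atom.GetNeighbors():
        if nb.GetSymbol() != "C":
            continue
        for bond in nb.GetBonds():
            other = bond.GetOtherAtom(nb)
            if other.GetSymbol() == "O" and bond.GetBondTypeAsDouble() >= 2.0:
                return True
    return False


def ensure_conformer(mol: Chem.Mol, seed: int = EMBED_SEED) -> Chem.Mol:
    """Return a molecule with one 3-D conformer (ETKDG embedding if absent)."""
    if mol.GetNumConformers() > 0:
        return mol
    molh = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(molh, params) != 0:
        raise FeaturelessMoleculeError("3-D embedding failed")
    AllChem.MMFFOptimizeMolecule(molh, maxIters=200)
    return Chem.RemoveHs(molh)


def featurize_molecule(
    mol: Chem.Mol,
    mol_id: str | None = None,
    alpha: float = DEFAULT_ALPHA,
    height: float = DEFAULT_HEIGHT,
    embed_seed: int = EMBED_SEED,
) -> PharmacophoreModel:
    """Derive donor/acceptor/hydrophobic features from a 3-D molecule.

    DONOR at each O–H / N–H heavy atom; ACCEPTOR at each N or O with an
    available lone pair (amide and quaternary nitrogens excluded);
    HYDROPHOBIC at the centroid of each all-carbon/sulfur ring and of each
    connected acyclic cluster of ≥3 apolar heavy atoms.
    """
    if mol is None or mol.GetNumHeavyAtoms() == 0:
        raise FeaturelessMoleculeError("empty molecule")
    mol = ensure_conformer(mol, seed=embed_seed)
    conf = mol.GetConformer()
    pos = conf.GetPositions()
    feats: list[PharmacophoreFeature] = []

    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        i = atom.GetIdx()
        if sym in ("N", "O"):
            if atom.GetTotalNumHs(includeNeighbors=True) >= 1:
                feats.append(
                    PharmacophoreFeature(Chemotype.DONOR, pos[i], alpha, height)
                )
            quaternary = sym == "N" and (
                atom.GetDegree() >= 4 or atom.GetFormalCharge() > 0
            )
            amide = sym == "N" and _is_amide_nitrogen(atom)
            if not (quaternary or amide):
                feats.append(
                    PharmacophoreFeature(Chemotype.ACCEPTOR, pos[i], alpha, height)
                )

    ring_info = mol.GetRingInfo()
    ring_atoms: set[int] = set()
    for ring in ring_info.AtomRings():
        ring_atoms.update(ring)
        if all(mol.GetAtomWithIdx(a).GetSymbol() in APOLAR_ELEMENTS for a in ring):
            feats.append(
                PharmacophoreFeature(
                    Chemotype.HYDROPHOBIC, pos[list(ring)].mean(axis=0), alpha, height
                )
            )

    # connected acyclic clusters of >=3 apolar heavy atoms
    apolar = [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetSymbol() in APOLAR_ELEMENTS and a.GetIdx() not in ring_atoms
    ]
    apolar_set = set(apolar)
    seen: set[int] = set()
    for start in apolar:
        if start in seen:
            continue
        stack, cluster = [start], []
        seen.add(start)
        while stack:
            a = stack.pop()
            cluster.append(a)
            for nb in mol.GetAtomWithIdx(a).GetNeighbors():
                j = nb.GetIdx()
                if j in apolar_set and j not in seen:
                    seen.add(j)
                    stack.append(j)
        if len(cluster) >= 3:
            feats.append(
                PharmacophoreFeature(
                    Chemotype.HYDROPHOBIC, pos[cluster].mean(axis=0), alpha, height
                )
            )

    if not feats:
        raise FeaturelessMoleculeError(
            f"no pharmacophore features for molecule {mol_id or Chem.MolToSmiles(mol)}"
        )
    mid = mol_id or (mol.GetProp("_Name") if mol.HasProp("_Name") else "mol")
    return PharmacophoreModel(id=mid, features=feats, source="MOLECULE")


# ---------------------------------------------------------------------------
# Overlap volume and Tanimoto
# ---------------------------------------------------------------------------

def _model_arrays(model: PharmacophoreModel):
    kinds = np.array([CHEMO_INT[f.kind] for f in model.features])
    centers = model.centers()
    alphas = np.array([f.alpha for f in model.features])
    heights = np.array([f.height for f in model.features])
    return kinds, centers, alphas, heights


CHEMO_INT = {Chemotype.HYDROPHOBIC: 0, Chemotype.DONOR: 1, Chemotype.ACCEPTOR: 2}


def _overlap(kinds_a, ca, aa, ha, kinds_b, cb, ab, hb) -> float:
    same = kinds_a[:, None] == kinds_b[None, :]
    if not same.any():
        return 0.0
    d2 = np.sum((ca[:, None, :] - cb[None, :, :]) ** 2, axis=-1)
    asum = aa[:, None] + ab[None, :]
    prod = aa[:, None] * ab[None, :]
    vol = (
        ha[:, None]
        * hb[None, :]
        * (np.pi / asum) ** 1.5
        * np.exp(-prod * d2 / asum)
    )
    return float(np.sum(vol[same]))


def gaussian_overlap(a: PharmacophoreModel, b: PharmacophoreModel) -> float:
    """Kind-matched Gaussian pair-overlap volume V_AB."""
    return _overlap(*_model_arrays(a), *_model_arrays(b))


def tanimoto(a: PharmacophoreModel, b: PharmacophoreModel) -> float:
    """Volumetric Tanimoto T = V_AB / (V_AA + V_BB − V_AB) ∈ [0, 1]."""
    arrs_a, arrs_b = _model_arrays(a), _model_arrays(b)
    vab = _overlap(*arrs_a, *arrs_b)
    vaa = _overlap(*arrs_a, *arrs_a)
    vbb = _overlap(*arrs_b, *arrs_b)
    denom = vaa + vbb - vab
    if denom <= 0:
        raise DegenerateVolumeError("degenerate overlap volumes")
    return vab / denom


# ---------------------------------------------------------------------------
# Rigid alignment
# ---------------------------------------------------------------------------

def _principal_axes(centers: np.ndarray) -> np.ndarray:
    """Right-handed principal frame of a point cloud (3×3, columns = axes)."""
    centered = centers - centers.mean(axis=0)
    cov = centered.T @ centered
    _, vecs = np.linalg.eigh(cov)
    vecs = vecs[:, ::-1]  # descending variance
    if np.linalg.det(vecs) < 0:
        vecs[:, 2] *= -1
    return vecs


def _start_poses(
    mobile: PharmacophoreModel, target: PharmacophoreModel, n_starts: int, seed: int
):
    """Deterministic principal-axes starts (4 sign flips) + seeded random rotations."""
    cm = mobile.centers().mean(axis=0)
    ct = target.centers().mean(axis=0)
    starts = []
    fm, ft = _principal_axes(mobile.centers()), _principal_axes(target.centers())
    for sx, sy in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
        flip = np.diag([sx, sy, sx * sy])  # proper rotations only
        rot = ft @ flip @ fm.T
        starts.append((rot, ct - rot @ cm))
    rng = np.random.default_rng(seed)
    for _ in range(max(0, n_starts - 4)):
        rot = Rotation.random(random_state=rng).as_matrix()
        starts.append((rot, ct - rot @ cm))
    return starts[:max(n_starts, 1)]


def _pair_tables(mobile_arrays, target_arrays):
    """Precomputed kind-matched pair tables for fast repeated evaluation."""
    kinds_m, cm, am, hm = mobile_arrays
    kinds_t, ct, at, ht = target_arrays
    ii, jj = np.nonzero(kinds_m[:, None] == kinds_t[None, :])
    asum = am[ii] + at[jj]
    gamma = am[ii] * at[jj] / asum
    k = hm[ii] * ht[jj] * (np.pi / asum) ** 1.5
    return ii, ct[jj], gamma, k


def _tanimoto_at(mobile_centers, pair_tables, vmm, vtt, rot, trans) -> float:
    ii, bj, gamma, k = pair_tables
    if ii.size == 0:
        return 0.0
    moved = mobile_centers @ rot.T + trans
    d2 = np.sum((moved[ii] - bj) ** 2, axis=1)
    vab = float(np.sum(k * np.exp(-gamma * d2)))
    denom = vmm + vtt - vab
    if denom <= 0:
        return 0.0
    return vab / denom


def _rodrigues(r: np.ndarray) -> np.ndarray:
    """Rotation matrix from a rotation vector (Rodrigues formula)."""
    theta2 = float(r @ r)
    rx = np.array([[0, -r[2], r[1]], [r[2], 0, -r[0]], [-r[1], r[0], 0]])
    if theta2 < 1e-16:
        return np.eye(3) + rx + 0.5 * (rx @ rx)
    theta = math.sqrt(theta2)
    return (
        np.eye(3)
        + (math.sin(theta) / theta) * rx
        + ((1.0 - math.cos(theta)) / theta2) * (rx @ rx)
    )


def _so3_left_jacobian(r: np.ndarray) -> np.ndarray:
    """Left Jacobian of SO(3) at rotation vector r (dR = [J_l dr]_x R)."""
    theta = np.linalg.norm(r)
    rx = np.array([[0, -r[2], r[1]], [r[2], 0, -r[0]], [-r[1], r[0], 0]])
    if theta < 1e-8:
        return np.eye(3) + 0.5 * rx + rx @ rx / 6.0
    a = (1.0 - math.cos(theta)) / theta**2
    b = (theta - math.sin(theta)) / theta**3
    return np.eye(3) + a * rx + b * (rx @ rx)


def align(
    mobile: PharmacophoreModel,
    target: PharmacophoreModel,
    n_starts: int = 20,
    seed: int = 0,
    maxiter: int = 150,
) -> AlignmentResult:
    """Maximize the volumetric Tanimoto over rigid transforms of ``mobile``.

    Multi-start local optimization over rotation vector + translation
    (L-BFGS-B with analytic gradient); never returns less than the best
    start pose.  Deterministic for a fixed seed.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    arrs_m, arrs_t = _model_arrays(mobile), _model_arrays(target)
    vmm = _overlap(*arrs_m, *arrs_m)
    vtt = _overlap(*arrs_t, *arrs_t)
    ii, bj, gamma, kk = _pair_tables(arrs_m, arrs_t)
    centers_m = arrs_m[1]
    vsum = vmm + vtt

    def objective(x):
        rot = _rodrigues(x[:3])
        return -_tanimoto_at(centers_m, (ii, bj, gamma, kk), vmm, vtt, rot, x[3:])

    def objective_and_grad(x):
        if ii.size == 0:
            return 0.0, np.zeros(6)
        rot = _rodrigues(x[:3])
        p = centers_m @ rot.T  # rotated centers, translation excluded
        pi = p[ii]
        diff = pi + x[3:] - bj
        e = np.exp(-gamma * (diff * diff).sum(axis=1))
        vab = float(kk @ e)
        denom = vsum - vab
        if denom <= 0:
            return 0.0, np.zeros(6)
        w = -2.0 * gamma * kk * e
        dv_dt = w @ diff
        # cross(p_i, diff) expanded component-wise (hot path)
        cx = pi[:, 1] * diff[:, 2] - pi[:, 2] * diff[:, 1]
        cy = pi[:, 2] * diff[:, 0] - pi[:, 0] * diff[:, 2]
        cz = pi[:, 0] * diff[:, 1] - pi[:, 1] * diff[:, 0]
        dv_dr = _so3_left_jacobian(x[:3]).T @ np.array([w @ cx, w @ cy, w @ cz])
        dt_dv = vsum / denom**2
        return -vab / denom, -dt_dv * np.concatenate([dv_dr, dv_dt])

    best = None
    for rot0, t0 in _start_poses(mobile, target, n_starts, seed):
        x0 = np.concatenate([Rotation.from_matrix(rot0).as_rotvec(), t0])
        start_val = -objective(x0)
        res = minimize(
            objective_and_grad,
            x0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-9},
        )
        cand_val, cand_x = -res.fun, res.x
        if cand_val < start_val:  # monotone-improvement guarantee
            cand_val, cand_x = start_val, x0
        if best is None or cand_val > best[0] + 1e-15:
            best = (cand_val, cand_x)

    rot = Rotation.from_rotvec(best[1][:3]).as_matrix()
    trans = best[1][3:]
    moved = mobile.transformed(rot, trans)
    vab = gaussian_overlap(moved, target)
    t = tanimoto(moved, target)
    return AlignmentResult(rotation=rot, translation=trans, tanimoto=float(t), overlap_volume=float(vab))
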