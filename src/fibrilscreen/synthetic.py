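"""Synthetic ground-truth inputs for every pipeline stage.

* ``make_groove`` emits an idealized β-sheet groove as PDB text: parallel
  strands (3.5 Å residue spacing, 4.8 Å inter-strand stacking) whose upper
  face carries planted pharmacophoric sidechains — an N–H for a donor, a
  carbonyl C=O for an acceptor, a three-carbon patch for a hydrophobe — and
  a manifest recording exact placements and the complementary ligand sites.
* ``make_library`` builds a compound set around one planted active whose
  pharmacophore features sit on the groove-complement sites, plus decoys
  with shuffled, jittered, missing or scrambled features.
* ``simulate_competition`` / ``simulate_saturation`` draw noisy radioligand
  counts from the same curve models the fitters use (multiplicative
  Gaussian noise, CV-parameterized, truncated at −3σ).

All generators are pure functions of (seed, parameters).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Geometry import Point3D

from .assays import BindingMeasurement, Condition, competition_model, saturation_model
from .chemotypes import Chemotype
from .molio import LibraryEntry
from .pose import ScoreRecord
from .structure import FibrilStructure, PocketSpec

RESIDUE_SPACING = 3.5  # Å along the strand
STRAND_SPACING = 4.8  # Å between stacked strands
WALL_RISE = 2.5  # Å of elevation per strand away from the central one

#: complementary ligand chemotype opposite each planted protein feature
COMPLEMENT = {
    "donor": Chemotype.ACCEPTOR,
    "acceptor": Chemotype.DONOR,
    "hydrophobe": Chemotype.HYDROPHOBIC,
}


class GrooveGenerationError(ValueError):
    pass


@dataclass
class PlantedFeature:
    kind: str  # donor | acceptor | hydrophobe
    residue: int
    position: np.ndarray  # interaction atom (H, O, or patch centre)
    direction: np.ndarray  # interaction axis (unit)
    complement_site: np.ndarray  # ideal ligand-feature position


@dataclass
class GrooveManifest:
    seed: int
    n_strands: int
    n_residues: int
    central_chain: str
    anchor_residue: int
    pocket_residues: list[int]
    planted_features: list[PlantedFeature]
    n_atoms: int
    residues_per_chain: int
    planted_optimum_pose: tuple[np.ndarray, np.ndarray] = field(
        default_factory=lambda: (np.eye(3), np.zeros(3))
    )

    def complement_sites(self) -> list[tuple[Chemotype, np.ndarray]]:
        return [
            (COMPLEMENT[f.kind], f.complement_site) for f in self.planted_features
        ]

    def pocket_spec(self, site_label: str = "SiteS") -> PocketSpec:
        return PocketSpec(
            site_label=site_label,
            member_residues=tuple(self.pocket_residues),
            anchor_residue=self.anchor_residue,
            chain_selection=(self.central_chain,),
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "n_strands": self.n_strands,
                "n_residues": self.n_residues,
                "central_chain": self.central_chain,
                "anchor_residue": self.anchor_residue,
                "pocket_residues": self.pocket_residues,
                "n_atoms": self.n_atoms,
                "residues_per_chain": self.residues_per_chain,
                "planted_features": [
                    {
                        "kind": f.kind,
                        "residue": f.residue,
                        "position": f.position.tolist(),
                        "direction": f.direction.tolist(),
                        "complement_site": f.complement_site.tolist(),
                    }
                    for f in self.planted_features
                ],
                "planted_optimum_pose": {
                    "rotation": self.planted_optimum_pose[0].tolist(),
                    "translation": self.planted_optimum_pose[1].tolist(),
                },
            },
            indent=2,
            sort_keys=True,
        )


def _feature_offsets(n: int) -> list[int]:
    """Residue offsets around the anchor: 0, +1, −1, +2, −2, ..."""
    out, step = [], 1
    if n >= 1:
        out.append(0)
    while len(out) < n:
        out.append(step)
        if len(out) < n:
            out.append(-step)
        step += 1
    return out


#: Default planted site: a five-feature pharmacophore (typical of lead-like
#: pharmacophore models) across consecutive central-strand residues.
DEFAULT_PLANTED = ("donor", "acceptor", "hydrophobe", "acceptor", "donor")


def make_groove(
    seed: int,
    n_strands: int = 5,
    n_residues: int = 9,
    planted: tuple[str, ...] = DEFAULT_PLANTED,
) -> tuple[str, GrooveManifest]:
    """Generate the groove PDB text and its ground-truth manifest."""
    if n_strands < 3:
        raise GrooveGenerationError("need at least 3 strands")
    for kind in planted:
        if kind not in COMPLEMENT:
            raise GrooveGenerationError(f"unknown planted feature kind {kind!r}")
    if len(planted) > n_residues - 2:
        raise GrooveGenerationError("too many planted features for the strand length")

    rng = np.random.default_rng(seed)
    chains = [chr(ord("A") + s) for s in range(n_strands)]
    central_chain = chains[n_strands // 2]
    anchor_residue = n_residues // 2 + 1

    offsets = _feature_offsets(len(planted))
    # lateral stagger breaks collinearity of the planted sites so the pocket
    # geometry is asymmetric, as in a real groove
    stagger = [0.0, 1.2, -1.2, 0.6, -0.6, 1.0, -1.0]
    feature_by_residue = {
        anchor_residue + off: (kind, stagger[i % len(stagger)])
        for i, (off, kind) in enumerate(zip(offsets, planted))
    }
    if len(feature_by_residue) != len(planted):
        raise GrooveGenerationError("overlapping planted feature placement")

    atoms = []  # (chain, res_id, res_name, atom_name, element, xyz)
    features: list[PlantedFeature] = []

    for s, chain in enumerate(chains):
        y = STRAND_SPACING * s
        # strands rise away from the central one: the site is a concave
        # channel between walls, not an open face
        dz = WALL_RISE * abs(s - n_strands // 2)
        for i in range(1, n_residues + 1):
            x = RESIDUE_SPACING * (i - 1)
            planted_here = feature_by_residue.get(i) if chain == central_chain else None
            kind, dy = planted_here if planted_here else (None, 0.0)
            res_name = "ALA" if kind else "GLY"
            # N off the CA axis: strands zigzag, and the amide-H geometry
            # (bisector of N–CA and N–C(prev)) needs a non-collinear backbone
            atoms.append((chain, i, res_name, "N", "N", (x - 0.6, y + 0.35, dz)))
            atoms.append((chain, i, res_name, "CA", "C", (x, y, dz)))
            atoms.append((chain, i, res_name, "C", "C", (x + 0.8, y, dz)))
            atoms.append((chain, i, res_name, "O", "O", (x + 0.8, y, dz - 1.23)))
            # downward pseudo-carbons reach a common base depth so the fibril
            # cross-section is a solid stepped slab; the only accessible
            # region near the site is then the channel above the floor
            depth, k = dz - 1.2, 0
            while depth > -2.4 - 0.6:
                k += 1
                atoms.append((chain, i, res_name, f"CB{k}", "C", (x, y, depth)))
                depth -= 1.2
            if kind is None:
                continue
            jx, jy = rng.uniform(-0.2, 0.2, size=2)
            cx, cy = x + jx, y + dy + jy
            up = np.array([0.0, 0.0, 1.0])
            if kind == "donor":
                nd = np.array([cx, cy, 1.2])
                hd = nd + 1.01 * up
                atoms.append((chain, i, res_name, "ND", "N", tuple(nd)))
                atoms.append((chain, i, res_name, "HD", "H", tuple(hd)))
                features.append(
                    PlantedFeature(kind, i, hd, up, hd + 3.0 * up)
                )
            elif kind == "acceptor":
                cd = np.array([cx, cy, 1.0])
                od = cd + 1.23 * up
                atoms.append((chain, i, res_name, "CD", "C", tuple(cd)))
                atoms.append((chain, i, res_name, "OD", "O", tuple(od)))
                features.append(
                    PlantedFeature(kind, i, od, up, od + 3.3 * up)
                )
            else:  # hydrophobe: 3-carbon patch raised above the backbone
                centre = np.array([cx, cy, 1.5])
                for k, ang in enumerate((0.0, 2.0943951, 4.1887902)):
                    p = centre + 1.2 * np.array([np.cos(ang), np.sin(ang), 0.0])
                    atoms.append((chain, i, res_name, f"CP{k + 1}", "C", tuple(p)))
                features.append(
                    PlantedFeature(kind, i, centre, up, centre + 3.4 * up)
                )

    array = struc.AtomArray(len(atoms))
    array.coord = np.array([a[5] for a in atoms], dtype=np.float32)
    array.chain_id = np.array([a[0] for a in atoms])
    array.res_id = np.array([a[1] for a in atoms])
    array.res_name = np.array([a[2] for a in atoms])
    array.atom_name = np.array([a[3] for a in atoms])
    array.element = np.array([a[4] for a in atoms])
    array.hetero = np.zeros(len(atoms), dtype=bool)
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(array)
    pdb_text = "\n".join(pdb_file.lines) + "\n"

    pocket_residues = sorted(
        set(feature_by_residue) | {anchor_residue - 1, anchor_residue, anchor_residue + 1}
    )
    manifest = GrooveManifest(
        seed=seed,
        n_strands=n_strands,
        n_residues=n_residues,
        central_chain=central_chain,
        anchor_residue=anchor_residue,
        pocket_residues=pocket_residues,
        planted_features=features,
        n_atoms=len(atoms),
        residues_per_chain=n_residues,
    )
    return pdb_text, manifest


def groove_structure(pdb_text: str, structure_id: str = "groove") -> FibrilStructure:
    """Parse generated groove text without touching the filesystem."""
    import os
    import tempfile

    from .structure import load_pdb

    with tempfile.NamedTemporaryFile(
        "w", suffix=".pdb", delete=False
    ) as fh:
        fh.write(pdb_text)
        path = fh.name
    try:
        return load_pdb(path, structure_id=structure_id)
    finally:
        os.unlink(path)


# ---------------------------------------------------------------------------
# Library generation
# ---------------------------------------------------------------------------

def _build_site_molecule(
    sites: list[tuple[Chemotype, np.ndarray]], mol_id: str
) -> Chem.Mol:
    """Multi-fragment molecule whose features sit exactly on the given sites.

    ACCEPTOR → formaldehyde oxygen, DONOR → hydroxyl oxygen (methanol;
    carries an incidental acceptor), HYDROPHOBIC → cyclopropane centroid.
    """
    rw = Chem.RWMol()
    coords: list[np.ndarray] = []

    def add(symbol: str, position: np.ndarray) -> int:
        idx = rw.AddAtom(Chem.Atom(symbol))
        coords.append(np.asarray(position, dtype=float))
        return idx

    up = np.array([0.0, 0.0, 1.0])
    for kind, site in sites:
        site = np.asarray(site, dtype=float)
        if kind == Chemotype.ACCEPTOR:
            o = add("O", site)
            c = add("C", site + 1.22 * up)
            rw.AddBond(o, c, Chem.BondType.DOUBLE)
        elif kind == Chemotype.DONOR:
            o = add("O", site)
            c = add("C", site + 1.40 * up)
            rw.AddBond(o, c, Chem.BondType.SINGLE)
        else:  # HYDROPHOBIC: cyclopropane, C–C 1.52 Å → circumradius 0.8776
            r = 1.52 / np.sqrt(3.0)
            idxs = []
            for ang in (0.0, 2.0943951, 4.1887902):
                p = site + r * np.array([np.cos(ang), np.sin(ang), 0.0])
                idxs.append(add("C", p))
            for a, b in ((0, 1), (1, 2), (2, 0)):
                rw.AddBond(idxs[a], idxs[b], Chem.BondType.SINGLE)

    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    conf = Chem.Conformer(mol.GetNumAtoms())
    for i, p in enumerate(coords):
        conf.SetAtomPosition(i, Point3D(*p))
    mol.AddConformer(conf, assignId=True)
    mol.SetProp("_Name", mol_id)
    return mol


_DECOY_CATEGORIES = ("shuffled", "missing", "minimal")


def make_library(
    seed: int,
    n_decoys: int,
    active_sites: list[tuple[Chemotype, np.ndarray]],
) -> list[LibraryEntry]:
    """One planted active plus ``n_decoys`` structured decoys.

    Decoys preserve the site geometry but mismatch its chemistry — the
    quantity the alignment score is supposed to recognize.  Categories cycle
    deterministically: shuffled chemotypes at the true sites, one feature
    missing, and a feature-poor single-hydrophobe molecule.
    """
    if n_decoys < 1:
        raise ValueError("n_decoys must be >= 1")
    if not active_sites:
        raise ValueError("active_sites must be non-empty")
    rng = np.random.default_rng(seed)
    sites = [(Chemotype(k), np.asarray(p, dtype=float)) for k, p in active_sites]
    positions = np.array([p for _, p in sites])
    lo, hi = positions.min(axis=0) - 2.0, positions.max(axis=0) + 2.0

    entries = [
        LibraryEntry(
            id="ACT-001",
            mol=_build_site_molecule(sites, "ACT-001"),
            flags={"role": "active", "category": "active"},
        )
    ]
    kinds = [k for k, _ in sites]
    for d in range(n_decoys):
        category = _DECOY_CATEGORIES[d % len(_DECOY_CATEGORIES)]
        mol_id = f"DEC-{d + 1:03d}"
        if category == "shuffled" and len(sites) >= 2:
            shift = 1 + int(rng.integers(0, len(sites) - 1))
            decoy_sites = [
                (kinds[(i + shift) % len(kinds)], positions[i])
                for i in range(len(sites))
            ]
        elif category == "missing" and len(sites) >= 2:
            drop = int(rng.integers(0, len(sites)))
            decoy_sites = [sp for i, sp in enumerate(sites) if i != drop]
        else:  # minimal: a feature-poor molecule placed somewhere in the site box
            decoy_sites = [(Chemotype.HYDROPHOBIC, rng.uniform(lo, hi))]
        entries.append(
            LibraryEntry(
                id=mol_id,
                mol=_build_site_molecule(decoy_sites, mol_id),
                flags={"role": "decoy", "category": category},
            )
        )
    return entries


# ---------------------------------------------------------------------------
# Assay simulation
# ---------------------------------------------------------------------------

@dataclass
class AssayTruth:
    """Ground truth for one simulated assay dataset."""

    compound_id: str
    site_label: str
    seed: int
    true_log_ic50: float | None = None  # log10 molar (competition)
    true_kd: float | None = None  # molar (saturation)
    top: float = 2000.0  # CPM
    bottom: float = 200.0  # CPM
    bmax: float = 1000.0  # CPM
    ns_slope: float | None = None  # CPM per molar; default 1% Bmax per nM
    noise_cv: float = 0.05
    n_replicates: int = 3
    concentrations: np.ndarray | None = None  # molar

    def __post_init__(self):
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.ns_slope is None:
            self.ns_slope = 0.01 * self.bmax * 1e9


DEFAULT_COMPETITION_CONC = np.logspace(-11, -5, 12)  # 10 pM – 10 µM
DEFAULT_SATURATION_CONC = np.logspace(np.log10(0.1e-9), np.log10(30e-9), 8)


def _noise_factor(rng: np.random.Generator, cv: float) -> float:
    if cv == 0:
        return 1.0
    return 1.0 + max(rng.normal(0.0, cv), -3.0 * cv)


def simulate_competition(truth: AssayTruth) -> list[BindingMeasurement]:
    """Noisy one-site competition dataset with TOTAL and NONSPECIFIC controls."""
    if truth.true_log_ic50 is None:
        raise ValueError("truth.true_log_ic50 is required")
    conc = (
        np.asarray(truth.concentrations)
        if truth.concentrations is not None
        else DEFAULT_COMPETITION_CONC
    )
    span = np.log10(conc.max()) - np.log10(conc.min())
    if span < 2.0:
        raise ValueError("concentrations must span >= 2 log units")
    rng = np.random.default_rng(truth.seed)
    out = []
    for x in conc:
        expected = competition_model(x, truth.top, truth.bottom, truth.true_log_ic50)
        for rep in range(1, truth.n_replicates + 1):
            out.append(
                BindingMeasurement(
                    compound_id=truth.compound_id,
                    site_label=truth.site_label,
                    x=float(x),
                    counts=float(expected * _noise_factor(rng, truth.noise_cv)),
                    replicate=rep,
                    condition=Condition.SAMPLE,
                )
            )
    for rep in range(1, truth.n_replicates + 1):
        out.append(
            BindingMeasurement(
                compound_id=truth.compound_id,
                site_label=truth.site_label,
                x=0.0,
                counts=float(truth.top * _noise_factor(rng, truth.noise_cv)),
                replicate=rep,
                condition=Condition.TOTAL,
            )
        )
        out.append(
            BindingMeasurement(
                compound_id=truth.compound_id,
                site_label=truth.site_label,
                x=0.0,
                counts=float(truth.bottom * _noise_factor(rng, truth.noise_cv)),
                replicate=rep,
                condition=Condition.NONSPECIFIC,
            )
        )
    return out


def simulate_saturation(truth: AssayTruth) -> list[BindingMeasurement]:
    """Noisy saturation dataset: TOTAL = hyperbola + linear nonspecific term."""
    if truth.true_kd is None:
        raise ValueError("truth.true_kd is required")
    conc = (
        np.asarray(truth.concentrations)
        if truth.concentrations is not None
        else DEFAULT_SATURATION_CONC
    )
    rng = np.random.default_rng(truth.seed)
    log_kd = np.log10(truth.true_kd)
    out = []
    for x in conc:
        specific = saturation_model(x, truth.bmax, log_kd)
        nonspecific = truth.ns_slope * x
        for rep in range(1, truth.n_replicates + 1):
            out.append(
                BindingMeasurement(
                    compound_id=truth.compound_id,
                    site_label=truth.site_label,
                    x=float(x),
                    counts=float(
                        (specific + nonspecific) * _noise_factor(rng, truth.noise_cv)
                    ),
                    replicate=rep,
                    condition=Condition.TOTAL,
                )
            )
            out.append(
                BindingMeasurement(
                    compound_id=truth.compound_id,
                    site_label=truth.site_label,
                    x=float(x),
                    counts=float(nonspecific * _noise_factor(rng, truth.noise_cv)),
                    replicate=rep,
                    condition=Condition.NONSPECIFIC,
                )
            )
    return out


def simulate_score_records(
    seed: int,
    ddg_exp_by_compound: dict[str, float],
    structure_id: str,
    slope: float = 1.0,
    noise_sd: float = 0.2,
    scale: float = 2.94,
    score_ref: float = -20.0,
    reference_compound: str | None = None,
) -> list[ScoreRecord]:
    """Synthetic external score table linearly related to experimental ΔΔG.

    score = score_ref + scale·(slope·ΔΔG_exp + ε); the reference compound
    (ΔΔG_exp = 0) receives no noise so that score differences to the
    reference recover slope·ΔΔG_exp + ε exactly.
    """
    rng = np.random.default_rng(seed)
    records = []
    for compound_id, ddg in sorted(ddg_exp_by_compound.items()):
        noiseless = reference_compound is not None and compound_id == reference_compound
        eps = 0.0 if noiseless else rng.normal(0.0, noise_sd)
        records.append(
            ScoreRecord(
                compound_id=compound_id,
                structure_id=structure_id,
                score=score_ref + scale * (slope * ddg + eps),
                components={},
                source="EXTERNAL",
            )
        )
    return records
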