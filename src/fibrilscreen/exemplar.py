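"""Exemplar pseudoligand generation.

An exemplar is the ideal, bond-free molecular complement of a surface pocket:
the protein is cast onto a 3-D grid, solvent-accessible grid points inside the
pocket are kept, and each point is chemotyped by the protein feature it faces
— a point opposite a protein N–H becomes a ligand-side hydrogen-bond
ACCEPTOR, a point opposite a carbonyl-type oxygen lone pair becomes a DONOR,
and a point over an apolar patch becomes HYDROPHOBIC.  The surviving points,
thinned to a minimum separation, form the pseudoligand used as the virtual
screening query.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, field

import numpy as np
from scipy import ndimage

from .chemotypes import (
    APOLAR_ELEMENTS,
    CHEMOTYPE_PRIORITY,
    Chemotype,
    POLAR_ELEMENTS,
    vdw_radius,
)
from .structure import (
    AtomRecord,
    FibrilStructure,
    PocketSpec,
    add_backbone_amide_hydrogens,
    anchor_centroid,
    select_pocket,
)


class EmptyPocketError(ValueError):
    """No accessible grid point found near the anchor."""


@dataclass(frozen=True)
class Grid:
    origin: np.ndarray
    spacing: float
    dims: tuple[int, int, int]

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if any(d < 1 for d in self.dims):
            raise ValueError("grid dims must each be >= 1")
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))

    def points(self) -> np.ndarray:
        """All grid-point coordinates, lexicographic (i, j, k) order."""
        axes = [self.origin[a] + self.spacing * np.arange(self.dims[a]) for a in range(3)]
        mesh = np.meshgrid(*axes, indexing="ij")
        return np.stack([m.ravel() for m in mesh], axis=1)


@dataclass(frozen=True)
class ChemotypePoint:
    position: np.ndarray
    chemotype: Chemotype
    weight: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        if self.weight <= 0:
            raise ValueError("weight must be positive")


@dataclass
class Exemplar:
    site_label: str
    points: list[ChemotypePoint]
    source_structure: str
    anchor_residue: int

    def __post_init__(self):
        if not self.points:
            raise ValueError("exemplar must contain at least one point")

    def positions(self) -> np.ndarray:
        return np.array([p.position for p in self.points])


@dataclass(frozen=True)
class ExemplarParams:
    """Geometry thresholds for grid casting and chemotyping (Å, degrees).

    Defaults follow standard hydrogen-bond geometry and solvent-probe
    conventions; every value is overridable.
    """

    spacing: float = 0.75
    margin: float = 3.5
    probe_radius: float = 1.4
    d_hb_min: float = 2.5
    d_hb_max: float = 3.5
    angle_tol_deg: float = 45.0
    d_phob: float = 4.5
    d_polar_excl: float = 3.5
    n_apolar: int = 3
    min_separation: float = 1.5
    max_pocket_radius: float = 12.0

    def __post_init__(self):
        if not 0.1 < self.spacing <= 2.0:
            raise ValueError("spacing must be in (0.1, 2.0] Å")
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be positive")


def cast_grid(pocket_atoms: list[AtomRecord], spacing: float, margin: float) -> Grid:
    """Axis-aligned grid box: pocket bounding box expanded by ``margin``."""
    if not pocket_atoms:
        raise ValueError("cannot cast a grid around an empty atom list")
    if not 0.1 < spacing <= 2.0:
        raise ValueError("spacing must be in (0.1, 2.0] Å")
    coords = np.array([a.position for a in pocket_atoms])
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    extent = hi - lo
    dims = tuple(int(math.ceil(e / spacing)) + 1 for e in extent)
    return Grid(origin=lo, spacing=spacing, dims=dims)


def _occupancy_mask(grid: Grid, atoms: list[AtomRecord], probe_radius: float) -> np.ndarray:
    """Boolean (i,j,k) mask of grid points inside any inflated vdW sphere."""
    occupied = np.zeros(grid.dims, dtype=bool)
    spacing = grid.spacing
    dims = np.array(grid.dims)
    for atom in atoms:
        r = vdw_radius(atom.element) + probe_radius
        rel = (atom.position - grid.origin) / spacing
        lo = np.maximum(np.ceil(rel - r / spacing).astype(int), 0)
        hi = np.minimum(np.floor(rel + r / spacing).astype(int), dims - 1)
        if np.any(lo > hi):
            continue
        ii, jj, kk = np.meshgrid(
            np.arange(lo[0], hi[0] + 1),
            np.arange(lo[1], hi[1] + 1),
            np.arange(lo[2], hi[2] + 1),
            indexing="ij",
        )
        pts = np.stack([ii, jj, kk], axis=-1) * spacing + grid.origin
        d2 = np.sum((pts - atom.position) ** 2, axis=-1)
        inside = d2 <= r * r
        occupied[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] |= inside
    return occupied


def find_pocket_points(
    grid: Grid,
    structure_atoms: list[AtomRecord],
    anchor_centroid: np.ndarray,
    probe_radius: float,
    max_radius: float,
) -> np.ndarray:
    """Accessible pocket grid points (N×3), lexicographic index order.

    A point is accepted when it is (a) outside every vdW sphere inflated by
    the probe radius, (b) within ``max_radius`` of the anchor centroid, and
    (c) 6-neighbour connected, through accepted points, to the accepted point
    nearest the anchor centroid.
    """
    if probe_radius <= 0:
        raise ValueError("probe_radius must be positive")
    anchor = np.asarray(anchor_centroid, dtype=float)
    occupied = _occupancy_mask(grid, structure_atoms, probe_radius)

    pts = grid.points().reshape(*grid.dims, 3)
    within = np.sum((pts - anchor) ** 2, axis=-1) <= max_radius * max_radius
    accepted = (~occupied) & within
    if not accepted.any():
        raise EmptyPocketError("no accessible grid point within reach of the anchor")

    idx = np.argwhere(accepted)
    d2 = np.sum((idx * grid.spacing + grid.origin - anchor) ** 2, axis=1)
    seed = tuple(idx[np.argmin(d2)])

    structure6 = ndimage.generate_binary_structure(3, 1)  # face connectivity
    labels, _ = ndimage.label(accepted, structure=structure6)
    component = labels == labels[seed]
    out_idx = np.argwhere(component)  # lexicographic (i, j, k)
    return out_idx * grid.spacing + grid.origin


@dataclass
class _PolarFrames:
    """Precomputed interaction geometry of a structure.

    donor_h / donor_axis: polar hydrogen positions and heavy→H unit vectors;
    acceptor_o / acceptor_axis: acceptor oxygens and lone-pair directions
    (heavy-neighbour→O unit vector); apolar / polar: heavy-atom coordinates.
    """

    donor_h: np.ndarray
    donor_axis: np.ndarray
    acceptor_o: np.ndarray
    acceptor_axis: np.ndarray
    apolar: np.ndarray
    polar: np.ndarray


def _empty3() -> np.ndarray:
    return np.zeros((0, 3))


def polar_frames(atoms: list[AtomRecord]) -> _PolarFrames:
    coords = np.array([a.position for a in atoms])
    elements = [a.element.upper() for a in atoms]
    heavy = [i for i, e in enumerate(elements) if e != "H"]
    polar_idx = [i for i in heavy if elements[i] in POLAR_ELEMENTS]
    apolar_idx = [i for i in heavy if elements[i] in APOLAR_ELEMENTS]

    donor_h, donor_axis = [], []
    for i, e in enumerate(elements):
        if e != "H":
            continue
        if not polar_idx:
            continue
        d = np.linalg.norm(coords[polar_idx] - coords[i], axis=1)
        j = int(np.argmin(d))
        if d[j] < 1.3:  # H covalently bound to N/O: a donor hydrogen
            axis = coords[i] - coords[polar_idx[j]]
            donor_h.append(coords[i])
            donor_axis.append(axis / np.linalg.norm(axis))

    acceptor_o, acceptor_axis = [], []
    heavy_coords = coords[heavy] if heavy else _empty3()
    for i, e in enumerate(elements):
        if e != "O":
            continue
        d = np.linalg.norm(heavy_coords - coords[i], axis=1)
        d[d < 1e-6] = np.inf  # self
        j = int(np.argmin(d))
        if np.isfinite(d[j]) and d[j] < 1.8:  # attached heavy atom found
            axis = coords[i] - heavy_coords[j]
            acceptor_o.append(coords[i])
            acceptor_axis.append(axis / np.linalg.norm(axis))

    return _PolarFrames(
        donor_h=np.array(donor_h) if donor_h else _empty3(),
        donor_axis=np.array(donor_axis) if donor_axis else _empty3(),
        acceptor_o=np.array(acceptor_o) if acceptor_o else _empty3(),
        acceptor_axis=np.array(acceptor_axis) if acceptor_axis else _empty3(),
        apolar=coords[apolar_idx] if apolar_idx else _empty3(),
        polar=coords[polar_idx] if polar_idx else _empty3(),
    )


def _directional_match(
    point: np.ndarray,
    centers: np.ndarray,
    axes: np.ndarray,
    params: ExemplarParams,
) -> float | None:
    """Smallest in-window, in-cone distance from point to any center, or None."""
    if centers.shape[0] == 0:
        return None
    vec = point - centers
    dist = np.linalg.norm(vec, axis=1)
    ok = (dist >= params.d_hb_min) & (dist <= params.d_hb_max)
    if not ok.any():
        return None
    cosang = np.einsum("ij,ij->i", vec, axes) / np.where(dist > 0, dist, np.inf)
    cos_tol = math.cos(math.radians(params.angle_tol_deg))
    ok &= cosang >= cos_tol
    if not ok.any():
        return None
    return float(dist[ok].min())


def chemotype_point(
    point,
    structure_atoms: list[AtomRecord] | _PolarFrames,
    rules: ExemplarParams | None = None,
) -> Chemotype | None:
    """Chemotype of one accessible grid point, or None.

    ACCEPTOR opposite a protein donor H (distance window along the N→H
    axis), DONOR opposite a protein acceptor-oxygen lone pair, HYDROPHOBIC
    over an apolar patch with no nearby polar heavy atom.  Polar chemotypes
    take priority over hydrophobic; a donor/acceptor conflict is resolved by
    the closer interaction partner (donor wins exact ties).
    """
    params = rules or ExemplarParams()
    frames = (
        structure_atoms
        if isinstance(structure_atoms, _PolarFrames)
        else polar_frames(structure_atoms)
    )
    p = np.asarray(point, dtype=float)

    d_acc = _directional_match(p, frames.donor_h, frames.donor_axis, params)
    d_don = _directional_match(p, frames.acceptor_o, frames.acceptor_axis, params)
    if d_don is not None and (d_acc is None or d_don <= d_acc):
        return Chemotype.DONOR
    if d_acc is not None:
        return Chemotype.ACCEPTOR

    if frames.apolar.shape[0]:
        n_close = int(
            np.sum(np.linalg.norm(frames.apolar - p, axis=1) <= params.d_phob)
        )
    else:
        n_close = 0
    polar_near = (
        frames.polar.shape[0] > 0
        and bool(np.any(np.linalg.norm(frames.polar - p, axis=1) <= params.d_polar_excl))
    )
    if n_close >= params.n_apolar and not polar_near:
        return Chemotype.HYDROPHOBIC
    return None


def thin_points(points: list[ChemotypePoint], min_separation: float) -> list[ChemotypePoint]:
    """Greedy thinning: visit points by (chemotype priority, index); keep a
    point only if it is at least ``min_separation`` from every kept point."""
    order = sorted(
        range(len(points)),
        key=lambda i: (CHEMOTYPE_PRIORITY[points[i].chemotype], i),
    )
    kept: list[int] = []
    kept_pos = _empty3()
    for i in order:
        p = points[i].position
        if kept_pos.shape[0] and np.min(np.linalg.norm(kept_pos - p, axis=1)) < min_separation:
            continue
        kept.append(i)
        kept_pos = np.vstack([kept_pos, p[None, :]])
    return [points[i] for i in sorted(kept)]


def build_exemplar(
    structure: FibrilStructure,
    spec: PocketSpec,
    params: ExemplarParams | None = None,
) -> Exemplar:
    """Full pipeline: grid → accessible pocket points → chemotypes → thinning."""
    params = params or ExemplarParams()
    has_h = any(a.element.upper() == "H" for a in structure.atoms)
    if not has_h:
        structure = add_backbone_amide_hydrogens(structure)
    pocket_atoms = select_pocket(structure, spec)
    anchor = anchor_centroid(structure, spec)
    grid = cast_grid(pocket_atoms, params.spacing, params.margin)
    pocket_points = find_pocket_points(
        grid, structure.atoms, anchor, params.probe_radius, params.max_pocket_radius
    )
    frames = polar_frames(structure.atoms)
    typed = []
    for pos in pocket_points:
        kind = chemotype_point(pos, frames, params)
        if kind is not None:
            typed.append(ChemotypePoint(position=pos, chemotype=kind))
    if not typed:
        raise EmptyPocketError(
            f"no chemotypable point in pocket {spec.site_label!r}"
        )
    thinned = thin_points(typed, params.min_separation)
    return Exemplar(
        site_label=spec.site_label,
        points=thinned,
        source_structure=structure.id,
        anchor_residue=spec.anchor_residue,
    )


# ---------------------------------------------------------------------------
# Serialization: plain-text pharmacophore format, JSON sidecar, pseudo-PDB
# ---------------------------------------------------------------------------

def exemplar_to_text(exemplar: Exemplar) -> str:
    """One point per line: ``CHEMOTYPE x y z weight``."""
    lines = [
        f"# exemplar {exemplar.site_label} source={exemplar.source_structure}"
        f" anchor={exemplar.anchor_residue}"
    ]
    for p in exemplar.points:
        x, y, z = p.position
        lines.append(f"{p.chemotype.value} {x:.4f} {y:.4f} {z:.4f} {p.weight:.4f}")
    return "\n".join(lines) + "\n"


def exemplar_from_text(text: str) -> Exemplar:
    site, source, anchor = "site", "unknown", 0
    points = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            tokens = line[1:].split()
            if len(tokens) >= 2 and tokens[0] == "exemplar":
                site = tokens[1]
                for tok in tokens[2:]:
                    if tok.startswith("source="):
                        source = tok.split("=", 1)[1]
                    elif tok.startswith("anchor="):
                        anchor = int(tok.split("=", 1)[1])
            continue
        kind, x, y, z, w = line.split()
        points.append(
            ChemotypePoint(
                position=np.array([float(x), float(y), float(z)]),
                chemotype=Chemotype(kind),
                weight=float(w),
            )
        )
    return Exemplar(
        site_label=site, points=points, source_structure=source, anchor_residue=anchor
    )


def params_to_json(params: ExemplarParams) -> str:
    return json.dumps(asdict(params), indent=2, sort_keys=True)


_CHEMOTYPE_ELEMENT = {
    Chemotype.HYDROPHOBIC: "C",
    Chemotype.DONOR: "N",
    Chemotype.ACCEPTOR: "O",
}


def exemplar_to_pdb(exemplar: Exemplar) -> str:
    """Pseudo-PDB for visualization: one HETATM per point, element by chemotype."""
    lines = []
    for i, p in enumerate(exemplar.points, start=1):
        e = _CHEMOTYPE_ELEMENT[p.chemotype]
        x, y, z = p.position
        lines.append(
            f"HETATM{i:5d} {e:<4s}EXM X{i:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {e:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"
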