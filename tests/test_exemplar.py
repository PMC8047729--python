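"""Grid casting, pocket-point detection, chemotyping and exemplar assembly."""

import math

import numpy as np
import pytest

from fibrilscreen.chemotypes import Chemotype, vdw_radius
from fibrilscreen.exemplar import (
    ChemotypePoint,
    EmptyPocketError,
    ExemplarParams,
    build_exemplar,
    cast_grid,
    chemotype_point,
    exemplar_from_text,
    exemplar_to_text,
    find_pocket_points,
    thin_points,
)
from fibrilscreen.structure import AtomRecord, select_pocket

from conftest import rigid_motion


def atom(element, x, y, z, name=None, serial=1, resi=1, chain="A"):
    return AtomRecord(
        serial=serial,
        name=name or element,
        element=element,
        residue_number=resi,
        residue_name="GLY",
        chain_id=chain,
        position=np.array([x, y, z], dtype=float),
    )


class TestCastGrid:
    def test_single_atom_box(self):
        g = cast_grid([atom("C", 0, 0, 0)], spacing=1.0, margin=3.0)
        np.testing.assert_allclose(g.origin, [-3.0, -3.0, -3.0])
        assert g.dims == (7, 7, 7)

    def test_two_atom_extent(self):
        g = cast_grid([atom("C", 0, 0, 0), atom("C", 10, 0, 0)], spacing=0.5, margin=2.0)
        assert g.dims[0] == 29  # 14 Å extent / 0.5 + 1
        np.testing.assert_allclose(g.origin, [-2.0, -2.0, -2.0])

    def test_groove_pocket_contained(self, groove_struct, groove_pocket_spec):
        pocket = select_pocket(groove_struct, groove_pocket_spec)
        g = cast_grid(pocket, spacing=0.75, margin=3.5)
        hi = g.origin + g.spacing * (np.array(g.dims) - 1)
        for a in pocket:
            assert np.all(a.position >= g.origin) and np.all(a.position <= hi)

    def test_empty_input(self):
        with pytest.raises(ValueError):
            cast_grid([], spacing=1.0, margin=1.0)


def _oracle_pocket_points(grid, atoms, anchor, probe, max_radius):
    """Independent enumerate-and-test + BFS oracle for pocket detection."""
    pts = grid.points()
    accepted = np.ones(len(pts), dtype=bool)
    for a in atoms:
        r = vdw_radius(a.element) + probe
        accepted &= np.sum((pts - a.position) ** 2, axis=1) > r * r
    accepted &= np.sum((pts - np.asarray(anchor)) ** 2, axis=1) <= max_radius**2
    if not accepted.any():
        return None
    acc_3d = accepted.reshape(grid.dims)
    idx = np.argwhere(acc_3d)
    d2 = np.sum((idx * grid.spacing + grid.origin - anchor) ** 2, axis=1)
    seed = tuple(idx[np.argmin(d2)])
    # BFS over 6-neighbours
    from collections import deque

    seen = {seed}
    queue = deque([seed])
    while queue:
        i, j, k = queue.popleft()
        for di, dj, dk in ((1,0,0),(-1,0,0),(0,1,0),(0,-1,0),(0,0,1),(0,0,-1)):
            n = (i + di, j + dj, k + dk)
            if (
                0 <= n[0] < grid.dims[0]
                and 0 <= n[1] < grid.dims[1]
                and 0 <= n[2] < grid.dims[2]
                and n not in seen
                and acc_3d[n]
            ):
                seen.add(n)
                queue.append(n)
    out = sorted(seen)
    return np.array(out) * grid.spacing + grid.origin


class TestFindPocketPoints:
    def test_open_space_no_occlusion(self):
        far_atom = atom("C", 100.0, 0.0, 0.0)
        g = cast_grid([atom("C", 0, 0, 0)], spacing=1.0, margin=6.0)
        pts = find_pocket_points(g, [far_atom], np.zeros(3), probe_radius=1.4, max_radius=5.0)
        expected = g.points()
        mask = np.sum(expected**2, axis=1) <= 25.0
        assert len(pts) == int(mask.sum())

    def test_buried_anchor_is_empty_pocket(self):
        a = atom("S", 0, 0, 0)
        g = cast_grid([a], spacing=1.0, margin=1.0)
        with pytest.raises(EmptyPocketError):
            find_pocket_points(g, [a], np.zeros(3), probe_radius=1.4, max_radius=0.5)

    def test_matches_brute_force_oracle_on_groove(self, groove_struct, groove_pocket_spec):
        from fibrilscreen.structure import add_backbone_amide_hydrogens, anchor_centroid

        structure = add_backbone_amide_hydrogens(groove_struct)
        pocket = select_pocket(structure, groove_pocket_spec)
        g = cast_grid(pocket, spacing=0.75, margin=3.5)
        assert np.prod(g.dims) <= 40**3
        anchor = anchor_centroid(structure, groove_pocket_spec)
        pts = find_pocket_points(g, structure.atoms, anchor, 1.4, 12.0)
        oracle = _oracle_pocket_points(g, structure.atoms, anchor, 1.4, 12.0)
        np.testing.assert_allclose(pts, oracle, atol=1e-12)


class TestChemotypePoint:
    def test_point_facing_carbonyl_lone_pair_is_donor(self):
        atoms = [atom("C", 0, 0, 0, name="C"), atom("O", 0, 0, 1.23, name="O", serial=2)]
        assert chemotype_point([0, 0, 4.23], atoms) is Chemotype.DONOR

    def test_point_facing_amide_hydrogen_is_acceptor(self):
        atoms = [atom("N", 0, 0, 0, name="N"), atom("H", 0, 0, 1.01, name="H", serial=2)]
        assert chemotype_point([0, 0, 4.01], atoms) is Chemotype.ACCEPTOR

    def test_apolar_cluster_is_hydrophobic(self):
        atoms = [
            atom("C", 1.0, 0, 0, serial=1),
            atom("C", -1.0, 0, 0, serial=2),
            atom("C", 0, 1.0, 0, serial=3),
            atom("C", 0, -1.0, 0, serial=4),
        ]
        assert chemotype_point([0, 0, 4.0], atoms) is Chemotype.HYDROPHOBIC

    def test_polar_exclusion_blocks_hydrophobic(self):
        atoms = [
            atom("C", 1.0, 0, 0, serial=1),
            atom("C", -1.0, 0, 0, serial=2),
            atom("C", 0, 1.0, 0, serial=3),
            atom("O", 0, -1.0, 2.0, serial=4),
        ]
        assert chemotype_point([0, 0, 4.0], atoms) is None

    def test_out_of_window_is_none(self):
        atoms = [atom("C", 0, 0, 0), atom("O", 0, 0, 1.23, serial=2)]
        assert chemotype_point([0, 0, 9.0], atoms) is None
        assert chemotype_point([0, 4.0, 1.23], atoms) is None  # off-axis

    @pytest.mark.parametrize("seed", range(3))
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        atoms = [
            atom("N", 0, 0, 0, name="N"),
            atom("H", 0, 0, 1.01, name="H", serial=2),
            atom("C", 3.0, 0, 0, serial=3),
            atom("O", 3.0, 0, 1.23, serial=4),
        ]
        points = [np.array([0, 0, 4.01]), np.array([3.0, 0, 4.43]), np.array([1.5, 2, 9.0])]
        rot, trans = rigid_motion(rng)
        moved_atoms = [
            AtomRecord(
                serial=a.serial, name=a.name, element=a.element,
                residue_number=a.residue_number, residue_name=a.residue_name,
                chain_id=a.chain_id, position=rot @ a.position + trans,
            )
            for a in atoms
        ]
        for p in points:
            assert chemotype_point(p, atoms) == chemotype_point(rot @ p + trans, moved_atoms)


class TestBuildExemplar:
    def test_complementary_points_near_planted_features(
        self, groove_exemplar, groove_manifest
    ):
        params = ExemplarParams()
        complement = {"donor": Chemotype.ACCEPTOR, "acceptor": Chemotype.DONOR,
                      "hydrophobe": Chemotype.HYDROPHOBIC}
        for feat in groove_manifest.planted_features:
            wanted = complement[feat.kind]
            near = [
                p
                for p in groove_exemplar.points
                if p.chemotype is wanted
                and np.linalg.norm(p.position - feat.complement_site) <= params.d_hb_max
            ]
            assert near, f"no {wanted} exemplar point near planted {feat.kind}"

    def test_no_point_inside_vdw(self, groove_exemplar, groove_struct):
        from fibrilscreen.structure import add_backbone_amide_hydrogens

        structure = add_backbone_amide_hydrogens(groove_struct)
        coords = np.array([a.position for a in structure.atoms])
        radii = np.array([vdw_radius(a.element) for a in structure.atoms])
        for p in groove_exemplar.points:
            d = np.linalg.norm(coords - p.position, axis=1)
            assert np.all(d > radii), "exemplar point inside a vdW sphere"

    def test_apolar_pocket_yields_only_hydrophobic(self):
        # a purely apolar plate: no donor/acceptor chemotypes can appear
        from fibrilscreen.structure import FibrilStructure, PocketSpec

        atoms = []
        serial = 0
        for i in range(5):
            for j in range(5):
                serial += 1
                atoms.append(
                    AtomRecord(
                        serial=serial, name=f"C{j+1}", element="C", residue_number=i + 1,
                        residue_name="GLY", chain_id="A",
                        position=np.array([1.6 * i, 1.6 * j, 0.0]),
                    )
                )
        structure = FibrilStructure(atoms=atoms, id="plate")
        spec = PocketSpec("plate", tuple(range(1, 6)), 3, chain_selection=("A",))
        ex = build_exemplar(structure, spec)
        assert all(p.chemotype is Chemotype.HYDROPHOBIC for p in ex.points)

    def test_min_separation_monotonicity(self, groove_struct, groove_pocket_spec):
        import dataclasses

        base = ExemplarParams()
        counts = []
        for sep in (base.min_separation, 2 * base.min_separation):
            params = dataclasses.replace(base, min_separation=sep)
            counts.append(len(build_exemplar(groove_struct, groove_pocket_spec, params).points))
        assert counts[1] <= counts[0]

    def test_pairwise_separation_invariant(self, groove_exemplar):
        pos = groove_exemplar.positions()
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= ExemplarParams().min_separation - 1e-9

    def test_deterministic(self, groove_struct, groove_pocket_spec):
        a = build_exemplar(groove_struct, groove_pocket_spec)
        b = build_exemplar(groove_struct, groove_pocket_spec)
        assert exemplar_to_text(a) == exemplar_to_text(b)

    def test_text_roundtrip(self, groove_exemplar):
        text = exemplar_to_text(groove_exemplar)
        back = exemplar_from_text(text)
        assert back.site_label == groove_exemplar.site_label
        assert len(back.points) == len(groove_exemplar.points)
        np.testing.assert_allclose(
            back.positions(), np.round(groove_exemplar.positions(), 4), atol=1e-9
        )


class TestThinning:
    def test_priority_and_index_tiebreak(self):
        pts = [
            ChemotypePoint(np.array([0.0, 0, 0]), Chemotype.HYDROPHOBIC),
            ChemotypePoint(np.array([0.5, 0, 0]), Chemotype.DONOR),
            ChemotypePoint(np.array([5.0, 0, 0]), Chemotype.ACCEPTOR),
            ChemotypePoint(np.array([5.4, 0, 0]), Chemotype.ACCEPTOR),
        ]
        kept = thin_points(pts, min_separation=1.5)
        kinds = [p.chemotype for p in kept]
        # donor beats the hydrophobic 0.5 Å away; first acceptor beats the second
        assert kinds == [Chemotype.DONOR, Chemotype.ACCEPTOR]
        assert kept[1].position[0] == 5.0
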