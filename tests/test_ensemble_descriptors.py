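"""Tests for structural-ensemble descriptors."""

import numpy as np
import pytest

import biotite.structure as struc

from flexprofiler.ensemble_descriptors import (
    DEFAULT_VDW_RADII,
    HBondCriteria,
    StructureEnsemble,
    assign_secondary_structure,
    bfactors,
    count_hbonds,
    hbond_occupancy,
    radius_of_gyration,
    sasa_shrake_rupley,
    ss_fractions,
    summarize,
    superpose_ensemble,
    superpose_kabsch,
)
from flexprofiler.synthetic_data import (
    EnsembleTruth,
    build_toy_protein,
    simulate_ensemble,
)

B_SCALE = 8.0 * np.pi ** 2  # B for isotropic per-coordinate σ: B = 8π²σ²


def _rigid_transform(rng):
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0.5, 2.5)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    rot = np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)
    return rot, rng.uniform(-20, 20, size=3)


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

class TestKabsch:
    def test_self_superposition_is_identity(self, rng):
        pts = rng.normal(size=(10, 3))
        rot, trans, rmsd = superpose_kabsch(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        assert rot == pytest.approx(np.eye(3), abs=1e-10)

    def test_rigid_copy_recovered(self, rng):
        pts = rng.normal(size=(8, 3)) * 5
        rot0, trans0 = _rigid_transform(rng)
        moved = pts @ rot0.T + trans0
        _, _, rmsd = superpose_kabsch(moved, pts)
        assert rmsd < 1e-6
        assert np.linalg.det(superpose_kabsch(moved, pts)[0]) \
            == pytest.approx(1.0)

    def test_matches_rotation_grid_oracle(self, rng):
        # exhaustive nested Euler-angle search on a 4-point toy
        ref = np.array([[0.0, 0, 0], [2, 0, 0], [0, 3, 0], [0, 0, 4]])
        mobile = ref + rng.normal(0, 0.1, size=ref.shape)
        _, _, rmsd = superpose_kabsch(mobile, ref)

        def rmsd_at(angles):
            ca, cb, cc = np.cos(angles)
            sa, sb, sc = np.sin(angles)
            rz = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]])
            ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
            rz2 = np.array([[cc, -sc, 0], [sc, cc, 0], [0, 0, 1]])
            rot = rz @ ry @ rz2
            x = (mobile - mobile.mean(0)) @ rot.T + ref.mean(0)
            return np.sqrt(np.mean(np.sum((x - ref) ** 2, axis=1)))

        # dense global sweep, then local grid refinement around the best cell
        best = np.inf
        centre = np.zeros(3)
        coarse = np.linspace(-np.pi, np.pi, 25)
        for a in coarse:
            for b in coarse:
                for c in coarse:
                    v = rmsd_at((a, b, c))
                    if v < best:
                        best, centre = v, np.array([a, b, c])
        width = coarse[1] - coarse[0]
        for _ in range(5):
            axes = [np.linspace(c - width, c + width, 11) for c in centre]
            for a in axes[0]:
                for b in axes[1]:
                    for c in axes[2]:
                        v = rmsd_at((a, b, c))
                        if v < best:
                            best, centre = v, np.array([a, b, c])
            width /= 5.0
        assert rmsd == pytest.approx(best, abs=1e-3)
        assert rmsd <= best + 1e-12

    def test_collinear_selection_rejected(self):
        line = np.outer(np.arange(5.0), [1.0, 0, 0])
        with pytest.raises(ValueError):
            superpose_kabsch(line, line)


# ---------------------------------------------------------------------------
# B-factors and Rg
# ---------------------------------------------------------------------------

class TestBFactors:
    def test_identical_models_give_zero(self, helix12):
        ens = StructureEnsemble(np.repeat(helix12.coords, 5, axis=0),
                                helix12.atom_name, helix12.element,
                                helix12.residue_id, helix12.residue_name,
                                helix12.chain_id)
        assert all(b == pytest.approx(0.0, abs=1e-12)
                   for b in bfactors(ens).values())

    def test_gaussian_fluctuation_recovered(self, helix60):
        sigma = {int(r): 0.0 for r in helix60.residue_ids}
        sigma[30] = 0.5
        ens = simulate_ensemble(EnsembleTruth(helix60, sigma=sigma,
                                              n_models=5000, seed=3))
        b = bfactors(ens)
        assert b[30] == pytest.approx(B_SCALE * 0.25, rel=0.05)

    def test_invariant_under_global_rotation(self, helix12, rng):
        ens = simulate_ensemble(EnsembleTruth(helix12, sigma=0.3,
                                              n_models=40, seed=1))
        rot, trans = _rigid_transform(rng)
        moved = StructureEnsemble(ens.coords @ rot.T + trans,
                                  ens.atom_name, ens.element,
                                  ens.residue_id, ens.residue_name,
                                  ens.chain_id)
        b0, b1 = bfactors(ens), bfactors(moved)
        for rid in b0:
            assert b1[rid] == pytest.approx(b0[rid], abs=1e-6)

    def test_estimator_spread_shrinks_with_models(self, helix12):
        sigma = {int(r): 0.0 for r in helix12.residue_ids}
        sigma[6] = 0.5
        spread = {}
        for n in (300, 3000):
            vals = [bfactors(simulate_ensemble(
                EnsembleTruth(helix12, sigma=sigma, n_models=n,
                              seed=s)))[6] for s in range(5)]
            spread[n] = np.std(vals)
        assert spread[3000] < spread[300]


class TestRadiusOfGyration:
    def test_single_atom_zero(self):
        assert radius_of_gyration(np.zeros((1, 3))) == 0.0

    def test_two_atoms_two_angstrom(self):
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert radius_of_gyration(coords) == pytest.approx(1.0)

    def test_matches_loop_oracle(self, rng):
        cloud = rng.normal(size=(100, 3)) * 4
        centre = cloud.mean(axis=0)
        oracle = np.sqrt(sum(np.sum((p - centre) ** 2) for p in cloud)
                         / len(cloud))
        assert radius_of_gyration(cloud) == pytest.approx(oracle)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            radius_of_gyration(np.empty((0, 3)))


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------

class TestSasa:
    def test_isolated_carbon_closed_form(self):
        areas, total = sasa_shrake_rupley(np.zeros((1, 3)), ["C"])
        expected = 4 * np.pi * (1.70 + 1.4) ** 2
        assert total == pytest.approx(expected, rel=0.01)

    def test_distant_atoms_fully_accessible(self):
        coords = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        areas, _ = sasa_shrake_rupley(coords, ["C", "C"])
        iso = 4 * np.pi * 3.10 ** 2
        assert areas == pytest.approx([iso, iso], rel=1e-12)

    def test_two_sphere_overlap_matches_cap_formula(self):
        # equal expanded spheres radius R at distance d bury a cap of
        # height h = R − d/2 on each: accessible = 4πR² − 2πRh
        d = 3.0
        coords = np.array([[0.0, 0, 0], [d, 0, 0]])
        areas, total = sasa_shrake_rupley(coords, ["C", "C"])
        r = 1.70 + 1.4
        expected_each = 4 * np.pi * r ** 2 - 2 * np.pi * r * (r - d / 2)
        assert areas[0] == pytest.approx(expected_each, rel=0.02)
        assert total == pytest.approx(2 * expected_each, rel=0.02)

    def test_total_is_sum_and_within_bounds(self, helix12):
        areas, total = sasa_shrake_rupley(helix12.coords[0],
                                          helix12.element)
        assert total == pytest.approx(areas.sum())
        iso = np.array([4 * np.pi * (DEFAULT_VDW_RADII[e] + 1.4) ** 2
                        for e in helix12.element])
        assert np.all(areas >= 0) and np.all(areas <= iso + 1e-9)

    def test_cross_check_against_biotite(self, helix12):
        coords = helix12.coords[0]
        arr = struc.AtomArray(len(coords))
        arr.coord = coords.astype(np.float32)
        arr.chain_id = helix12.chain_id
        arr.res_id = helix12.residue_id
        arr.res_name = helix12.residue_name
        arr.atom_name = helix12.atom_name
        arr.element = np.char.upper(helix12.element.astype("U2"))
        radii = np.array([DEFAULT_VDW_RADII[e] for e in helix12.element])
        reference = struc.sasa(arr, vdw_radii=radii, point_number=960).sum()
        _, total = sasa_shrake_rupley(coords, helix12.element)
        assert total == pytest.approx(reference, rel=0.02)

    def test_unknown_element_rejected(self):
        with pytest.raises(KeyError):
            sasa_shrake_rupley(np.zeros((1, 3)), ["Xx"])


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

def _nh_oc_system(d_no, angle_deg=180.0):
    """Minimal N-H···O=C geometry with donor-acceptor distance d_no."""
    theta = np.deg2rad(180.0 - angle_deg)
    h = np.array([1.01 * np.cos(theta), 1.01 * np.sin(theta), 0.0])
    coords = np.array([
        [0.0, 0.0, 0.0],          # N (donor, residue 2)
        h,                        # H
        [d_no, 0.0, 0.0],         # O (acceptor, residue 1)
        [d_no + 1.23, 0.0, 0.0],  # C
    ])
    return StructureEnsemble(
        coords[None], np.array(["N", "H", "O", "C"]),
        np.array(["N", "H", "O", "C"]), np.array([2, 2, 1, 1]),
        np.array(["ALA"] * 4), np.array(["A"] * 4))


class TestHBonds:
    def test_ideal_linear_geometry_counted(self):
        count, bonds = count_hbonds(_nh_oc_system(2.9))
        assert count == 1

    def test_long_distance_not_counted(self):
        assert count_hbonds(_nh_oc_system(3.5))[0] == 0

    def test_bent_geometry_not_counted(self):
        assert count_hbonds(_nh_oc_system(2.9, angle_deg=100.0))[0] == 0

    def test_matches_pair_enumeration_oracle(self, helix12):
        ens = simulate_ensemble(EnsembleTruth(helix12, sigma=0.15,
                                              n_models=3, seed=9))
        criteria = HBondCriteria()
        for m in range(3):
            xyz = ens.coords[m]
            oracle = 0
            for h in np.nonzero(ens.element == "H")[0]:
                heavy = np.nonzero(np.isin(ens.element, ("N", "O")))[0]
                dists = np.linalg.norm(xyz[heavy] - xyz[h], axis=1)
                donor = heavy[np.argmin(dists)]
                if dists.min() > 1.25:
                    continue
                for acc in heavy:
                    if ens.residue_id[acc] == ens.residue_id[donor]:
                        continue
                    d = np.linalg.norm(xyz[acc] - xyz[donor])
                    v1 = xyz[donor] - xyz[h]
                    v2 = xyz[acc] - xyz[h]
                    cosang = v1 @ v2 / (np.linalg.norm(v1)
                                        * np.linalg.norm(v2))
                    ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                    if d <= criteria.max_distance \
                            and ang >= criteria.min_angle:
                        oracle += 1
            assert count_hbonds(ens, m, criteria)[0] == oracle


class TestHBondOccupancy:
    def test_bond_present_in_all_models(self, helix12):
        ens = StructureEnsemble(np.repeat(helix12.coords, 4, axis=0),
                                helix12.atom_name, helix12.element,
                                helix12.residue_id, helix12.residue_name,
                                helix12.chain_id)
        assert hbond_occupancy(ens, (6, "N"), (2, "O")) == 1.0

    def test_constructed_fraction_exact(self, helix12):
        truth = EnsembleTruth(helix12, sigma=0.0, n_models=100, seed=0,
                              bond_break=((6, "N"), (2, "O"), 0.08))
        ens = simulate_ensemble(truth)
        assert hbond_occupancy(ens, (6, "N"), (2, "O")) == 0.92

    def test_equals_mean_of_indicator(self, helix12):
        ens = simulate_ensemble(EnsembleTruth(helix12, sigma=0.25,
                                              n_models=20, seed=4))
        per_model = [hbond_occupancy(ens.model(m), (6, "N"), (2, "O"))
                     for m in range(20)]
        assert hbond_occupancy(ens, (6, "N"), (2, "O")) \
            == pytest.approx(np.mean(per_model))

    def test_never_formed_bond_zero(self, helix12):
        assert hbond_occupancy(helix12, (12, "N"), (1, "O")) == 0.0

    def test_unresolvable_atom_rejected(self, helix12):
        with pytest.raises(KeyError):
            hbond_occupancy(helix12, (99, "N"), (2, "O"))


# ---------------------------------------------------------------------------
# secondary structure
# ---------------------------------------------------------------------------

class TestSecondaryStructure:
    def test_helix_interior_labelled_h(self, helix12):
        labels = assign_secondary_structure(helix12)
        assert all(labels[r] == "H" for r in range(3, 11))

    def test_extended_chain_all_coil(self):
        strand = build_toy_protein(8, "strand")
        assert set(assign_secondary_structure(strand).values()) == {"C"}

    def test_antiparallel_sheet_labelled_e(self):
        sheet = build_toy_protein(6, "sheet")
        labels = assign_secondary_structure(sheet)
        assert sum(1 for s in labels.values() if s == "E") >= 4

    def test_fractions_sum_to_one(self, helix12):
        fractions = ss_fractions(assign_secondary_structure(helix12))
        assert sum(fractions.values()) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# summary
# ---------------------------------------------------------------------------

class TestSummarize:
    def test_rigid_ensemble_matches_single_model(self, helix12):
        rigid = StructureEnsemble(np.repeat(helix12.coords, 3, axis=0),
                                  helix12.atom_name, helix12.element,
                                  helix12.residue_id, helix12.residue_name,
                                  helix12.chain_id)
        s_multi = summarize(rigid)
        s_single = summarize(helix12)
        assert s_multi.avg_b == pytest.approx(0.0, abs=1e-12)
        assert s_multi.sasa == pytest.approx(s_single.sasa)
        assert s_multi.n_hb == pytest.approx(s_single.n_hb)
        assert s_multi.rg == pytest.approx(s_single.rg)

    def test_fields_match_componentwise_loops(self, helix12):
        ens = simulate_ensemble(EnsembleTruth(helix12, sigma=0.2,
                                              n_models=4, seed=2))
        s = summarize(ens)
        sasa_each = [sasa_shrake_rupley(ens.coords[m], ens.element)[1]
                     for m in range(4)]
        hb_each = [count_hbonds(ens, m)[0] for m in range(4)]
        ca = ens.ca_mask()
        rg_each = [radius_of_gyration(ens.coords[m][ca]) for m in range(4)]
        assert s.sasa == pytest.approx(np.mean(sasa_each))
        assert s.n_hb == pytest.approx(np.mean(hb_each))
        assert s.rg == pytest.approx(np.mean(rg_each))
        assert sum(s.ss_fractions.values()) == pytest.approx(1.0)

    def test_invariant_under_rigid_transform(self, helix12, rng):
        ens = simulate_ensemble(EnsembleTruth(helix12, sigma=0.2,
                                              n_models=5, seed=6))
        rot, trans = _rigid_transform(rng)
        moved = StructureEnsemble(ens.coords @ rot.T + trans,
                                  ens.atom_name, ens.element,
                                  ens.residue_id, ens.residue_name,
                                  ens.chain_id)
        s0, s1 = summarize(ens), summarize(moved)
        # SASA uses a fixed sphere-point lattice, so its rotational
        # invariance is limited by the point discretisation
        assert s1.sasa == pytest.approx(s0.sasa, rel=5e-3)
        assert s1.n_hb == pytest.approx(s0.n_hb)
        assert s1.avg_b == pytest.approx(s0.avg_b, rel=1e-6)
        assert s1.rg == pytest.approx(s0.rg, rel=1e-9)

    def test_flexible_ensemble_ranks_above_rigid(self, helix12):
        rigid = simulate_ensemble(EnsembleTruth(helix12, sigma=0.05,
                                                n_models=30, seed=8))
        floppy = simulate_ensemble(EnsembleTruth(helix12, sigma=0.45,
                                                 n_models=30, seed=8))
        s_rigid = summarize(rigid, include_ss=False)
        s_floppy = summarize(floppy, include_ss=False)
        assert s_floppy.avg_b > s_rigid.avg_b
        assert s_floppy.n_hb < s_rigid.n_hb
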