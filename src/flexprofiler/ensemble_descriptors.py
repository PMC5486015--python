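"""Structural descriptors of multi-model conformational ensembles.

An ensemble is N conformers of identical topology (same atoms, same order),
the desk-scale analogue of an MD snapshot collection.  The module computes
the descriptors used to compare conformational heterogeneity between protein
variants: per-residue Cα B-factors after global superposition, radius of
gyration, Shrake-Rupley solvent-accessible surface area, geometric
intramolecular hydrogen-bond counts and per-bond occupancies, and a
simplified three-state secondary-structure assignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Bondi van der Waals radii, Å
DEFAULT_VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20}

#: water-probe radius, Å
PROBE_RADIUS = 1.4

B_FACTOR_SCALE = 8.0 * np.pi**2 / 3.0  # B = (8π²/3)·MSF

#: simplified Kabsch-Sander electrostatic H-bond energy threshold, kcal/mol
DSSP_ENERGY_CUTOFF = -0.5
_DSSP_Q = 0.084 * 332.0


# ---------------------------------------------------------------------------
# ensemble container
# ---------------------------------------------------------------------------

@dataclass
class StructureEnsemble:
    """N models × M atoms with shared topology.

    ``coords`` has shape (n_models, n_atoms, 3) in Å; the annotation arrays
    all have length n_atoms and define the shared atom ordering.
    """

    coords: np.ndarray
    atom_name: np.ndarray
    element: np.ndarray
    residue_id: np.ndarray
    residue_name: np.ndarray
    chain_id: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_models, n_atoms, 3)")
        for name in ("atom_name", "element", "residue_id", "residue_name",
                     "chain_id"):
            arr = np.asarray(getattr(self, name))
            if len(arr) != self.coords.shape[1]:
                raise ValueError(f"{name} length does not match atom count")
            setattr(self, name, arr)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def residue_ids(self) -> np.ndarray:
        """Unique residue identifiers in order of first appearance."""
        _, idx = np.unique(self.residue_id, return_index=True)
        return self.residue_id[np.sort(idx)]

    def model(self, i: int) -> "StructureEnsemble":
        return StructureEnsemble(self.coords[i:i + 1].copy(), self.atom_name,
                                 self.element, self.residue_id,
                                 self.residue_name, self.chain_id)

    def atom_index(self, residue_id: int, atom_name: str) -> int:
        hits = np.nonzero((self.residue_id == residue_id)
                          & (self.atom_name == atom_name))[0]
        if len(hits) != 1:
            raise KeyError(
                f"atom {atom_name!r} of residue {residue_id}: "
                f"{len(hits)} matches")
        return int(hits[0])

    def ca_mask(self) -> np.ndarray:
        return self.atom_name == "CA"


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond definition (AMBER-style defaults)."""

    max_distance: float = 3.0   # donor–acceptor heavy-atom distance, Å
    min_angle: float = 135.0    # donor–H–acceptor angle, degrees

    def __post_init__(self) -> None:
        if self.max_distance <= 0:
            raise ValueError("max_distance must be positive")
        if not 0 < self.min_angle <= 180:
            raise ValueError("min_angle must lie in (0, 180]")


@dataclass
class DescriptorSummary:
    """Table-style ensemble summary: means over models."""

    sasa: float                        # Å²
    n_hb: float                        # intramolecular H-bond count
    avg_b: float                       # Å²
    rg: float                          # Å
    ss_fractions: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# superposition and fluctuations
# ---------------------------------------------------------------------------

def superpose_kabsch(mobile: np.ndarray, reference: np.ndarray,
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid-body superposition of ``mobile`` onto ``reference``.

    Returns (rotation, translation, rmsd) such that
    ``mobile @ rotation.T + translation`` minimises the RMSD to
    ``reference``.  The rotation is proper (det = +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 \
            or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must both be (n, 3)")
    if len(mobile) < 3:
        raise ValueError("need at least 3 atoms for superposition")
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    x = mobile - cm
    y = reference - cr
    sv = np.linalg.svd(x, compute_uv=False)
    if sv[1] < 1e-8 * max(sv[0], 1.0):
        raise ValueError("selection is degenerate (collinear or coincident)")
    h = x.T @ y
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cr - rot @ cm
    moved = x @ rot.T + cr
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return rot, trans, rmsd


def superpose_ensemble(ensemble: StructureEnsemble,
                       reference_model: int = 0) -> StructureEnsemble:
    """Superpose every model onto the reference model using Cα atoms."""
    mask = ensemble.ca_mask()
    if mask.sum() < 3:
        raise ValueError("fewer than 3 Cα atoms available for alignment")
    ref = ensemble.coords[reference_model][mask]
    out = ensemble.coords.copy()
    for i in range(ensemble.n_models):
        rot, trans, _ = superpose_kabsch(out[i][mask], ref)
        out[i] = out[i] @ rot.T + trans
    return StructureEnsemble(out, ensemble.atom_name, ensemble.element,
                             ensemble.residue_id, ensemble.residue_name,
                             ensemble.chain_id)


def bfactors(ensemble: StructureEnsemble, reference_model: int = 0,
             superpose: bool = True) -> dict[int, float]:
    """Per-residue Cα B-factors, B = (8π²/3)·⟨|r − r̄|²⟩ after alignment.

    Residues lacking a Cα in the shared topology are excluded (and logged).
    """
    ens = superpose_ensemble(ensemble, reference_model) if superpose \
        else ensemble
    mask = ens.ca_mask()
    ca = ens.coords[:, mask, :]                    # (models, n_ca, 3)
    mean = ca.mean(axis=0)
    msf = np.mean(np.sum((ca - mean) ** 2, axis=2), axis=0)
    rids = ens.residue_id[mask]
    missing = set(ens.residue_ids.tolist()) - set(rids.tolist())
    if missing:
        logger.info("bfactors: residues without Cα excluded: %s",
                    sorted(missing))
    return {int(r): float(B_FACTOR_SCALE * m) for r, m in zip(rids, msf)}


def radius_of_gyration(coords: np.ndarray) -> float:
    """Unweighted Rg = √⟨|rᵢ − r̄|²⟩ of the supplied atom coordinates."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or len(coords) == 0:
        raise ValueError("coords must be a non-empty (n, 3) array")
    centred = coords - coords.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centred ** 2, axis=1))))


# ---------------------------------------------------------------------------
# solvent-accessible surface area
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere points (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def sasa_shrake_rupley(coords: np.ndarray, elements: Sequence[str],
                       probe: float = PROBE_RADIUS, n_points: int = 960,
                       radii: dict[str, float] | None = None
                       ) -> tuple[np.ndarray, float]:
    """Shrake-Rupley SASA: per-atom areas and their total, Å².

    Each atom is covered with ``n_points`` test points on its expanded
    sphere of radius r + probe; the accessible fraction (points not inside
    any other atom's expanded sphere) times 4π(r + probe)² is its area.
    """
    coords = np.asarray(coords, dtype=float)
    elements = np.asarray(elements)
    table = DEFAULT_VDW_RADII if radii is None else radii
    unknown = sorted({e for e in elements if e not in table})
    if unknown:
        raise KeyError(f"no van der Waals radius configured for: {unknown}")
    r = np.array([table[e] for e in elements]) + probe
    sphere = _sphere_points(n_points)
    n = len(coords)
    areas = np.empty(n)
    # pairwise neighbour lists keep the point test O(n_points · #neighbours)
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt(np.sum(diff ** 2, axis=2))
    for i in range(n):
        neigh = np.nonzero((dist[i] < r[i] + r) & (np.arange(n) != i))[0]
        pts = coords[i] + r[i] * sphere
        if len(neigh):
            d2 = np.sum((pts[:, None, :] - coords[neigh][None, :, :]) ** 2,
                        axis=2)
            buried = np.any(d2 < r[neigh][None, :] ** 2, axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * r[i] ** 2
    return areas, float(areas.sum())


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

def _donor_triplets(ensemble: StructureEnsemble, model_xyz: np.ndarray,
                    max_dh: float = 1.25) -> list[tuple[int, int]]:
    """(heavy donor, hydrogen) index pairs: H within ``max_dh`` Å of an N/O."""
    heavy = np.nonzero(np.isin(ensemble.element, ("N", "O")))[0]
    hydrogens = np.nonzero(ensemble.element == "H")[0]
    pairs = []
    for h in hydrogens:
        d = np.sqrt(np.sum((model_xyz[heavy] - model_xyz[h]) ** 2, axis=1))
        j = np.argmin(d)
        if d[j] <= max_dh:
            pairs.append((int(heavy[j]), int(h)))
    return pairs


def count_hbonds(ensemble: StructureEnsemble, model: int = 0,
                 criteria: HBondCriteria = HBondCriteria()
                 ) -> tuple[int, list[tuple[int, int, int]]]:
    """Geometric intramolecular H-bonds in one model.

    Donors are N/O atoms with a covalently attached hydrogen, acceptors are
    N/O atoms of a *different* residue.  A bond requires donor–acceptor
    heavy-atom distance ≤ ``criteria.max_distance`` and donor–H–acceptor
    angle ≥ ``criteria.min_angle``.  Each (H, acceptor) pair counts once.
    Returns (count, list of (donor, hydrogen, acceptor) atom indices).
    """
    xyz = ensemble.coords[model]
    donors = _donor_triplets(ensemble, xyz)
    if not donors and np.sum(ensemble.element == "H") == 0:
        raise ValueError("no hydrogens in topology; cannot detect H-bonds")
    acceptors = np.nonzero(np.isin(ensemble.element, ("N", "O")))[0]
    bonds = []
    cos_min = np.cos(np.deg2rad(criteria.min_angle))
    for d_idx, h_idx in donors:
        same_res = ensemble.residue_id[acceptors] \
            == ensemble.residue_id[d_idx]
        cand = acceptors[~same_res]
        dv = xyz[cand] - xyz[d_idx]
        dist = np.sqrt(np.sum(dv ** 2, axis=1))
        ok = dist <= criteria.max_distance
        if not np.any(ok):
            continue
        hv = xyz[cand[ok]] - xyz[h_idx]
        dh = xyz[d_idx] - xyz[h_idx]
        cosang = (hv @ dh) / (np.linalg.norm(hv, axis=1)
                              * np.linalg.norm(dh) + 1e-30)
        # angle ≥ min_angle  ⇔  cos(angle) ≤ cos(min_angle)
        for a_idx, c in zip(cand[ok], cosang):
            if c <= cos_min:
                bonds.append((d_idx, h_idx, int(a_idx)))
    return len(bonds), bonds


def hbond_occupancy(ensemble: StructureEnsemble,
                    donor: tuple[int, str], acceptor: tuple[int, str],
                    criteria: HBondCriteria = HBondCriteria()) -> float:
    """Fraction of models in which one specific H-bond is formed.

    ``donor`` and ``acceptor`` are (residue_id, atom_name) of the heavy
    atoms, e.g. donor (95, "N") and acceptor (92, "O") for the backbone
    92 CO – 95 NH contact.
    """
    d_idx = ensemble.atom_index(*donor)
    a_idx = ensemble.atom_index(*acceptor)
    cos_min = np.cos(np.deg2rad(criteria.min_angle))
    formed = 0
    for m in range(ensemble.n_models):
        xyz = ensemble.coords[m]
        pairs = [h for d, h in _donor_triplets(ensemble, xyz) if d == d_idx]
        hit = False
        dist = np.linalg.norm(xyz[a_idx] - xyz[d_idx])
        if dist <= criteria.max_distance:
            for h_idx in pairs:
                hv = xyz[a_idx] - xyz[h_idx]
                dh = xyz[d_idx] - xyz[h_idx]
                c = (hv @ dh) / (np.linalg.norm(hv)
                                 * np.linalg.norm(dh) + 1e-30)
                if c <= cos_min:
                    hit = True
                    break
        formed += hit
    return formed / ensemble.n_models


# ---------------------------------------------------------------------------
# secondary structure (simplified 3-state DSSP)
# ---------------------------------------------------------------------------

def _backbone_bond_matrix(ensemble: StructureEnsemble,
                          model: int) -> tuple[np.ndarray, np.ndarray]:
    """Backbone CO(i)→NH(j) H-bond matrix from the Kabsch-Sander energy.

    E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol; a bond is
    assigned when E < −0.5.  Residues missing any of N, H, C, O are inert.
    """
    xyz = ensemble.coords[model]
    rids = ensemble.residue_ids
    pos = {}
    for k, rid in enumerate(rids):
        atoms = {}
        sel = ensemble.residue_id == rid
        for name in ("N", "H", "C", "O"):
            hit = np.nonzero(sel & (ensemble.atom_name == name))[0]
            if len(hit) == 1:
                atoms[name] = xyz[hit[0]]
        pos[k] = atoms
    n = len(rids)
    bond = np.zeros((n, n), dtype=bool)
    for i in range(n):          # acceptor C=O of residue i
        if "C" not in pos[i] or "O" not in pos[i]:
            continue
        for j in range(n):      # donor N-H of residue j
            if abs(i - j) < 2:
                continue
            if "N" not in pos[j] or "H" not in pos[j]:
                continue
            r_on = np.linalg.norm(pos[i]["O"] - pos[j]["N"])
            r_ch = np.linalg.norm(pos[i]["C"] - pos[j]["H"])
            r_oh = np.linalg.norm(pos[i]["O"] - pos[j]["H"])
            r_cn = np.linalg.norm(pos[i]["C"] - pos[j]["N"])
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                continue  # clashing geometry, not a physical bond
            e = _DSSP_Q * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
            bond[i, j] = e < DSSP_ENERGY_CUTOFF
    return bond, rids


def assign_secondary_structure(ensemble: StructureEnsemble,
                               model: int = 0) -> dict[int, str]:
    """Per-residue {H, E, C} labels from backbone H-bond patterns.

    α-helix: runs of i→i+4 bonds (residues inside consecutive 4-turns);
    strand: residues in parallel or antiparallel bridges (|i − j| ≥ 3);
    everything else, including residues with incomplete backbones, is coil.
    Helix takes precedence over strand.
    """
    bond, rids = _backbone_bond_matrix(ensemble, model)
    n = len(rids)
    labels = np.full(n, "C", dtype=object)

    turn4 = np.zeros(n, dtype=bool)
    for i in range(n - 4):
        turn4[i] = bond[i, i + 4]
    # bridges
    is_e = np.zeros(n, dtype=bool)
    for i in range(n):
        for j in range(i + 3, n):
            anti = (bond[i, j] and bond[j, i]) or (
                0 <= i - 1 and j + 1 < n and 0 <= j - 1 and i + 1 < n
                and bond[i - 1, j + 1] and bond[j - 1, i + 1])
            par = (0 <= i - 1 and i + 1 < n
                   and bond[i - 1, j] and bond[j, i + 1]) or (
                0 <= j - 1 and j + 1 < n
                and bond[j - 1, i] and bond[i, j + 1])
            if anti or par:
                is_e[i] = is_e[j] = True
    labels[is_e] = "E"
    # helices override: consecutive 4-turn runs
    i = 0
    while i < n - 1:
        if turn4[i] and turn4[i + 1]:
            j = i
            while j + 1 < n and turn4[j + 1]:
                j += 1
            labels[i + 1:j + 4] = "H"
            i = j + 1
        else:
            i += 1
    return {int(r): str(label) for r, label in zip(rids, labels)}


def ss_fractions(labels: dict[int, str] | Iterable[str]) -> dict[str, float]:
    values = list(labels.values()) if isinstance(labels, dict) else list(labels)
    if not values:
        raise ValueError("no residues to summarise")
    n = len(values)
    return {s: values.count(s) / n for s in ("H", "E", "C")}


# ---------------------------------------------------------------------------
# summary
# ---------------------------------------------------------------------------

def summarize(ensemble: StructureEnsemble,
              criteria: HBondCriteria = HBondCriteria(),
              sasa_points: int = 960,
              include_ss: bool = True) -> DescriptorSummary:
    """Ensemble means of SASA, H-bond count, Cα Rg, avg B and SS content."""
    ca = ensemble.ca_mask()
    sasa_vals, hb_vals, rg_vals = [], [], []
    ss_counts = {"H": 0.0, "E": 0.0, "C": 0.0}
    for m in range(ensemble.n_models):
        _, total = sasa_shrake_rupley(ensemble.coords[m], ensemble.element,
                                      n_points=sasa_points)
        sasa_vals.append(total)
        hb_vals.append(count_hbonds(ensemble, m, criteria)[0])
        rg_vals.append(radius_of_gyration(ensemble.coords[m][ca]))
        if include_ss:
            for s, f in ss_fractions(
                    assign_secondary_structure(ensemble, m)).items():
                ss_counts[s] += f
    b = bfactors(ensemble)
    avg_b = float(np.mean(list(b.values()))) if b else 0.0
    nm = ensemble.n_models
    fractions = {s: v / nm for s, v in ss_counts.items()} if include_ss else {}
    return DescriptorSummary(
        sasa=float(np.mean(sasa_vals)),
        n_hb=float(np.mean(hb_vals)),
        avg_b=avg_b,
        rg=float(np.mean(rg_vals)),
        ss_fractions=fractions,
    )
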