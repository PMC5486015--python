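"""Seeded synthetic inputs with known ground truth for every pipeline stage.

Three generators mirror the statistical structure of the three data
modalities the pipeline consumes:

* CPMG peak-volume tables — per-residue two-state exchange parameters are
  forward-simulated through the numerical Bloch-McConnell echo train (never
  the Carver-Richards closed form, so fits are checked against an
  independent signal path), converted to volumes I = I0·exp(−R2,eff·Trelax)
  and perturbed with Gaussian noise on R2,eff.
* HDX time series — mono-exponential decays on the SOFAST acquisition grid
  with multiplicative Gaussian noise; fast exchangers decay inside the dead
  time and come out censored.
* Coordinate ensembles — a toy backbone at ideal dihedrals, replicated with
  per-residue isotropic Gaussian displacements, per-model rigid-body jitter
  and, optionally, a chosen fraction of models with one hydrogen bond
  deliberately broken.

Every generator is a pure function of its truth object; the truth carries
the seed and doubles as the ground-truth manifest for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ensemble_descriptors import StructureEnsemble, count_hbonds
from .relaxation_dispersion import (
    CpmgExperiment,
    TwoStateExchangeParams,
    bloch_mcconnell_r2eff,
)

#: standard constant-time CPMG pulse-count grid: 33–933 Hz at Trelax = 30 ms,
#: with the 67 Hz and 600 Hz points measured twice
DEFAULT_PULSE_COUNTS = (2, 4, 4, 6, 8, 10, 12, 16, 20, 24, 28, 32, 36, 36,
                        40, 44, 48, 56)

DEFAULT_HDX_SPACING_S = 510.0       # one SOFAST spectrum
DEFAULT_HDX_DEAD_TIME_S = 510.0     # mixing to mid-first-spectrum


# ---------------------------------------------------------------------------
# CPMG
# ---------------------------------------------------------------------------

@dataclass
class CpmgTruth:
    """Ground truth for a synthetic dispersion data set."""

    residues: Mapping[int, TwoStateExchangeParams]
    experiment: CpmgExperiment = None  # type: ignore[assignment]
    sigma_r2eff: float = 0.2           # Gaussian noise on R2,eff, s⁻¹
    i0: float = 1.0e6                  # reference partial peak volume
    seed: int = 0

    def __post_init__(self) -> None:
        if self.experiment is None:
            t_relax = 0.030
            grid = tuple(n / (2.0 * t_relax) for n in DEFAULT_PULSE_COUNTS)
            self.experiment = CpmgExperiment(t_relax=t_relax,
                                             nu_cpmg_list=grid)
        if self.sigma_r2eff < 0:
            raise ValueError("sigma_r2eff must be non-negative")

    def manifest(self) -> dict:
        return {
            "kind": "cpmg",
            "seed": self.seed,
            "sigma_r2eff": self.sigma_r2eff,
            "i0": self.i0,
            "t_relax": self.experiment.t_relax,
            "nu0_15n": self.experiment.nu0_15n,
            "nu_cpmg": list(self.experiment.nu_cpmg_list),
            "residues": {str(r): asdict(p) for r, p in self.residues.items()},
        }


def simulate_cpmg_volumes(truth: CpmgTruth) -> pd.DataFrame:
    """Peak-volume table for the truth's residues and frequency grid.

    Columns: residue_id, nu_cpmg (NaN on reference rows), volume, sigma.
    R2,eff comes from the Bloch-McConnell propagation with experimental
    amplitude detection; Gaussian noise of SD ``sigma_r2eff`` is applied on
    the R2,eff scale and then mapped to volumes, so repeat-frequency scatter
    reproduces the nominal noise level.
    """
    rng = np.random.default_rng(truth.seed)
    exp = truth.experiment
    rows = []
    for rid in sorted(truth.residues):
        params = truth.residues[rid]
        rows.append((rid, np.nan, truth.i0, 0.0))
        for nu in exp.nu_cpmg_list:
            r2 = bloch_mcconnell_r2eff(params, nu, exp.t_relax,
                                       detection="amplitude")
            r2_noisy = r2 + rng.normal(0.0, truth.sigma_r2eff)
            volume = truth.i0 * np.exp(-r2_noisy * exp.t_relax)
            sigma_vol = volume * truth.sigma_r2eff * exp.t_relax
            rows.append((rid, nu, volume, sigma_vol))
    return pd.DataFrame(rows, columns=["residue_id", "nu_cpmg", "volume",
                                       "sigma"])


def shared_exchange_truth(n_residues: int = 10, kex: float = 1000.0,
                          pb: float = 0.04,
                          dw_range: tuple[float, float] = (200.0, 1200.0),
                          r20_range: tuple[float, float] = (6.0, 14.0),
                          sigma_r2eff: float = 0.2,
                          seed: int = 0) -> CpmgTruth:
    """Truth with (kex, pB) shared by all residues, per-residue Δω and R2⁰."""
    rng = np.random.default_rng(seed)
    residues = {}
    for rid in range(1, n_residues + 1):
        dw = rng.uniform(*dw_range)
        r20 = rng.uniform(*r20_range)
        residues[rid] = TwoStateExchangeParams(pb, kex, dw, r20)
    return CpmgTruth(residues, sigma_r2eff=sigma_r2eff, seed=seed)


def dw_for_delta_rex(target: float, pb: float, kex: float, r20: float,
                     nu_ref: float = 1000.0) -> float:
    """Shift difference Δω (rad·s⁻¹) giving a requested ΔRex amplitude."""
    from scipy.optimize import brentq
    from .relaxation_dispersion import delta_rex

    def f(dw: float) -> float:
        return delta_rex(TwoStateExchangeParams(pb, kex, dw, r20),
                         nu_ref) - target

    # ΔRex is unimodal in Δω (large shifts move the dispersion above
    # nu_ref): solve on the rising branch up to the peak
    grid = np.geomspace(1.0, 3.0e4, 80)
    peak = grid[int(np.argmax([f(d) for d in grid]))]
    if f(peak) < 0:
        raise ValueError(f"target ΔRex = {target} unreachable at "
                         f"pb = {pb}, kex = {kex}")
    return float(brentq(f, 1.0, peak, xtol=1e-6))


def flexibility_cohort_truth(n_residues: int = 50, pb: float = 0.04,
                             kex: float = 1200.0, sigma_r2eff: float = 0.2,
                             fractions: tuple[float, float, float, float]
                             = (0.20, 0.30, 0.24, 0.26),
                             seed: int = 0) -> CpmgTruth:
    """Cohort whose ΔRex distribution emulates a highly flexible protein.

    ``fractions`` are the proportions of residues that are flat, in
    [1, 5), in [5, 10) and ≥ 10 s⁻¹ — the default reproduces a backbone
    with ~80% non-flat profiles of which 26% exceed 10 s⁻¹.  ΔRex targets
    are drawn away from the class edges so that classification of the
    noisy refits is not dominated by boundary flips.
    """
    if abs(sum(fractions)) - 1.0 > 1e-9 or any(f < 0 for f in fractions):
        raise ValueError("fractions must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    counts = [int(round(f * n_residues)) for f in fractions]
    counts[0] = n_residues - sum(counts[1:])  # absorb rounding in flat bin
    bins = [(0.0, 0.0), (1.5, 4.5), (5.5, 9.5), (12.0, 25.0)]
    residues: dict[int, TwoStateExchangeParams] = {}
    rid = 1
    for count, (lo, hi) in zip(counts, bins):
        for _ in range(count):
            r20 = rng.uniform(6.0, 14.0)
            if hi == 0.0:
                residues[rid] = TwoStateExchangeParams(0.0, 0.0, 0.0, r20)
            else:
                target = rng.uniform(lo, hi)
                dw = dw_for_delta_rex(target, pb, kex, r20)
                residues[rid] = TwoStateExchangeParams(pb, kex, dw, r20)
            rid += 1
    return CpmgTruth(residues, sigma_r2eff=sigma_r2eff, seed=seed)


# ---------------------------------------------------------------------------
# HDX
# ---------------------------------------------------------------------------

@dataclass
class HdxTruth:
    """Ground truth for synthetic amide-exchange decays."""

    residues: Mapping[int, tuple[float, float, float]]  # rid → (k_hd, A, C)
    dead_time: float = DEFAULT_HDX_DEAD_TIME_S
    spacing: float = DEFAULT_HDX_SPACING_S
    n_spectra: int = 56                                 # ≈ 8 h of SOFASTs
    relative_noise: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for rid, (k, a, c) in self.residues.items():
            if k < 0 or a < 0 or c < 0:
                raise ValueError(f"residue {rid}: k, A, C must be ≥ 0")
        if self.dead_time < 0 or self.spacing <= 0 or self.n_spectra < 1:
            raise ValueError("invalid acquisition grid")

    @property
    def times(self) -> np.ndarray:
        return self.dead_time + self.spacing * np.arange(self.n_spectra)

    def manifest(self) -> dict:
        return {
            "kind": "hdx",
            "seed": self.seed,
            "dead_time": self.dead_time,
            "spacing": self.spacing,
            "n_spectra": self.n_spectra,
            "relative_noise": self.relative_noise,
            "residues": {str(r): {"k_hd": k, "amplitude": a, "baseline": c}
                         for r, (k, a, c) in self.residues.items()},
        }


def simulate_hdx(truth: HdxTruth) -> pd.DataFrame:
    """HDX series table: residue_id, time_s, volume, sigma.

    V(t) = A·exp(−k·t) + C with multiplicative Gaussian noise
    (1 + ε, ε ~ N(0, relative_noise)); zero noise reproduces the model
    exactly.  Censoring is not decided here — it is an analysis-side call
    made against the reference volume A + C.
    """
    rng = np.random.default_rng(truth.seed)
    t = truth.times
    rows = []
    for rid in sorted(truth.residues):
        k, a, c = truth.residues[rid]
        clean = a * np.exp(-k * t) + c
        noise = rng.normal(0.0, truth.relative_noise, size=len(t)) \
            if truth.relative_noise > 0 else np.zeros(len(t))
        v = clean * (1.0 + noise)
        sig = np.maximum(clean * truth.relative_noise, 1e-12)
        for ti, vi, si in zip(t, v, sig):
            rows.append((rid, ti, vi, si))
    return pd.DataFrame(rows, columns=["residue_id", "time_s", "volume",
                                       "sigma"])


def paired_hdx_truths(n_residues: int = 12, ratio: float = 9.0,
                      k_slow_range: tuple[float, float] = (2e-5, 2e-4),
                      amplitude: float = 10.0, baseline: float = 1.0,
                      relative_noise: float = 0.02,
                      seed: int = 0) -> tuple[HdxTruth, HdxTruth]:
    """Two matched truths whose rates differ by ``ratio`` at every residue.

    Emulates a uniformly accelerated variant: protein B exchanges ``ratio``
    times faster than protein A at every matched amide.
    """
    rng = np.random.default_rng(seed)
    res_a, res_b = {}, {}
    for rid in range(1, n_residues + 1):
        k = float(np.exp(rng.uniform(np.log(k_slow_range[0]),
                                     np.log(k_slow_range[1]))))
        res_a[rid] = (k, amplitude, baseline)
        res_b[rid] = (k * ratio, amplitude, baseline)
    return (HdxTruth(res_a, relative_noise=relative_noise, seed=seed),
            HdxTruth(res_b, relative_noise=relative_noise, seed=seed + 1))


# ---------------------------------------------------------------------------
# toy backbone geometry
# ---------------------------------------------------------------------------

_BOND = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231,
         "N-H": 1.010}
_ANGLE = {"N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7, "CA-C-O": 120.5}
# helix dihedrals sit in the α basin and are chosen so that the built helix
# realises canonical 2.90 Å i→i+4 N···O hydrogen bonds with this bond set
_PHI_PSI = {"helix": (-61.0, -47.0), "strand": (-139.0, 135.0)}


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float
                ) -> np.ndarray:
    """Natural-extension (NeRF) placement of atom d bonded to c."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array([-np.cos(angle),
                               np.sin(angle) * np.cos(torsion),
                               np.sin(angle) * np.sin(torsion)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _build_chain(phi_psi: Sequence[tuple[float, float]], chain_id: str,
                 first_residue: int) -> dict[str, list]:
    """Ideal all-alanine backbone (N, H, CA, C, O) for given dihedrals."""
    n_res = len(phi_psi)
    coords: list[np.ndarray] = []
    names, elements, rids = [], [], []

    def add(name: str, element: str, rid: int, xyz: np.ndarray) -> None:
        names.append(name)
        elements.append(element)
        rids.append(rid)
        coords.append(np.asarray(xyz, dtype=float))

    # seed the first residue in the xy-plane
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_BOND["N-CA"], 0.0, 0.0])
    ang = np.deg2rad(_ANGLE["N-CA-C"])
    c0 = ca0 + _BOND["CA-C"] * np.array([-np.cos(ang), np.sin(ang), 0.0])
    positions = [{"N": n0, "CA": ca0, "C": c0}]
    for i in range(1, n_res):
        prev = positions[-1]
        psi_prev = phi_psi[i - 1][1]
        ni = _place_atom(prev["N"], prev["CA"], prev["C"],
                         _BOND["C-N"], _ANGLE["CA-C-N"], psi_prev)
        cai = _place_atom(prev["CA"], prev["C"], ni,
                          _BOND["N-CA"], _ANGLE["C-N-CA"], 180.0)  # ω trans
        ci = _place_atom(prev["C"], ni, cai,
                         _BOND["CA-C"], _ANGLE["N-CA-C"], phi_psi[i][0])
        positions.append({"N": ni, "CA": cai, "C": ci})
    for i, pos in enumerate(positions):
        rid = first_residue + i
        add("N", "N", rid, pos["N"])
        if i > 0:
            # amide H in the peptide plane, anti to both N neighbours
            u1 = pos["N"] - positions[i - 1]["C"]
            u2 = pos["N"] - pos["CA"]
            u = u1 / np.linalg.norm(u1) + u2 / np.linalg.norm(u2)
            add("H", "H", rid, pos["N"] + _BOND["N-H"] * u / np.linalg.norm(u))
        add("CA", "C", rid, pos["CA"])
        add("C", "C", rid, pos["C"])
        # carbonyl O anti to the next amide N (ψ + 180 about N-CA-C)
        psi = phi_psi[i][1]
        add("O", "O", rid, _place_atom(pos["N"], pos["CA"], pos["C"],
                                       _BOND["C-O"], _ANGLE["CA-C-O"],
                                       psi + 180.0))
    return {"coords": coords, "names": names, "elements": elements,
            "rids": rids, "chain": [chain_id] * len(names)}


def _as_ensemble(parts: Sequence[dict]) -> StructureEnsemble:
    coords = np.concatenate([np.array(p["coords"]) for p in parts])
    return StructureEnsemble(
        coords[None],
        atom_name=np.concatenate([p["names"] for p in parts]),
        element=np.concatenate([p["elements"] for p in parts]),
        residue_id=np.concatenate([p["rids"] for p in parts]).astype(int),
        residue_name=np.array(["ALA"] * len(coords)),
        chain_id=np.concatenate([p["chain"] for p in parts]),
    )


def build_toy_protein(n_residues: int, geometry: str = "helix"
                      ) -> StructureEnsemble:
    """Single-model ideal backbone: helix, strand, sheet or mixed.

    * ``helix`` — α-helical (φ, ψ) = (−57°, −47°).
    * ``strand`` — a single extended strand (−139°, 135°).
    * ``sheet`` — two antiparallel strands of n_residues each (chains A and
      B, residues continuing across the chain break), registered against
      each other by a deterministic search that maximises the inter-strand
      hydrogen-bond count.
    * ``mixed`` — a helix followed by a short coil linker and a strand.
    """
    if n_residues < 4:
        raise ValueError("need at least 4 residues")
    if geometry == "helix":
        return _as_ensemble([_build_chain([_PHI_PSI["helix"]] * n_residues,
                                          "A", 1)])
    if geometry == "strand":
        return _as_ensemble([_build_chain([_PHI_PSI["strand"]] * n_residues,
                                          "A", 1)])
    if geometry == "sheet":
        return _build_sheet(n_residues)
    if geometry == "mixed":
        n_h = max(n_residues // 2, 4)
        n_c = 2
        n_s = max(n_residues - n_h - n_c, 2)
        dihedrals = ([_PHI_PSI["helix"]] * n_h + [(-80.0, 80.0)] * n_c
                     + [_PHI_PSI["strand"]] * n_s)
        return _as_ensemble([_build_chain(dihedrals, "A", 1)])
    raise ValueError(f"unsupported geometry {geometry!r}")


def _build_sheet(n_residues: int) -> StructureEnsemble:
    a = _build_chain([_PHI_PSI["strand"]] * n_residues, "A", 1)
    b = _build_chain([_PHI_PSI["strand"]] * n_residues, "B", n_residues + 1)
    xyz_a = np.array(a["coords"])
    xyz_b0 = np.array(b["coords"])
    # flip strand B head-to-tail (180° about z), then register the two
    # strands by a deterministic grid search maximising the H-bond ladder
    flip = np.diag([-1.0, -1.0, 1.0])
    xyz_b0 = (xyz_b0 - xyz_b0.mean(axis=0)) @ flip.T
    best = None
    for dy in np.arange(3.5, 6.51, 0.25):
        for dx in np.arange(-6.0, 6.01, 0.25):
            for dz in (-0.5, 0.0, 0.5):
                cand = xyz_b0 + xyz_a.mean(axis=0) + np.array([dx, dy, dz])
                clash = np.min(np.linalg.norm(
                    xyz_a[:, None, :] - cand[None, :, :], axis=2))
                if clash < 1.8:
                    continue
                ens = _as_ensemble([a, dict(b, coords=list(cand))])
                count, _ = count_hbonds(ens)
                if best is None or count > best[0]:
                    best = (count, cand)
    if best is None or best[0] == 0:  # pragma: no cover
        raise RuntimeError("sheet registration found no hydrogen bonds")
    b["coords"] = list(best[1])
    return _as_ensemble([a, b])


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------

@dataclass
class EnsembleTruth:
    """Ground truth for a synthetic coordinate ensemble."""

    reference: StructureEnsemble
    sigma: Mapping[int, float] | float = 0.3   # per-residue (or global) σ, Å
    n_models: int = 100
    jitter_rotation_deg: float = 10.0          # rigid-body jitter amplitudes
    jitter_translation: float = 2.0
    bond_break: tuple[tuple[int, str], tuple[int, str], float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_models < 1:
            raise ValueError("n_models must be ≥ 1")
        if np.isscalar(self.sigma):
            if self.sigma < 0:
                raise ValueError("sigma must be ≥ 0")
        elif any(s < 0 for s in self.sigma.values()):
            raise ValueError("sigma must be ≥ 0")

    def sigma_for(self, residue_id: int) -> float:
        if np.isscalar(self.sigma):
            return float(self.sigma)
        return float(self.sigma.get(int(residue_id), 0.0))

    def manifest(self) -> dict:
        sigma = self.sigma if np.isscalar(self.sigma) \
            else {str(k): v for k, v in self.sigma.items()}
        return {
            "kind": "ensemble",
            "seed": self.seed,
            "n_models": self.n_models,
            "sigma": sigma,
            "jitter_rotation_deg": self.jitter_rotation_deg,
            "jitter_translation": self.jitter_translation,
            "bond_break": self.bond_break,
        }


def _random_rotation(rng: np.random.Generator, max_deg: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(-max_deg, max_deg))
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def simulate_ensemble(truth: EnsembleTruth) -> StructureEnsemble:
    """Reference + per-residue Gaussian displacement + rigid-body jitter.

    If ``bond_break = (donor, acceptor, f)`` is set, the first
    ``round(f·n_models)`` models have the donor amide (N and H) displaced
    4 Å away from the acceptor, breaking that bond in exactly that fraction
    of models (exact when f·n_models is an integer).
    """
    rng = np.random.default_rng(truth.seed)
    ref = truth.reference
    base = ref.coords[0]
    sigmas = np.array([truth.sigma_for(r) for r in ref.residue_id])
    models = np.empty((truth.n_models, ref.n_atoms, 3))
    n_broken = 0
    if truth.bond_break is not None:
        donor, acceptor, fraction = truth.bond_break
        d_idx = ref.atom_index(*donor)
        a_idx = ref.atom_index(*acceptor)
        h_idx = [i for i in np.nonzero(ref.element == "H")[0]
                 if np.linalg.norm(base[i] - base[d_idx]) < 1.25]
        away = base[d_idx] - base[a_idx]
        away = 4.0 * away / np.linalg.norm(away)
        n_broken = int(round(fraction * truth.n_models))
    for m in range(truth.n_models):
        xyz = base + rng.normal(0.0, 1.0, size=(ref.n_atoms, 3)) \
            * sigmas[:, None]
        if truth.bond_break is not None and m < n_broken:
            xyz[d_idx] = base[d_idx] + away
            for h in h_idx:
                xyz[h] = base[h] + away
        rot = _random_rotation(rng, truth.jitter_rotation_deg)
        shift = rng.uniform(-truth.jitter_translation,
                            truth.jitter_translation, size=3)
        models[m] = xyz @ rot.T + shift
    return StructureEnsemble(models, ref.atom_name, ref.element,
                             ref.residue_id, ref.residue_name, ref.chain_id)
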