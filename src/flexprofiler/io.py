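"""Readers and writers for the pipeline's file formats, plus sequence utils.

Formats: TSV tables (CPMG peak volumes, dispersion profiles, HDX series,
fit results), multi-model PDB ensembles (via biotite), FASTA sequences
(via Biopython) and JSON run manifests.  Parsers are strict: malformed
numeric fields raise with the offending line rather than being coerced.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from Bio import SeqIO

from .ensemble_descriptors import StructureEnsemble
from .hdx_exchange import HdxSeries
from .relaxation_dispersion import DispersionProfile, r2eff_from_volumes

logger = logging.getLogger(__name__)

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequencePair:
    """Two aligned, equal-length, ungapped amino-acid sequences."""

    id_a: str
    seq_a: str
    id_b: str
    seq_b: str

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError(
                f"sequence lengths differ: {len(self.seq_a)} vs "
                f"{len(self.seq_b)} (no alignment is performed)")
        for sid, seq in ((self.id_a, self.seq_a), (self.id_b, self.seq_b)):
            bad = set(seq.upper()) - AMINO_ACIDS
            if bad:
                raise ValueError(f"{sid}: non-standard residues {sorted(bad)}")


def percent_identity(pair: SequencePair) -> float:
    """100 × matching positions / length, rounded to one decimal."""
    a, b = pair.seq_a.upper(), pair.seq_b.upper()
    matches = sum(x == y for x, y in zip(a, b))
    return round(100.0 * matches / len(a), 1)


def read_fasta_pair(path: str | Path) -> SequencePair:
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise ValueError(f"{path}: expected exactly 2 records, "
                         f"got {len(records)}")
    return SequencePair(records[0].id, str(records[0].seq),
                        records[1].id, str(records[1].seq))


def write_fasta(path: str | Path, sequences: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for sid, seq in sequences.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, columns: dict[str, type],
              na_values: tuple[str, ...] = ()) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = set(columns) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        logger.warning("%s: header-only table, empty dataset", path)
    out = {}
    for col, typ in columns.items():
        raw = df[col]
        if typ is str:
            out[col] = raw
            continue
        converted = pd.to_numeric(raw.replace(list(na_values), np.nan),
                                  errors="coerce")
        bad = converted.isna() & raw.notna() & ~raw.isin(na_values)
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise ValueError(
                f"{path}: non-numeric value {raw[bad.idxmax()]!r} in column "
                f"{col!r} at line {line}")
        out[col] = converted.astype(float) if typ is float else converted
    result = pd.DataFrame(out)
    if "residue_id" in result:
        result["residue_id"] = result["residue_id"].astype(int)
    return result


def read_peak_table(path: str | Path) -> pd.DataFrame:
    """CPMG peak volumes: residue_id, nu_cpmg ('ref' rows → NaN), volume, sigma."""
    return _read_tsv(path, {"residue_id": int, "nu_cpmg": float,
                            "volume": float, "sigma": float},
                     na_values=("ref",))


def write_peak_table(path: str | Path, table: pd.DataFrame) -> None:
    out = table.copy()
    out["nu_cpmg"] = out["nu_cpmg"].map(
        lambda v: "ref" if pd.isna(v) else f"{v:.6f}")
    out.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_dispersion_table(path: str | Path) -> list[DispersionProfile]:
    df = _read_tsv(path, {"residue_id": int, "nu_cpmg": float,
                          "r2eff": float, "sigma": float})
    return [DispersionProfile(int(rid), g["nu_cpmg"].values,
                              g["r2eff"].values, g["sigma"].values)
            for rid, g in df.groupby("residue_id")]


def write_dispersion_table(path: str | Path,
                           profiles: Iterable[DispersionProfile]) -> None:
    rows = [(p.residue_id, nu, r2, s) for p in profiles
            for nu, r2, s in zip(p.nu_cpmg, p.r2eff, p.sigma)]
    pd.DataFrame(rows, columns=["residue_id", "nu_cpmg", "r2eff", "sigma"]
                 ).to_csv(path, sep="\t", index=False, float_format="%.8g")


def profiles_from_peak_table(table: pd.DataFrame, t_relax: float
                             ) -> list[DispersionProfile]:
    """Convert a peak-volume table into per-residue dispersion profiles.

    Each residue needs one reference row (nu_cpmg = NaN).  Nonpositive
    volumes are dropped with a log entry.  Per-point σ(R2,eff) is propagated
    from the volume σ; where absent (zero), it is replaced by the pooled
    standard deviation of R2,eff over repeated νCPMG values.
    """
    profiles = []
    for rid, g in table.groupby("residue_id"):
        ref = g[g["nu_cpmg"].isna()]
        if len(ref) != 1:
            raise ValueError(f"residue {rid}: expected exactly 1 reference "
                             f"row, got {len(ref)}")
        i0 = float(ref["volume"].iloc[0])
        pts = []
        for _, row in g[g["nu_cpmg"].notna()].iterrows():
            if row["volume"] <= 0:
                logger.warning("residue %s: dropping nonpositive volume at "
                               "nu_cpmg = %s Hz", rid, row["nu_cpmg"])
                continue
            r2 = r2eff_from_volumes(row["volume"], i0, t_relax)
            sig = row["sigma"] / (row["volume"] * t_relax) \
                if row["sigma"] > 0 else np.nan
            pts.append((float(row["nu_cpmg"]), r2, sig))
        if not pts:
            continue
        nu, r2, sig = (np.array(x) for x in zip(*pts))
        if np.any(np.isnan(sig)):
            pooled = _pooled_repeat_sd(nu, r2)
            sig = np.where(np.isnan(sig), pooled, sig)
        profiles.append(DispersionProfile(int(rid), nu, r2, sig))
    return profiles


def _pooled_repeat_sd(nu: np.ndarray, r2: np.ndarray) -> float:
    """Pooled SD of R2,eff over repeated νCPMG values (σ fallback)."""
    ss, dof = 0.0, 0
    for v in np.unique(nu):
        vals = r2[nu == v]
        if len(vals) > 1:
            ss += np.sum((vals - vals.mean()) ** 2)
            dof += len(vals) - 1
    if dof == 0:
        logger.warning("no repeated nu_cpmg values; assuming sigma = 0.3 s⁻¹")
        return 0.3
    return float(np.sqrt(ss / dof))


def read_hdx_table(path: str | Path) -> list[HdxSeries]:
    df = _read_tsv(path, {"residue_id": int, "time_s": float,
                          "volume": float, "sigma": float})
    out = []
    for rid, g in df.groupby("residue_id"):
        g = g.sort_values("time_s")
        out.append(HdxSeries(int(rid), g["time_s"].values,
                             g["volume"].values, g["sigma"].values))
    return out


def write_hdx_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_reference_volumes(path: str | Path) -> dict[int, float]:
    df = _read_tsv(path, {"residue_id": int, "volume": float})
    return dict(zip(df["residue_id"], df["volume"]))


def write_reference_volumes(path: str | Path,
                            refs: dict[int, float]) -> None:
    pd.DataFrame(sorted(refs.items()), columns=["residue_id", "volume"]
                 ).to_csv(path, sep="\t", index=False, float_format="%.8g")


# ---------------------------------------------------------------------------
# multi-model PDB
# ---------------------------------------------------------------------------

def _check_model_topology(path: str | Path) -> None:
    """Fail early, naming the model, when atom counts differ across models."""
    counts: list[int] = []
    current: int | None = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("MODEL"):
                current = 0
            elif line.startswith(("ATOM", "HETATM")):
                if current is None:
                    current = 0
                current += 1
            elif line.startswith("ENDMDL"):
                counts.append(current or 0)
                current = None
    if current:
        counts.append(current)
    if counts and len(set(counts)) > 1:
        bad = next(i + 1 for i, c in enumerate(counts) if c != counts[0])
        raise ValueError(
            f"{path}: model {bad} has {counts[bad - 1]} atoms, "
            f"model 1 has {counts[0]}")


def read_ensemble_pdb(path: str | Path) -> StructureEnsemble:
    _check_model_topology(path)
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    element = np.array([e.capitalize() if len(e) > 1 else e
                        for e in stack.element])
    return StructureEnsemble(
        coords=np.asarray(stack.coord, dtype=float),
        atom_name=np.asarray(stack.atom_name),
        element=element,
        residue_id=np.asarray(stack.res_id, dtype=int),
        residue_name=np.asarray(stack.res_name),
        chain_id=np.asarray(stack.chain_id),
    )


def write_ensemble_pdb(path: str | Path, ensemble: StructureEnsemble) -> None:
    n_models, n_atoms = ensemble.n_models, ensemble.n_atoms
    stack = struc.AtomArrayStack(n_models, n_atoms)
    stack.coord = np.asarray(ensemble.coords, dtype=np.float32)
    stack.chain_id = np.asarray(ensemble.chain_id, dtype="U4")
    stack.res_id = np.asarray(ensemble.residue_id, dtype=int)
    stack.res_name = np.asarray(ensemble.residue_name, dtype="U5")
    stack.atom_name = np.asarray(ensemble.atom_name, dtype="U6")
    stack.element = np.char.upper(np.asarray(ensemble.element, dtype="U2"))
    stack.hetero = np.zeros(n_atoms, dtype=bool)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def config_hash(settings: dict) -> str:
    blob = json.dumps(settings, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(path: str | Path, settings: dict, seed: int) -> dict:
    manifest = {"seed": seed, "config_hash": config_hash(settings),
                "settings": settings}
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
    return manifest


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
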