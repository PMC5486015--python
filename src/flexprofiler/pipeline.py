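"""Umbrella pipeline: simulate inputs, run each analysis stage, combine.

A ``RunConfig`` selects stages; each stage writes its own outputs plus a
JSON manifest carrying the seed and a hash of the settings, so reruns with
the same config and seed are reproducible.  The final report joins the
per-residue flexibility measures from all stages (ΔRex class, HDX rate and
censoring, Cα B-factor) into one site-resolved table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .ensemble_descriptors import HBondCriteria, bfactors, summarize
from .hdx_exchange import acceleration_factor, censor_fast, fit_decay
from .relaxation_dispersion import (
    CpmgExperiment,
    fit_global,
    fit_residue,
    flexibility_fractions,
)
from .synthetic_data import (
    CpmgTruth,
    EnsembleTruth,
    HdxTruth,
    build_toy_protein,
    paired_hdx_truths,
    shared_exchange_truth,
    simulate_cpmg_volumes,
    simulate_ensemble,
    simulate_hdx,
)

logger = logging.getLogger(__name__)

KNOWN_STAGES = ("simulate_cpmg", "fit_cpmg", "simulate_hdx", "fit_hdx",
                "simulate_ensemble", "analyze_ensemble", "report")


@dataclass
class RunConfig:
    """Stage selection and shared settings for one pipeline run."""

    stages: list[str]
    out_dir: str
    seed: int = 0
    t_relax: float = 0.030
    field_mhz: float = 800.0
    global_fit: bool = True
    n_residues: int = 10
    cpmg_sigma: float = 0.2
    hdx_ratio: float = 9.0
    hdx_noise: float = 0.02
    censor_threshold: float = 0.2
    ensemble_models: int = 200
    ensemble_sigma: float = 0.3
    hb_distance: float = 3.0
    hb_angle: float = 135.0

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("config selects no stages")
        unknown = set(self.stages) - set(KNOWN_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages in order; return the combined report.

    A stage failure propagates (halting downstream stages); outputs written
    by earlier stages remain on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    settings = asdict(config)
    report: dict = {"seed": config.seed,
                    "config_hash": fio.config_hash(settings)}
    experiment = CpmgExperiment.from_field_mhz(config.field_mhz,
                                               t_relax=config.t_relax)

    if "simulate_cpmg" in config.stages:
        truth = shared_exchange_truth(
            n_residues=config.n_residues, sigma_r2eff=config.cpmg_sigma,
            seed=config.seed)
        table = simulate_cpmg_volumes(truth)
        fio.write_peak_table(out / "cpmg_peaks.tsv", table)
        fio.write_manifest(out / "cpmg_truth.json", truth.manifest(),
                           config.seed)
        report["cpmg_truth"] = {"kex": truth.residues[1].kex,
                                "pb": truth.residues[1].pb}

    if "fit_cpmg" in config.stages:
        table = fio.read_peak_table(out / "cpmg_peaks.tsv")
        profiles = fio.profiles_from_peak_table(table, config.t_relax)
        rows = []
        if config.global_fit:
            gres = fit_global(profiles, experiment)
            fits = gres.residues
            report["cpmg_global"] = {"kex": gres.kex, "pb": gres.pb,
                                     "chi2": gres.chi2}
        else:
            fits = {p.residue_id: fit_residue(p, experiment)
                    for p in profiles}
        for rid, f in sorted(fits.items()):
            rows.append({
                "residue_id": rid, "pB": f.params.pb, "kex": f.params.kex,
                "dw_ppm": f.params.dw_ppm(experiment.nu0_15n),
                "r20": f.params.r20, "delta_rex": f.delta_rex,
                "chi2": f.chi2, "class": f.flex_class})
        df = pd.DataFrame(rows)
        df.to_csv(out / "cpmg_fits.tsv", sep="\t", index=False,
                  float_format="%.6g")
        report["cpmg_fractions"] = {
            str(k): v for k, v in flexibility_fractions(
                list(fits.values())).items()}
        report["cpmg_fits"] = df

    if "simulate_hdx" in config.stages:
        truth_a, truth_b = paired_hdx_truths(
            n_residues=config.n_residues, ratio=config.hdx_ratio,
            relative_noise=config.hdx_noise, seed=config.seed)
        for name, truth in (("a", truth_a), ("b", truth_b)):
            fio.write_hdx_table(out / f"hdx_{name}.tsv", simulate_hdx(truth))
            fio.write_manifest(out / f"hdx_truth_{name}.json",
                               truth.manifest(), config.seed)
            refs = {rid: a + c for rid, (k, a, c) in truth.residues.items()}
            fio.write_reference_volumes(out / f"hdx_ref_{name}.tsv", refs)

    if "fit_hdx" in config.stages:
        fits = {}
        for name in ("a", "b"):
            series_list = fio.read_hdx_table(out / f"hdx_{name}.tsv")
            refs = fio.read_reference_volumes(out / f"hdx_ref_{name}.tsv")
            fits[name] = {}
            for series in series_list:
                censored = censor_fast(series, refs[series.residue_id],
                                       config.censor_threshold)
                if censored:
                    fit = fit_decay(series)
                    fit.censored = True
                else:
                    fit = fit_decay(series)
                fits[name][series.residue_id] = fit
        rows = [{"residue_id": rid, "isoform": name, "k_hd": f.k_hd,
                 "amplitude": f.amplitude, "baseline": f.baseline,
                 "chi2": f.chi2, "censored": f.censored}
                for name in fits for rid, f in sorted(fits[name].items())]
        hdx_df = pd.DataFrame(rows)
        hdx_df.to_csv(out / "hdx_fits.tsv", sep="\t", index=False,
                      float_format="%.6g")
        accel = acceleration_factor(fits["a"], fits["b"])
        report["hdx_acceleration"] = {
            "median": accel.median, "iqr": accel.iqr,
            "censored_a": accel.censored_a, "censored_b": accel.censored_b,
            "lower_bound_residues": accel.lower_bound_residues}
        report["hdx_fits"] = hdx_df

    if "simulate_ensemble" in config.stages:
        rng = np.random.default_rng(config.seed)
        reference = build_toy_protein(max(config.n_residues, 12), "helix")
        sigma = {int(r): float(s) for r, s in zip(
            reference.residue_ids,
            rng.uniform(0.1, config.ensemble_sigma * 2,
                        len(reference.residue_ids)))}
        truth = EnsembleTruth(reference, sigma=sigma,
                              n_models=config.ensemble_models,
                              seed=config.seed)
        fio.write_ensemble_pdb(out / "ensemble.pdb", simulate_ensemble(truth))
        fio.write_manifest(out / "ensemble_truth.json", truth.manifest(),
                           config.seed)

    if "analyze_ensemble" in config.stages:
        ens = fio.read_ensemble_pdb(out / "ensemble.pdb")
        criteria = HBondCriteria(config.hb_distance, config.hb_angle)
        summary = summarize(ens, criteria)
        b = bfactors(ens)
        pd.DataFrame(sorted(b.items()), columns=["residue_id", "b_factor"]
                     ).to_csv(out / "bfactors.tsv", sep="\t", index=False,
                              float_format="%.6g")
        report["ensemble_summary"] = {
            "sasa": summary.sasa, "n_hb": summary.n_hb,
            "avg_b": summary.avg_b, "rg": summary.rg,
            "ss_fractions": summary.ss_fractions}
        report["bfactors"] = b

    if "report" in config.stages:
        report["site_table"] = _site_table(report, out)

    fio.write_manifest(out / "run_manifest.json", settings, config.seed)
    return report


def _site_table(report: dict, out: Path) -> pd.DataFrame:
    """Per-residue join of ΔRex class, HDX rate/censoring and B-factor."""
    frames = []
    if "cpmg_fits" in report:
        frames.append(report["cpmg_fits"][
            ["residue_id", "delta_rex", "class"]].set_index("residue_id"))
    if "hdx_fits" in report:
        hdx = report["hdx_fits"]
        sub = hdx[hdx["isoform"] == "a"][
            ["residue_id", "k_hd", "censored"]].set_index("residue_id")
        frames.append(sub)
    if "bfactors" in report:
        frames.append(pd.DataFrame.from_dict(
            report["bfactors"], orient="index", columns=["b_factor"]))
    if not frames:
        return pd.DataFrame()
    table = pd.concat(frames, axis=1)
    table.index.name = "residue_id"
    table.to_csv(out / "site_flexibility.tsv", sep="\t",
                 float_format="%.6g")
    return table
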