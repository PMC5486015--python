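"""Backbone amide hydrogen-deuterium exchange kinetics.

After dissolution in D₂O, each amide's cross-peak volume decays as the proton
is replaced by a deuteron.  Volumes sampled on a SOFAST grid (one 2D spectrum
every ~8.5 min) are fitted per residue with a mono-exponential,
V(t) = A·exp(−k_hd·t) + C, with a free plateau C: equal-volume mixing leaves
a 50% H₂O/D₂O solvent, so a residual proton population is physically
expected.  Residues whose exchange completes within the dead time before the
first spectrum are censored rather than fitted.  Acceleration of one protein
relative to another is summarised as the cohort median of per-residue rate
ratios over matched, uncensored residues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

#: one SOFAST 2D acquisition, s
SOFAST_SPECTRUM_S = 510.0

#: first-point volume below this fraction of the reference ⇒ censored
DEFAULT_CENSOR_FRACTION = 0.2


@dataclass
class HdxSeries:
    """Peak-volume decay of one backbone amide after D₂O mixing."""

    residue_id: int
    times: np.ndarray      # s since mixing, strictly increasing
    volumes: np.ndarray    # partial peak volumes, arbitrary units
    sigma: np.ndarray | float = 1.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if np.isscalar(self.sigma):
            self.sigma = np.full_like(self.times, float(self.sigma))
        else:
            self.sigma = np.asarray(self.sigma, dtype=float)
        if len(self.times) != len(self.volumes):
            raise ValueError("times and volumes must be equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class HdxFit:
    residue_id: int
    k_hd: float            # exchange rate, s⁻¹
    amplitude: float       # A, volume units
    baseline: float        # C, residual plateau
    chi2: float
    censored: bool = False
    converged: bool = True
    k_sigma: float = float("nan")


@dataclass
class AccelerationReport:
    """Per-residue k(B)/k(A) ratios and their cohort summary.

    Residues censored in B but not in A exchange faster than the slowest
    observable rate, so they bound their ratio from below and are listed in
    ``lower_bound_residues`` instead of entering the median.
    """

    ratios: dict[int, float]
    median: float
    iqr: tuple[float, float]
    censored_a: int = 0
    censored_b: int = 0
    lower_bound_residues: list[int] = field(default_factory=list)


def _decay(t: np.ndarray, a: float, k: float, c: float) -> np.ndarray:
    return a * np.exp(-k * t) + c


def fit_decay(series: HdxSeries) -> HdxFit:
    """Weighted least-squares fit of V(t) = A·exp(−k·t) + C, all ≥ 0.

    A constant series converges to the k → 0, A → 0 branch (A and C are then
    exchangeable; only A + C is determined).  A rate pinned at the upper
    bound is logged as a warning — the series is effectively censored.
    """
    if len(series.times) < 5:
        raise ValueError(
            f"residue {series.residue_id}: need ≥ 5 time points, "
            f"got {len(series.times)}")
    t, v, sig = series.times, series.volumes, series.sigma
    v0 = max(float(v[0]), 1e-12)
    vend = max(float(v[-1]), 0.0)
    # crude rate guess from the time at which the decay loses half its span
    span = v0 - vend
    k0 = 1.0 / max(float(t[-1]) / 3.0, float(t[0]), 1e-9)
    if span > 0.05 * v0:
        below = np.nonzero(v <= vend + span / 2.0)[0]
        if len(below):
            k0 = np.log(2.0) / max(float(t[below[0]]), 1e-9)
    k_hi = 10.0 / max(float(t[0]), 1e-9)
    p0 = (max(span, 1e-6 * v0), min(k0, k_hi * 0.9), vend)
    try:
        popt, pcov = curve_fit(
            _decay, t, v, p0=p0, sigma=sig, absolute_sigma=True,
            bounds=([0.0, 0.0, 0.0], [np.inf, k_hi, np.inf]), maxfev=20000)
        converged = True
    except RuntimeError:
        logger.warning("residue %d: HDX fit did not converge",
                       series.residue_id)
        popt = np.array(p0)
        pcov = np.full((3, 3), np.nan)
        converged = False
    a, k, c = (float(x) for x in popt)
    # a series with no decay over the sampled window leaves (A, k)
    # unconstrained: canonicalise to the A → 0, k = 0 branch
    model_span = a * (np.exp(-k * t[0]) - np.exp(-k * t[-1]))
    if model_span <= 1e-8 * max(v0, 1e-30):
        c = c + a * np.exp(-k * float(t[0]))
        a, k = 0.0, 0.0
    if converged and k > 0.99 * k_hi:
        logger.warning("residue %d: fitted rate at the upper bound "
                       "(%.3g s⁻¹); treat as censored", series.residue_id, k)
    chi2 = float(np.sum(((v - _decay(t, *popt)) / sig) ** 2))
    return HdxFit(series.residue_id, k, a, c, chi2, converged=converged,
                  k_sigma=float(np.sqrt(pcov[1, 1])))


def censor_fast(series: HdxSeries, reference_volume: float,
                threshold_fraction: float = DEFAULT_CENSOR_FRACTION) -> bool:
    """True when the first spectrum already lost most of the signal.

    ``reference_volume`` is the expected fully protonated volume of this
    amide (e.g. from a spectrum in H₂O); exchange completed within the dead
    time leaves a first-point volume below ``threshold_fraction`` of it.
    """
    if reference_volume is None or not np.isfinite(reference_volume) \
            or reference_volume <= 0:
        raise ValueError(
            f"residue {series.residue_id}: censoring undecidable without a "
            "positive reference volume")
    return bool(series.volumes[0] < threshold_fraction * reference_volume)


def acceleration_factor(fits_a: dict[int, HdxFit] | list[HdxFit],
                        fits_b: dict[int, HdxFit] | list[HdxFit]
                        ) -> AccelerationReport:
    """Cohort acceleration of protein B over protein A, k_B/k_A per residue."""
    da = _as_dict(fits_a)
    db = _as_dict(fits_b)
    common = sorted(set(da) & set(db))
    if not common:
        raise ValueError("no overlapping residues between the two fit sets")
    ratios: dict[int, float] = {}
    lower_bound: list[int] = []
    for rid in common:
        fa, fb = da[rid], db[rid]
        if fa.censored and fb.censored:
            continue
        if fb.censored:          # faster than observable in B only
            lower_bound.append(rid)
            continue
        if fa.censored or fa.k_hd <= 0:
            continue
        ratios[rid] = fb.k_hd / fa.k_hd
    if not ratios:
        raise ValueError("no matched uncensored residue pairs")
    values = np.array(list(ratios.values()))
    q1, q3 = np.percentile(values, [25, 75])
    return AccelerationReport(
        ratios=ratios,
        median=float(np.median(values)),
        iqr=(float(q1), float(q3)),
        censored_a=sum(f.censored for f in da.values()),
        censored_b=sum(f.censored for f in db.values()),
        lower_bound_residues=lower_bound,
    )


def _as_dict(fits: dict[int, HdxFit] | list[HdxFit]) -> dict[int, HdxFit]:
    if isinstance(fits, dict):
        return fits
    return {f.residue_id: f for f in fits}
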