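# Methods

## Two-state exchange model for CPMG dispersion

The dispersion stage models chemical exchange between a major state A and
a minor state B with populations p_A = 1 − p_B, total rate
k_ex = k_AB + k_BA (k_AB = p_B·k_ex, k_BA = p_A·k_ex) and a ¹⁵N chemical
shift difference Δω (rad·s⁻¹; ppm values are converted with the ¹⁵N Larmor
frequency, 0.10136783 × the ¹H field).  Both states share one intrinsic
transverse rate R₂⁰: the minor-state rate is unidentifiable from
single-field data, and an equal-rate model is standard practice.

Effective rates come from partial peak volumes (5×5 intensity sums around
a peak maximum) via R₂,eff = −(1/T_relax)·ln(I/I₀), with T_relax = 30 ms
and CPMG field strengths ν_CPMG = 1/(2·τ_cp), where τ_cp is the delay
between successive 180° pulses.  Valid frequencies correspond to an even
pulse count n = 2·ν_CPMG·T_relax; the default grid spans 33–933 Hz with
the 67 and 600 Hz points duplicated, and the duplicates provide a pooled
estimate of σ(R₂,eff) when per-point uncertainties are absent.

### Carver-Richards closed form and its numerical reference

The fitted model is the Carver-Richards expression with
Ψ = k_ex² − Δω², ζ = −2·Δω·k_ex·(p_A − p_B),
D± = ½[±1 + (Ψ + 2Δω²)/√(Ψ² + ζ²)],
η± = (τ_cp/√2)·√(±Ψ + √(Ψ² + ζ²)), and

    R₂,eff = R₂⁰ + k_ex/2 − (1/(2τ_cp))·arcosh(D₊·cosh η₊ − D₋·cos η₋).

For ν → 0 the arcosh term grows like η₊, giving the closed zero-field
limit R₂⁰ + k_ex/2 − √[(Ψ + √(Ψ² + ζ²))/8] used for the dispersion
amplitude.  cosh overflows past η₊ ≈ 700, where the asymptotic form
arcosh(x) ≈ η₊ + ln D₊ takes over; arcosh arguments that dip below 1
through floating-point cancellation are clamped to 1 and logged.

The independent reference is a Bloch-McConnell propagation of the explicit
echo train: transverse magnetization (M⁺_A, M⁺_B) evolves under the
complex 2×2 Liouvillian, ideal instantaneous 180° pulses conjugate the
transverse components, and the two-echo-cycle propagator
U₂ = P·conj(P·P)·P (P = expm(L·τ_cp/2)) is raised to integer powers.  Two
detection conventions are exposed:

* **rate** (default, the validation reference): the steady per-train decay
  rate of the A-line between 2·T_relax and 4·T_relax.  The first periods
  flush the fast-decaying minor-state eigenmode; what remains is the
  dominant-eigenvalue decay rate that a closed-form dispersion expression
  models.  Against this reference the Carver-Richards form agrees to
  better than 0.5% over p_B ∈ [0.005, 0.2] and k_ex/Δω ∈ [0.1, 50] (and to
  machine precision against the eigenvalue itself).
* **amplitude**: the constant-time experimental observable,
  −(1/T_relax)·ln(|M_A(T_relax)|/p_A), which is what a measured I/I₀
  yields.  In slow exchange it retains a minor-state transient the closed
  form does not describe (deviations up to ~25% in the slowest corners);
  the synthetic generator uses this convention so that fits face the same
  model mismatch as real data.

Dispersion profiles are not perfectly monotone in ν_CPMG: in slow exchange
the echo train shows small refocusing resonances at low frequencies (a few
percent of the profile span, in both the closed form and the propagation).
Tests assert monotonicity up to 5% of the span for this reason.

### Fitting and classification

Single-residue fits minimise the 1/σ²-weighted squared residuals over
(p_B, k_ex, Δω, R₂⁰) with multi-start initialisation — k_ex ∈ {100, 300,
1000, 3000, 10000} s⁻¹ × p_B ∈ {0.01, 0.05, 0.15}, with Δω and R₂⁰ seeded
from the profile extremes — because the χ² surface is multimodal.  Bounds:
p_B ≤ 0.5, k_ex ∈ [1, 10⁵] s⁻¹, R₂⁰ ≤ 300 s⁻¹.  Uncertainties come from
the Gauss-Newton covariance at the optimum.  Global fits share (k_ex, p_B)
across a residue group (default: one group for all residues) with
per-residue (Δω, R₂⁰), and flag the shared parameters unidentifiable when
every member prefits flat.

The dispersion amplitude is reported as a positive quantity,
ΔR_ex = R₂,eff(ν→0) − R₂,eff(1 kHz); classes are flat/≥1/≥5/≥10 s⁻¹.
Because the measured band carries no information below its lowest
frequency, an unconstrained fit of a flat profile can place the entire
dispersion below 33 Hz and report a large extrapolated amplitude with
essentially no in-band signal.  The flatness decision therefore applies
the 1 s⁻¹ criterion to the fitted model's amplitude across the measured
band, R₂,eff(ν_min) − R₂,eff(ν_max); residues failing it collapse to the
flat model (Δω = 0, R₂⁰ = weighted mean).  This keeps the false-positive
rate on pure-noise profiles at the sub-percent level while leaving true
dispersions untouched.  A consequence worth knowing: k_ex is the
well-determined parameter of a single-field fit (median error < 10% at
σ = 0.2 s⁻¹), whereas Δω and p_B are strongly anticorrelated and
individually recovered only to tens of percent; the global fit resolves
most of that degeneracy.

## Hydrogen-deuterium exchange

Per-residue decays are fitted with V(t) = A·e^(−k_hd·t) + C by bounded
weighted least squares (A, k, C ≥ 0).  The plateau C is free because
equal-volume mixing leaves 50% D₂O, so a residual proton signal is
physically expected.  A series with no decay over the sampled window
leaves (A, k) unconstrained and is canonicalised to the A → 0, k = 0
branch.  Censoring: a residue whose first-spectrum volume is below 0.2 of
its fully protonated reference exchanged within the dead time (default
510 s, one SOFAST acquisition) and is excluded from rate ratios.  The
acceleration of protein B over protein A is summarised as the median (and
IQR) of per-residue ratios k_B/k_A over matched uncensored residues — a
robust estimator, since the underlying report is a range rather than a
point value; residues censored only in B bound their ratio from below and
are listed separately.

## Ensemble descriptors

Ensembles are N equal-topology models (multi-model PDB).  All models are
Kabsch-superposed (SVD, proper rotation) on the Cα atoms of the reference
model (default: first), without outlier trimming.  Per-residue B-factors
are (8π²/3) times the mean-square fluctuation of each Cα about its
ensemble-mean position; the estimator carries a small negative bias
because the rigid-body fit absorbs part of the fluctuation (≈ 6 degrees of
freedom out of 3·N_Cα, i.e. ~3% for a 60-residue chain — tests use chains
of that length).

SASA uses the Shrake-Rupley algorithm with Bondi radii (C 1.70, N 1.55,
O 1.52, S 1.80, H 1.20 Å), probe 1.4 Å and 960 golden-spiral sphere
points.  The point lattice is fixed in space, so SASA is rotationally
invariant only to the discretisation (~0.1%); all other descriptors are
invariant to machine precision.

Hydrogen bonds use the AMBER-style geometric criterion: donor–acceptor
heavy-atom distance ≤ 3.0 Å and donor–H–acceptor angle ≥ 135°, donors
being N/O with a covalently attached hydrogen (H within 1.25 Å), acceptors
N/O of a different residue.  Per-bond occupancy is the fraction of models
in which a specified donor/acceptor pair meets the criterion — identically
the mean of the per-model bond indicator.

Secondary structure is a simplified 3-state assignment built on the
Kabsch-Sander electrostatic energy
E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol with a bond at
E < −0.5: runs of i→i+4 bonds mark helix, parallel/antiparallel bridges
(|i − j| ≥ 3) mark strand, everything else (including incomplete
backbones) is coil, with helix taking precedence.

## Synthetic data

The generators reproduce the statistical structure of each modality at the
study conditions and never share a code path with the estimators they
benchmark:

* **CPMG**: R₂,eff from the Bloch-McConnell propagation (amplitude
  detection — the experimental observable — never the closed form),
  converted to volumes I = I₀·e^(−R₂,eff·T_relax), with Gaussian noise
  applied on the R₂,eff scale (default σ = 0.2 s⁻¹) so repeat-frequency
  scatter reproduces the nominal level.  Cohort builders provide shared
  (k_ex, p_B) groups and ΔRex-targeted distributions (solving Δω for a
  requested amplitude on the rising branch of the unimodal ΔRex(Δω)
  curve, with targets drawn away from class edges so classification of
  noisy refits is not dominated by boundary flips).
* **HDX**: exponential decays on the SOFAST grid (510 s dead time, 510 s
  spacing, 56 spectra ≈ 8 h) with multiplicative Gaussian noise (default
  2%); censored residues arise from large rates.  Paired truths implement
  a uniform rate ratio (default 9, the centre of the 8–10× contrast the
  flexible-isoform comparison is built to emulate).
* **Ensembles**: an ideal all-alanine backbone (N, H, Cα, C, O placed by
  natural-extension geometry; helix dihedrals (−61°, −47°) chosen inside
  the α basin so the built helix realises canonical 2.90 Å i→i+4 N···O
  bonds; sheets register two antiparallel strands by a deterministic
  search maximising the inter-strand bond ladder), replicated with
  per-residue isotropic Gaussian displacements, per-model rigid-body
  jitter, and optionally a chosen fraction of models with one bond's donor
  displaced — giving exactly constructed occupancies.

What the generators do *not* emulate: correlated motions, realistic
force-field energetics, spectral artifacts, intrinsic-rate sequence
dependence of exchange, or side chains.  Passing recovery tests therefore
demonstrates estimator correctness under the stated noise models, not
robustness to every feature of experimental data.

## Problem sizes and numerical choices

Tests and the acceptance script use desk-scale sizes chosen to give stable
statistics: 50-residue cohorts (4 × 50 for the false-positive rate),
10-residue global-fit groups over 3 replicates, 20 HDX replicates,
5000-model ensembles for B-factor recovery and 100-model ensembles for
exact occupancy fractions.  All randomness flows through seeded
`numpy.random.Generator` instances; identical seeds give byte-identical
outputs.  Optimiser tolerances are `least_squares` defaults tightened to
xtol = ftol = 1e-10; HDX rates are bounded above by 10/t₁ (ten decades
within the first sample) to keep censored series from driving the
optimiser to infinity.

## Known limitations

* Single-field, single-temperature data: p_B·Δω² is the robust observable;
  p_B and Δω separate only through the global fit or at higher ΔRex.
* The flat/non-flat decision is threshold-based, not an F-test, by design;
  profiles whose exchange lies entirely below the 33 Hz band edge are
  reported flat because the experiment cannot see them.
* B-factors are unweighted and Cα-only; the rigid-body absorption bias
  grows for short chains.
* The 3-state secondary-structure scheme ignores 3₁₀/π helices and turns;
  bridge detection requires amide hydrogens.
* Multi-model PDB is the only ensemble format; trajectory formats are out
  of scope.
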