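# flexprofiler

Quantifies protein backbone conformational flexibility from three
complementary measurements, the combination used to explain why nearly
identical protein isoforms — such as the birch-pollen allergen variants
Bet v 1.0101 and 1.0102, which share 95.6% sequence identity yet differ
sharply in proteolytic susceptibility — can behave so differently:

1. **¹⁵N CPMG relaxation dispersion** (µs–ms motions).  Peak volumes from a
   constant-time CPMG experiment are converted to effective relaxation
   rates, R₂,eff = −(1/T_relax)·ln(I/I₀), and fitted per residue or
   globally with the Carver-Richards closed form for two-site exchange
   A ⇌ B (populations p_A, p_B, rate k_ex = k_AB + k_BA, shift difference
   Δω).  Residues are classified by the dispersion amplitude
   ΔR_ex = R₂,eff(ν→0) − R₂,eff(1 kHz) at thresholds 1/5/10 s⁻¹.
2. **Amide hydrogen-deuterium exchange** (solvent exposure).  Cross-peak
   volumes after D₂O mixing, sampled on a SOFAST grid (~8.5 min per
   spectrum), are fitted with V(t) = A·e^(−k_hd·t) + C; residues that
   exchange within the dead time are censored, and two proteins are
   compared by the cohort median of per-residue rate ratios.
3. **Structural-ensemble descriptors** (ns–µs fluctuations).  Multi-model
   coordinate ensembles yield per-residue Cα B-factors
   (B = (8π²/3)·⟨|r − r̄|²⟩ after Kabsch superposition), Shrake-Rupley
   SASA, geometric hydrogen-bond counts and per-bond occupancies, radius
   of gyration and a simplified 3-state secondary-structure content.

A Bloch-McConnell echo-train propagator provides the independent numerical
reference for the closed-form exchange model, and a seeded synthetic-data
module generates inputs with known ground truth for every stage.

Intended users: NMR spectroscopists and structural bioinformaticians who
need a tested, scriptable implementation of this analysis chain, with
synthetic benchmarks in place of unreleased raw data.

## Worked example

```python
from flexprofiler import (
    shared_exchange_truth, simulate_cpmg_volumes, fit_global,
    flexibility_fractions,
)
from flexprofiler.io import profiles_from_peak_table

# ten residues sharing (kex = 1000 1/s, pB = 0.04), per-residue Δω and R2⁰,
# Gaussian noise of 0.2 1/s on R2,eff
truth = shared_exchange_truth(n_residues=10, kex=1000.0, pb=0.04, seed=1)
table = simulate_cpmg_volumes(truth)
profiles = profiles_from_peak_table(table, t_relax=0.030)
result = fit_global(profiles)
print(f"shared kex = {result.kex:.0f} 1/s, pB = {result.pb:.4f}")
fractions = flexibility_fractions(list(result.residues.values()))
print({t: round(f, 2) for t, f in fractions.items()})
```

```
shared kex = 1041 1/s, pB = 0.0416
{1.0: 1.0, 5.0: 0.8, 10.0: 0.4}
```

The global fit recovers the shared exchange rate within a few percent, and
the classification reports which fraction of residues disperses by at
least 1, 5 and 10 s⁻¹.

The same analyses run from the shell:

```bash
flexprofiler simulate cpmg --seed 1 --out run/
flexprofiler fit-cpmg --peaks run/cpmg_peaks.tsv --t-relax 0.030 \
    --field-mhz 800 --out run/
flexprofiler fit-hdx --series a.tsv --series b.tsv --ref ref_a.tsv \
    --ref ref_b.tsv --out run/
flexprofiler analyze-ensemble --pdb ensemble.pdb --out run/
```

The numbered scripts under `analysis/` run the full two-isoform study on
synthetic data (generate inputs, fit dispersion, fit HDX, compute ensemble
descriptors, join the site-resolved report) and write their tables under
`results/`.

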