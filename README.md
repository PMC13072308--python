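# phagekit

Quantitative characterization of lytic bacteriophages from desk-scale
inputs: titer time series, plating matrices, gene-call sets, and predicted
proteomes. The package is aimed at phage biologists and bioinformaticians
who need the standard numbers of a phage characterization study — burst
size, adsorption kinetics, host-range breadth, annotation concordance,
proteome similarity — computed reproducibly and testably, plus a synthetic
data generator that emulates each assay with recorded ground truth.

## What it computes

**One-step growth** (`phagekit.growth`). From a titer-vs-time curve:
relative burst size *(final − initial)/initial*, the latent period (first
sustained rise above the initial titer), the end of the rise phase, and a
noise-robust final titer.

**Adsorption kinetics** (`phagekit.adsorption`). From free-phage counts
*P(t)* with bacterial density *B*: per-time adsorption capacity *P₀ − Pₜ*,
rate constant *K = (P₀ − Pₜ)/(P₀·B·t)* (mL/min), velocity *ν = K·B*
(1/min), efficiency *(P₀ − P₆₀)/P₀ × 100*, normalized progress curves, an
OLS regression of ν on K with Pearson R² (the first-order consistency
check), and a whole-series estimate of K from the slope of ln(Pₜ/P₀) vs t.

**Host range** (`phagekit.hostrange`). Efficiency of plating (test titer /
reference-host titer), four-tier classification (high ≥ 0.5, medium
0.1–0.5, poor 0.001–0.1, inefficient below), and per-phage breadth — the
percent of tested strains infected at all.

**Annotation consensus** (`phagekit.consensus`). Gene calls from multiple
prediction tools (GFF3) are matched by strand + 3′ coordinate; a gene is
high-confidence when called by ≥ k of N tools (default 4 of 7). Reports the
consensus rate, pairwise Jaccard concordance, UpSet-style exclusive
intersection counts, and per-tool unique predictions.

**Proteome AAI** (`phagekit.aai`). Average amino-acid identity between two
proteomes: Smith–Waterman local alignments (BLOSUM62, affine gaps 11/1),
reciprocal best hits filtered at ≥ 30% identity and alignment length
≥ 70% of the query, unweighted mean identity over ortholog pairs, and
species-delineation tiers (conspecific > 95%, distinct < 60%).

**Synthetic data** (`phagekit.simulate`) generates all five input kinds
with multiplicative lognormal noise and returns the planted parameters, so
every estimator has a parameter-recovery test.

## Worked example

```python
import phagekit as pk

cfg = pk.SimulationConfig(seed=1, noise_sd=0.05)

# a phage with planted burst size 103, latent period 60 min
curve, truth = pk.simulate_growth_curve(
    initial_titer=1e8, latent_min=60, rise_min=120, burst=103, config=cfg)
summary = pk.segment_phases(curve)
print(round(summary.relative_burst_size, 1), summary.latent_end_min)

# adsorption at K = 1.2e-9 mL/min against 1e8 CFU/mL
series, truth = pk.simulate_adsorption_series(P0=1e9, B=1e8, K=1.2e-9, config=cfg)
report = pk.analyze_series(series)
print(round(report.efficiency_pct, 2), f"{report.fitted_K:.3e}",
      round(report.regression.r_squared, 3))
```

prints

```
110.0 70.0
99.93 1.203e-09 1.0
```

The recovered burst (110.0) sits within 7% of the planted 103 — one noisy
assay; averaging triplicates tightens it — and the latent end is reported
at the first sample after the true 60-min latent period. The adsorption
assay reaches 99.93% efficiency by 60 min, the decay-fit rate constant
1.203×10⁻⁹ mL/min is within 0.3% of the planted value, and
R² = 1.0 because within one series ν is exactly K·B — the regression
validates the reporting pipeline, and departs from 1 only when series with
different bacterial densities are pooled.

A CLI mirrors the library (`phagekit simulate growth`, `phagekit growth`,
`phagekit adsorb`, `phagekit hostrange`, `phagekit consensus`,
`phagekit aai`); every command reads the plain-text formats the simulator
writes (TSV/CSV/GFF3/FASTA) and emits JSON reports.

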