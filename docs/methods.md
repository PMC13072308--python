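# Methods

This note documents the models behind each analysis, the synthetic-data
generators and what they do and do not emulate, the defaults that matter,
and the design decisions taken where more than one convention exists.

## One-step growth

A one-step growth assay follows total titer after synchronized infection.
The summary statistics are:

* **relative burst size** = (final titer − initial titer) / initial titer,
  dimensionless progeny per initially infecting phage;
* **latent period end**: the first sampled time at which the titer exceeds
  `initial × (1 + rise_threshold)` and stays above it for `sustain_points`
  consecutive samples. Defaults `rise_threshold = 0.10`, `sustain_points = 2`:
  the smallest sustained excursion plating noise at ~5% CV will essentially
  never produce, while a genuine rise crosses it within one sampling step.
  A curve that never crosses is flagged "no burst detected" rather than
  segmented arbitrarily;
* **rise end**: the first time at or after the latent end reaching 95% of
  the curve maximum;
* **final titer**: the maximum of the last three samples. A single point at
  the end of an assay is the least replicated; the max-of-3 rule is robust
  to one noisy endpoint at the cost of a small (~+4% at 5% noise) upward
  bias, which stays well inside the 10% recovery tolerance used throughout.

An eclipse phase cannot be resolved from total-titer counts alone (it
requires artificial lysis to count intracellular virions), so it is not
segmented; only latent and rise boundaries are reported. Negative burst
sizes (final below initial) are returned as computed and flagged, never
clamped — they indicate abortive infection or assay failure and should be
visible.

Burst estimates quoted from noisy assays are best taken as the mean over
replicate curves; assays of this kind are conventionally run in triplicate,
and the acceptance script follows that convention (`replicate_count = 3`).

## Adsorption kinetics

Free phage decays by first-order binding, `P(t) = P0·exp(−K·B·t)`, with
`B` the bacterial density (CFU/mL). The per-time statistics are defined
directly from counts:

| quantity | formula | units |
|---|---|---|
| capacity | `P0 − Pt` | PFU/mL |
| rate constant K | `(P0 − Pt)/(P0·B·t)` | mL/min |
| velocity ν | `K·B` | 1/min |
| efficiency | `(P0 − P_final)/P0 × 100` | percent |

Units for K follow from dimensional analysis of the formula; reports carry
them explicitly. The t = 0 row is excluded from per-time tables (K is a
0/0 there). On noiseless first-order data the per-time K equals
`(1 − e^(−K·B·t))/(B·t)`, which decreases in t — so the maximum per-time
rate falls at the first positive sample, matching the intuition that
binding is fastest while receptors are unoccupied. Negative capacities
from upward count noise clamp to 0 with a warning; efficiencies are
reported half-up to two decimals.

**K-vs-ν regression.** Because ν is defined as K·B, within one series the
(K, ν) pairs are exactly collinear and the OLS slope is B, intercept 0,
R² = 1 (to machine precision). The regression is therefore an internal
consistency identity for a single assay — it catches unit or pipeline
errors, not biology. It becomes a real regression when pairs are pooled
across assays with different bacterial densities; the acceptance script
pools 200 noisy replicates whose B varies with 5% CV (a typical
between-culture plating variability) and the pooled R² stays above 0.92.
Zero variance in K (e.g. a K = 0 series) makes R² undefined; the result is
flagged degenerate rather than reported as 0 or 1.

**Whole-series K estimate.** OLS of `ln(Pt/P0)` on t has slope −K·B under
the first-order model; `estimate_rate_constant` returns −slope/B, clamped
at 0. Zero counts are excluded (with a warning) since they cannot be
log-transformed. On noiseless synthetic series the estimate recovers the
planted K to ≥ 6 significant digits; at 5% multiplicative noise over the
standard 7-point design (0–60 min) the relative standard error is ~1%, so
the 10% recovery criterion holds in essentially every seeded replicate.

## Host range and EOP

EOP is the titer ratio test strain / isolation host. It is a ratio, not a
probability — values above 1 occur when a heterologous strain plates a
phage better than its own host — which is why the classification has no
upper bound. Tiers: high ≥ 0.5, medium [0.1, 0.5), poor [0.001, 0.1),
inefficient < 0.001. The conventional published bounds overlap at 0.001;
half-open intervals resolve the overlap (0.001 → poor) so the tiers
partition [0, ∞), and the bounds are configurable.

Breadth is the percent of tested strains with any productive infection
(EOP > 0 by default; the threshold is configurable), rounded half-up to
one decimal — the rule that reproduces 20/21 → 95.2 and 10/21 → 47.6
exactly. Matrix summaries require a complete grid (a missing cell raises
an error naming the cell): an absent measurement and a measured zero mean
different things.

## Annotation consensus

Gene callers disagree mostly on start codons; the stop codon of a true
gene is fixed by its reading frame. Two calls are therefore the same gene
when they share strand and 3′ coordinate — the `stop` field on the +
strand, the `start` field on the − strand. An exact mode (start + stop +
strand) exists in the matcher's callers for sensitivity analysis simply by
comparing call tuples. On circular genomes the 3′ coordinate is reduced
modulo the genome length, so origin-spanning calls match their linearized
equivalents; linear genomes reject wrap-around calls.

The consensus at threshold k keeps keys called by ≥ k of the N tools
(default 4 of 7 — a majority-leaning threshold that suppresses single-tool
false positives while tolerating three misses). The **consensus rate** is
the consensus count as a percentage of the union of all keys across tools;
the union denominator is the only choice under which "rate" is a property
of the tool ensemble rather than of one tool, and per-tool alternatives
can be derived from the reported per-tool counts. Jaccard concordance,
exclusive (UpSet) intersection counts over all 2^N − 1 tool subsets, and
per-tool unique counts are computed on the same key sets; the exclusive
counts partition the union, an identity asserted in tests on every run.

## Proteome AAI

AAI between proteomes A and B is the unweighted mean identity over
reciprocal-best-hit pairs. Alignments are Smith–Waterman local alignments
under BLOSUM62 with BLAST-convention affine gaps (gap of length L costs
11 + L). Identity is identical columns over all aligned columns (gaps
included). Filters, applied in both RBH directions:

* identity ≥ 30%;
* alignment length ≥ 70% of the query length (the stricter reading of the
  common "70% alignment length" filter; a shorter-sequence-fraction mode
  is available via `cover_mode="shorter"`);
* raw score ≥ 50 BLOSUM62 units. A calibrated e-value threshold would
  require Karlin–Altschul parameters; for desk-scale proteomes a raw-score
  floor rejects the same spurious short hits and is exactly reproducible.
  The threshold is configurable.

Best-hit ties are broken by higher identity, then lexicographic subject
id, for determinism. Mean AAI is unweighted across pairs (not
length-weighted); the orthologous fraction is the pair count over the
smaller proteome. Zero surviving pairs make the AAI undefined (NaN with a
flag, tier "unresolved") — reporting 0 would conflate "no orthologs
detectable" with "orthologs of 0% identity". Tiers use strict
inequalities: conspecific > 95, distinct < 60, related in between.

Each unordered genome pair is computed once and mirrored, so the AAI
matrix is symmetric by construction with a diagonal of 100.

## Synthetic data: what it emulates, and what it does not

All generators share `SimulationConfig(seed, noise_sd, replicate_count)`;
identical seed and parameters give bit-identical output, and `noise_sd = 0`
reproduces the closed-form expectations exactly. Noise on counts is
multiplicative lognormal (`× exp(N(0, noise_sd))`): titers span five or
more decades within one assay, so additive noise has no meaningful scale.
The default `noise_sd = 0.05` is a free parameter chosen as a plausible
plaque-count CV, not inferred from data. The t = 0 observation of each
kinetic series is left noiseless: it defines the assay's reference (P0 /
initial titer).

* **Growth curves**: flat latent segment, exponential rise of duration
  `rise_min` to `initial × (1 + burst)`, plateau after. Real curves show
  rounded shoulders and sometimes biphasic rises; the piecewise form is
  the minimal shape that makes latent/burst recovery well-posed. Defaults
  (initial 10⁸ PFU/mL, latent 60 min, rise 120 min, burst 103, sampled
  every 10 min to 240 min) mirror a typical coliphage assay design.
* **Adsorption series**: exact first-order decay at planted K, sampled at
  0–60 min in 10-min steps, the model the per-time K formula assumes.
  Desorption, multi-phase binding and receptor saturation are not
  simulated — so recovery tests validate the estimator, not the biology.
* **Host-range matrices**: each phage infects exactly
  `round(breadth × n_strains)` randomly chosen strains with log-normal
  EOPs (base-10 mean −0.5, sd 1.0 — spanning all four tiers); zeros stay
  zero under multiplicative noise, so planted breadths are recovered
  exactly. Defaults emulate a panel of 21 strains.
* **Prediction sets**: a shared true gene set (non-overlapping genes,
  180–1197 bp in codon multiples) perturbed per tool: true genes dropped
  with `miss_rate`, Poisson(`spurious_rate`) spurious calls with globally
  unique 3′ keys, and 5′ ends jittered in codon steps up to `start_jitter`
  bp. The 3′ anchor is never moved — the property the matching rule relies
  on. Real tools disagree more richly (frameshifts, merged/split genes);
  those failure modes are out of scope.
* **Proteome pairs**: i.i.d. substitutions at the planted divergence rate
  (always to a different residue), giving expected pair identity
  (1 − d) × 100%. Orthologs are positionally paired and realized per-pair
  identities are recorded. Indels are off by default so the positional
  identity oracle is exact; an `indel_rate` (deletions in the second
  proteome) can be enabled. Residues are drawn uniformly, not from natural
  amino-acid frequencies — local alignment statistics on random sequence
  are therefore slightly conservative relative to real proteins.

Because generated data obey the estimators' model assumptions by
construction, passing recovery tests demonstrates estimator correctness
and numerical stability, not robustness to model misspecification in real
assays.

## Numerical choices

* Half-up rounding (via `decimal`) wherever published-style percentages
  are reported: breadths to 1 decimal, efficiencies and rates to 2 and 1.
* Exact-collinearity R² is asserted to 1 within 10⁻¹² (scipy's `linregress`
  leaves ~1 ulp of rounding).
* Local-alignment scores are validated against an independent pure-Python
  Gotoh dynamic program kept in the test suite, never imported by the
  package.
* TSV round trips use `%.17g` formatting and `float_precision="round_trip"`
  parsing, so written curves re-read bit-identically.
* Problem sizes in tests and the acceptance script (200 seeded replicates
  for Monte-Carlo rates; 7-tool/80-gene prediction sets; 50-protein
  proteomes of 200–400 aa; 500 alignment-oracle pairs up to length 50)
  are chosen so each suite completes in seconds while keeping Monte-Carlo
  standard errors far below the tolerances being checked.

## Known limitations

* Growth segmentation is a threshold rule, not a change-point fit; very
  small bursts (≲ `rise_threshold`) are reported as "no burst detected".
* The per-time K table assumes free-phage counts; lysis-released progeny
  during long adsorption assays would violate the monotone-decay
  assumption and is not modelled.
* AAI on highly divergent proteomes (planted divergence ≳ 0.6) is governed
  by the filters: occasional borderline pairs pass near the 30% identity
  floor, so the orthologous fraction approaches 0 without being exactly 0.
* No functional annotation, phylogenetics, or nucleotide-level ANI; the
  package consumes gene calls and proteomes, it does not produce them.
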