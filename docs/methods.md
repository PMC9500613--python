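# Methods

This note records the models, rules and numerical choices behind the
package, the assumptions they rest on, and what the synthetic benchmark
can and cannot show.

## Input model

The atomic record is an identified peptide ion with a modification
string, identification metadata (charge, score, signed mass error in
ppm) and per-sample normalized abundances. The package deliberately
starts *after* spectral identification: chromatogram alignment, spectrum
scoring and the target–decoy FDR of the search engine are out of scope,
and their output is trusted as given. Abundance tables are assumed to be
normalized upstream (as search-engine exports are); the
`TotalIntensityNormalizer` (each sample column scaled to the grand-mean
column sum) exists for raw tables and is off by default. Missing
abundance cells parse as 0.0 with a warning, matching the zero-filling
convention of common exports; a strict mode rejects them instead.

## Filtering rules

A peptide is kept when |mass error| < 20 ppm (the export's printed
cutoff, applied to the absolute value because exported errors are
signed) and it has at most one missed cleavage. Missed cleavages are
internal K/R residues, with two exemptions: acyl-modified lysines
(succinylation/malonylation neutralizes the lysine charge and blocks
trypsin, so a modified K is not a cleavage site) and K/R followed by
proline. The terminal residue never counts. The KP exemption is
flag-controlled (`kp_rule`, default on) because identification engines
differ on it. Every rejected peptide carries a machine-readable reason
(`mass_error` or `missed_cleavages`), and kept + rejected always
partitions the input.

## Hi-N quantitation

Protein relative abundance per sample is the mean of the protein's N
(default 3) most intense peptides. The peptide set is fixed across
samples by ranking on the mean abundance over all samples — not
re-selected per sample — so ratios between samples compare like with
like. Ties break deterministically by higher identification score, then
lexicographic sequence. Acyl-modified peptides are excluded by default
(their intensity tracks site stoichiometry, not protein amount); a flag
includes them. With N at least the number of peptides, Hi-N reduces to
the plain per-sample mean; the selected rows are averaged in original
table order so this limit holds to machine precision.

## Differential testing

Each acyl-modified peptide is tested by classical one-way fixed-effects
ANOVA across all design groups, on log₂(abundance + 1) by default
(log-scale is standard for LFQ intensities; the +1 pseudo-count keeps
zero-filled cells finite, and a linear-scale flag is retained). The raw
p-value is thresholded at α = 0.05 with **no multiple-testing
correction** — this mirrors how such tables are conventionally filtered
— while BH q-values are reported alongside for reference. Degenerate
features: all-zero abundances and under-replicated groups are skipped
with a warning; zero within-group variance yields p = 0 (unequal means,
with a warning) or p = 1 (identical groups). Direction is the sign of
the mean of non-reference group means minus the reference (vehicle 1 by
default) group mean on the linear scale; a protein whose significant
sites move both ways is classed "Both".

## Attenuation grading

Per modified peptide, on linear-scale group means of normalized
abundance (the band rules speak of percent changes of quantitation
scores, so no log transform):

1. Vehicle concordance: the two vehicle means must satisfy
   |v₁ − v₂| / ((v₁ + v₂)/2) ≤ 0.10. The symmetric denominator makes
   the rule order-independent.
2. Baseline b = (v₁ + v₂)/2; deviations d = (mean − b)/b.
3. Severity from |d_model| with bands (0.10, 0.25, 0.50]: none ≤ 0.10 <
   mild ≤ 0.25 < moderate ≤ 0.50 < severe. Exact boundary values fall in
   the milder class ("dysregulated by 10%" is read as strictly
   exceeding).
4. Attenuated iff severity ≠ none, |d_treated| < the severity's own
   threshold, and |d_treated| < |d_model| (movement toward control).
   Overshoot past control still counts by magnitude — the rules are
   direction-agnostic.
5. Residual band of |d_treated| with half-open bands [0, 0.10),
   [0.10, 0.25), [0.25, 0.50); asterisks = severity index − residual
   index, so `**` occurs exactly for a > ±50% disturbance returning to
   within ±10%.

Eligibility is by the band rules alone; requiring ANOVA significance in
addition is available behind a flag (off by default). Features with any
non-positive group mean are excluded with a warning. Proteins with more
than one attenuated modified peptide are flagged in the rendered table.

## Over-representation analysis

For a query of protein/gene identifiers against a GMT collection, the
p-value is the exact hypergeometric upper tail P(X ≥ k) with overlap k,
set size K counted within the background, query size n and background
size N, followed by Benjamini–Hochberg FDR across sets. The background
defaults to all proteins quantified in the experiment — enrichment of a
subset of detected proteins is the question being asked — with the GMT
universe available as an alternative. A set passes at FDR ≤ 0.01,
p ≤ 0.01 and k ≥ 5; the minimum-genes rule is applied to the *overlap*
(the dot-plot sizes dots by gene names found), not to the set size.
Query identifiers absent from the background are dropped with a logged
warning.

## Synthetic data generator

The generator emulates the cell-line design: two vehicle groups, one
insult (model) group and one co-treatment group, 3 replicates each.
Proteins are random sequences concatenated from their own 8–16-residue
peptides (core alphabet without K/R/P, tryptic K/R terminus), so every
peptide occurs exactly once in its protein and unmodified peptides have
zero missed cleavages. A fraction of peptides (default 6.5%, the
midpoint of the 5–8% observed for these PTMs) carries one succinyl or
malonyl lysine (50:50).

Planted effects, per feature, relative to a baseline intensity drawn
log-uniformly over four decades (10⁴–10⁸):

- Vehicle pairs are identical (concordant) or split symmetrically past
  the 10% rule (discordant, rate 10%) — so the concordance rule is
  obeyed/violated *exactly* on noiseless means. Graded sub-threshold
  vehicle effects are not modeled.
- 40% of modified peptides are dysregulated in the model group, with
  severity mix 40/35/25 (mild/moderate/severe) and a deviation drawn
  uniformly inside the band, kept 0.02 away from the band edges.
- Half of dysregulated features are attenuated: the co-treatment
  deviation keeps the model's sign and is drawn from a residual band at
  or below the severity's threshold, with band mix 33/22/45 (the pooled
  column frequencies of the published attenuation table); non-attenuated
  features keep the model deviation unchanged.
- Observed abundances are planted mean × 2^N(0, σ) with σ = 0.1 (log₂),
  independent per sample.

Ground-truth labels are produced by running the package's own band
classifier on the noiseless planted means, so truth and pipeline agree
exactly in the σ = 0 limit by construction; the planted "differential"
flag is true iff any planted group means differ (dysregulation or a
vehicle split), which is what ANOVA on noiseless data detects. The
generator is a pure function of its seed; outputs are byte-identical
across reruns.

**What the benchmark does not show.** Real LFQ data has correlated
(run-level) noise, missing features, intensity-dependent variance,
shared peptides between proteins, and multi-site peptides; the generator
has none of these, so recovery rates here bound what clean data allows
and say nothing about alignment or identification errors.

**A measured limitation.** With σ = 0.1 and 3 replicates/group, a
deviation estimate carries an sd of ≈ 0.05. Planted deviations sit only
0.02 from the band edges, so band-boundary flips are not rare:
severity-band accuracy plateaus around 0.92–0.95, and the precision of
`**` calls plateaus around 0.86 (moderate effects near the 0.50 edge and
severe effects with 10–25% residuals leak into predicted `**`). Making
`**` precision exceed 0.9 would require either a boundary margin of
about twice the deviation-estimate sd (~0.10) or more replicates; the
margin is kept at 0.02 as a deliberate, documented stress condition.

## Pipeline and determinism

Stages run in a fixed order (load → filter → annotate → quantify →
differential → attenuation → enrichment); any stage failure aborts with
the stage name (CLI exit codes: 2 configuration, 3 data). All tables are
written with a fixed float format and no timestamps, and the manifest
records thresholds, per-stage counts and SHA-256 checksums of every
table, so identical inputs and seed give bitwise-identical outputs. The
default verification scale (500 proteins, ~2 700 peptide ions, 12
samples) keeps a full generate–analyze–score cycle under a few seconds.
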