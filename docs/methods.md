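# Methods

## Occupancy model

A lysine site with initial (pre-treatment) occupancy `s0` (percent)
exposed to acetyl-phosphate gains a chemical increment on its unmodified
pool. We model the treated occupancy as

```
s1 = s0 + c · (1 − s0/100)
```

where `c` (percent) is the per-lysine reactivity: chemical acetylation can
only convert copies that are not already acetylated, and the model reduces
to the additive picture `s1 ≈ s0 + c` when `s0` is small. The SILAC ratio
between treated (light) and untreated (heavy) channels is `R = s1/s0`.

The bound estimator reports `s0 < c_max / R` with `c_max = 1 %` by
default. This follows the published convention of dividing by `R`, not the
exact algebra `c_max/(R−1)`. The two differ — `c_max/R` is the slightly
tighter number — and the division-by-R form is kept because the reference
report defines the estimate that way for both its 10-fold→0.1 % rule and
its AQUA table. Its validity as an upper bound then rests on `c_max`
being a generous ceiling: `c_max/R` covers the exact `c/(R−1)` whenever
`c ≤ c_max·(R−1)/R`, i.e. whenever the true reactivity stays below half
the ceiling at the worst case `R = 2` — comfortably true, since measured
reactivities have median 0.07 % with range ≈ 0.01–0.11 % against the 1 %
ceiling. Sites with
`R < 2` change by less than the measurement variability of the assay, so
no numeric bound is reported; they are classed *insensitive* and flagged
`>1%`. The threshold is exclusive: `R = 2` is sensitive.

AQUA occupancy is `100 · a/(a+u)` where `a` and `u` are the absolute
amounts of the acetylated and unmodified peptide, each obtained as
(light intensity / standard intensity) × spiked amount. Initial occupancy
is `s0 = s_acp/R` and the degree of chemical acetylation `c = s_acp − s0`.
All computation is at full precision; the reporting layer rounds `s0` to
4 decimals and `c` to 2 decimals (percent), matching the reference
report's print precision. Note that one published row
(`AND(ac)NESATINEMMK`) is not exactly reproducible from its printed,
rounded inputs (0.181/1.7 = 0.1065, printed 0.1055 — evidently computed
from unrounded inputs); validation targets only self-consistent rows.

## Detection limit and minimum ratios

Sites whose heavy (untreated) channel is below detection still carry
information: the treated light intensity must have grown from *somewhere
below* the detection floor. The floor is estimated empirically as the
median intensity of the bottom 10 % of observed heavy peptides (bottom set
size `max(1, floor(0.10·n))` — deterministic and conservative for small
`n`; at least 10 intensities are required). The minimum fold increase is
`light / limit`, and the bound `c_max / min_ratio` applies as before.
Because the limit sits above every censored heavy intensity, the minimum
ratio understates the true ratio and the derived bound stays conservative.
Light intensities *below* the limit yield `min_ratio < 1`; these are
reported unclamped with a `light_below_detection_limit` flag rather than
dropped, so upstream data problems stay visible.

## iBAQ and I/iBAQ-A

iBAQ is total protein intensity divided by the number of theoretically
observable tryptic peptides: fully tryptic fragments (cleavage after K/R,
blocked before P, zero missed cleavages) of length 7–30. This is the
standard iBAQ convention; the digest is done with pyteomics. I/iBAQ-A is
the acetyl-peptide intensity divided by the protein's iBAQ, using
*untreated-channel* quantities only (the heavy channel in this design), so
it is an occupancy proxy independent of the AcP treatment. Sites on
proteins without iBAQ, or without an observed heavy channel, carry no
score rather than a zero.

`stoichiometry_fractions` counts `>1%`-flagged sites in every denominator
and in no numerator; the tabulated thresholds of interest (0.02, 0.05,
0.1, 1 %) never exceed 1 %, where that reading is exact.

## Statistical tests

"Wilcoxon test" is implemented as the two-sample rank-sum
(Mann–Whitney U) test, since compartment comparisons are between
independent site sets: exact enumeration when the smaller sample has ≤ 8
values and no ties, otherwise the normal approximation with midranks,
tie-corrected variance and continuity correction (scipy's
`mannwhitneyu`). Term enrichment uses the one-sided hypergeometric tail
P(X ≥ k) (scipy `hypergeom.sf`) — enrichment is a one-tailed question —
and the output table carries both raw p-values and Benjamini–Hochberg
adjusted ones; the BH column is this package's addition, and which to
report is left to the caller. TMT relative abundance is
mean(treated)/mean(control) with a two-tailed pooled-variance t-test;
zero-variance groups are degenerate and yield a flagged p of 1 (equal
means) or 0 (different means) instead of a NaN. The parent-ion purity
filter is inclusive at exactly 0.90. Protein-abundance correction of site
ratios is division in linear space; log2 is applied only for reporting,
and because log2 is monotone the reported `median_log2_ratio` is exactly
`log2(median_linear_ratio)`.

## Acetyl-CoA pool arithmetic

With whole-cell acetyl-CoA totals for wild type, a strain unable to make
mitochondrial acetyl-CoA (pda1Δ) and a strain unable to consume it
(cit1Δ), the mitochondrial pool of each strain is taken as its total
minus the pda1Δ total; the cit1Δ/wild-type mitochondrial fold change is
then `(cit1 − pda1)/(wt − pda1)`. A compartment holding pool fraction `p`
of a metabolite in volume fraction `v` of the cell is enriched
`(p/v)/((1−p)/(1−v))`-fold in concentration over the remainder — e.g. a
third of the pool in 1.5–2 % of the volume is a ~25–33-fold enrichment.

## Synthetic-data generator

The generator emulates the processed tables of a partial-chemical-
acetylation SILAC experiment, not the instrument. Defaults (all
overridable in `GeneratorConfig`):

* **Protein abundance**: log-normal, median e^18 ≈ 6.6×10⁷ intensity
  units, log-sd 2.3 natural-log units (~1 decade), matching the several-
  decade dynamic range of yeast protein abundance. The wide spread makes
  detection censoring abundance-driven, as in real data.
* **Compartments**: mitochondrion 0.20, cytoplasm 0.40, nucleus 0.25,
  other 0.15; 10 % of proteins get a second localization (such proteins
  are excluded from exclusive-compartment analyses).
* **Site occupancy**: log-uniform on 10⁻⁴–10⁻¹ %, multiplied by a
  compartment basal factor (mitochondrion 3×) so mitochondrial occupancy
  runs a few-fold above cytoplasmic; 25 % of nuclear sites instead draw
  from a high-occupancy mode (1–100 %). This yields ≈ 94 % of sites below
  1 % true occupancy and a bimodal nuclear ratio distribution.
* **Reactivity**: log-normal with median 0.07 % and log-sd 0.6 (central
  mass ≈ 0.02–0.2 %), truncated at 1 % by resampling — centered on the
  measured per-lysine reactivities. The true reactivity distribution
  beyond the few measured values is unknown; this is a modeling choice.
* **Intensities**: heavy ∝ abundance × s0/100, light ∝ abundance × s1/100,
  each with multiplicative log-normal noise of CV 0.15. Heavy intensities
  below the detection threshold (default 2000, chosen so that roughly
  45 % of sites lack a ratio, as in the real experiment where 1540 of
  2456 natural sites had none) are censored and flagged in the truth
  table. 60 % of sites are marked naturally occurring (≈ the observed
  share among ratio-bearing sites).
* **Determinism**: one integer seed drives a single `numpy` Generator;
  identical configurations give byte-identical output tables.

What the generator does **not** emulate: identification error, protein
inference ambiguity, missed/over cleavage, chromatographic or ionization
effects, isotope impurity, co-isolation interference beyond the scalar
purity value, and correlated noise between channels. Passing recovery
tests therefore demonstrates the estimators' correctness under the stated
statistical model, not robustness to every artifact of real MS data.

### Recovery guarantees checked on synthetic data

With default problem sizes (400 proteins, ≈ 1200 sites — seconds on one
CPU): the occupancy bound covers the true occupancy for every sensitive
site with reactivity ≤ 0.5 %; minimum ratios understate the true ratio
for ≥ 95 % of censored sites; AQUA occupancy recovery at 5 % intensity
noise has a median relative error ≤ 15 % (per-site error combines four
noisy intensities, so a median criterion is the meaningful one — ~16 % of
individual sites necessarily exceed 15 % at this noise level); I/iBAQ-A
rank-correlates with true occupancy above 0.5; and the rank tests agree
with brute-force enumeration oracles.

## Numerical and interface choices

* Stoichiometry, reactivity and bounds are in **percent** everywhere to
  avoid fraction/percent confusion; ratios are dimensionless L/H with
  light = treated fixed at read time (`ratio_is_heavy_over_light` converts
  inverse tables).
* Missing values are empty TSV fields, never sentinel numbers; floats are
  serialized at full `repr` precision so write∘read is the identity.
* Rejected table rows each produce exactly one diagnostic carrying the
  1-based data-row number; readers never silently drop data.
* Whether the published "86 % of sites < 1 %" class is delimited by R > 1
  or R ≥ 2 is ambiguous in the source; the pipeline exposes both views
  (flagged insensitive sites are always tabulated separately) and asserts
  neither.
* Search-engine exports vary in column naming; readers accept a canonical
  schema plus a column-remapping config instead of guessing vendor column
  names.

## Known limitations

The bound is an upper bound only: sites with unusually reactive lysines
(`c > c_max`) would be over-bounded, and chemically unreactive or buried
lysines can masquerade as high-occupancy (insensitive) sites. Minimum
ratios depend on the empirical detection limit being representative of
the censored sites' noise floor. AQUA absolute values require matched
heavy standards; no isotope-impurity correction is applied. Protein
grouping/inference is out of scope — site tables are taken at face value.
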