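# Methods

## Screen statistic

The pipeline scores pooled screens read out as count tables over paired
samples: stable vs unstable sorted gates (reporter screens) or drug vs DMSO
arms (resistance screens). The five stages are normalization to per-sample
totals, per-replicate enrichment ratios, within-replicate ranking,
median/rank-sum aggregation to targets, and an empirical two-sided
rank-sum p-value. Both screen modes run the identical code path; the
design only decides which sample is the ratio's numerator.

Assumptions worth stating explicitly:

* **Exchangeability under the null.** The empirical null assigns ranks to
  features uniformly at random, independently per replicate. This is
  exactly correct when guides are exchangeable within a replicate and
  replicates are independent; it does not model guide-specific variance or
  correlated replicates. Whether the experimental analysis permuted ranks
  jointly or independently across replicates is not observable from the
  procedure's description; independent permutation is implemented.
* **Ties.** Average ranks preserve the per-replicate rank-sum invariant
  N(N+1)/2, which the suite checks property-based.
* **Medians.** Even-sized medians (4 guides/gene, even replicate counts)
  are the midpoint of the two central order statistics. One consequence:
  swapping numerator and denominator maps fold changes to exact
  reciprocals only for odd feature/replicate counts, because midpoint
  medians do not commute with reciprocals.

### Numerical choices

* **Pseudocount** (default 0.5, applied to normalized values in both
  numerator and denominator): guide dropout in a sorted gate is common, and
  a symmetric pseudocount keeps ratios finite without biasing direction.
  With pseudocount 0, a zero denominator is a hard error listing the
  features.
* **Normalization** is computed as `(integer counts × scale) / integer
  total`. Both operands are exact in double precision for any realistic
  depth (< 2⁵³), so multiplying a sample's raw counts by a constant changes
  nothing downstream, bit for bit — a useful invariant for regression
  testing and a guard against depth artifacts.
* **Null pooling.** Each null iteration permutes ranks once and yields
  `floor(N/k)` pseudo-target draws of size `k`; pooling across
  pseudo-targets within an iteration multiplies the effective null size M
  at no extra simulation cost (100 iterations × 713 pseudo-targets =
  71,300 draws at library scale). Pseudo-target draws within an iteration
  share one permutation and are therefore not independent, but each has
  the exact marginal null distribution, which is what the empirical tail
  counts require.
* **Two-sided p.** Both tails carry the +1 correction; the two-sided value
  doubles the smaller tail and caps at 1, giving a floor of 2/(M+1) and
  ruling out p = 0. Targets with different guide counts are compared
  against separate nulls of matching pseudo-target size.
* **Ranking direction** defaults to `enriched_first`; the two-sided test
  makes hit calling direction-agnostic. Control features are ranked along
  with everything else by default (`exclude_controls=True` to drop them).
* Fold changes are reported on the raw ratio scale; log-transforms are
  left to presentation.

## Synthetic data generator

The generator stands in for raw screen sequencing data and defines the
conditions all recovery tests run under. It emulates:

* a UPS-targeted knockout library — 713 genes × 4 sgRNAs = 2,852 guides,
  50 of the genes control-labelled, 3 sorting replicates, 10⁶ reads per
  sample (`make_bison_library` defaults);
* an alanine scan — one variant per residue over a window (the default,
  positions 349–461, gives 113 variants), contiguous sub-libraries
  simulated as independently cloned and sequenced pools and concatenated
  as the analysis expects.

A target with effect β multiplies its features' sampling weight by e^{+β}
in the stable gate and e^{−β} in the unstable gate (drug arm only, e^{β},
for resistance screens), so the expected normalized ratio is e^{2β}
(e^{β}); the symmetry makes the expected log-ratio exactly 2β and is a
modelling choice, not an experimental claim. Counts are multinomial at
fixed depth; overdispersion is available as a Dirichlet–multinomial with
concentration `weights/dispersion` (`dispersion = 0` is pure multinomial
and the default). Library abundance is lognormal (σ = 0.5, normalized) to
mimic cloning skew. Every sample draws from `default_rng([seed,
stream_index])`, so generated data are bit-reproducible and adding samples
never perturbs existing ones.

What the generator deliberately does **not** model: cell growth and
selection dynamics between infection and sorting, sgRNA cutting-efficiency
heterogeneity, sorter impurity, PCR jackpotting beyond the dispersion
knob, and guide-specific off-target effects. Passing recovery tests
therefore show the statistics are correct and well calibrated under the
stated sampling model — not that any particular biological screen will be
as clean.

Recovery conditions used by the test suite and acceptance script (chosen
once as realistic desk-scale stand-ins): 10 planted hits at β = 1.5 among
713 targets at depth 10⁶ for the knockout screen; 5 critical residues at
β = 1.5 among 113 positions for the alanine scan; null calibration with
500 null iterations at full library scale.

## Alanine scan specifics

Sub-library count tables of the same sorting replicates are row-stacked
before analysis; per-sample totals are recomputed on the merged matrix, so
normalization happens after concatenation (default). The alternative
reading — normalize each sub-library on its own totals, then merge — is
available via `per_sublibrary_normalization=True`; with comparable
sequencing depths the two agree closely, and the choice is surfaced
rather than hidden because the published procedure is ambiguous on the
order. Variant ids follow the `<wt><position><substitution>` convention
(`H437A`; alanines become arginine, `A412R`) and are parsed into residue
position and substitution for residue-level maps.

## Dose–response

Wells with concentration 0 are the vehicle set: they define the
normalization (each well's eGFP/mCherry ratio divided by the mean vehicle
ratio) and are excluded from fitting. The 4PL
`f(x) = d + (a − d)/(1 + (x/c)^b)` is fit by bounded least squares on log
concentration with four deterministic starts built from response
quantiles, because 4PL objectives on sparse 8-point grids are multimodal;
the best start by SSR wins. The slope is constrained positive — falling
and rising curves are distinguished by the asymptotes, keeping the
parameterization identifiable. Flat data (range < 10⁻⁶) return
`converged = False` with NaN DC50 instead of a spurious fit.
`Dmax = (1 − d/a)·100` from the fitted asymptotes is the primary
definition; the model-free `(1 − min response)·100` is reported alongside
since published "maximal depth of degradation" figures are often read off
the data directly. LOESS display curves are local-linear with tricube
weights on log10 dose (span 0.75 default); the implementation evaluates at
the observed doses and interpolates the dense display grid.

## Closed-form metrics

TR-FRET points are 520/490 nm emission ratios (gain-invariant by
construction). Hook peaks — the turnover of ternary-complex signal at high
degrader dose — are localized as the argmax of the LOESS-smoothed curve
over the tested doses, with a `no_hook` flag when the maximum sits at the
highest dose; smoothing is skipped below 5 points where LOESS is not
meaningful. Labeling efficiency uses peak heights as given (deconvolution
is upstream); the labeled species is either labelled explicitly or
identified as the unique peak within ±2 Da (configurable) of the unlabeled
mass plus the expected adduct mass, with ambiguity reported as an error
listing candidates, never resolved silently.

## Problem sizes

Full-library simulations (2,852 guides × 6 samples at depth 10⁶, null of
500 iterations ≈ 3.6 × 10⁵ draws) run in seconds; the
Monte-Carlo-vs-enumeration comparison enumerates all rank assignments for
instances up to 8 features × 2 replicates (2.8 × 10⁶ outcomes) and checks
agreement within ±0.02 at 20,000 null iterations. These sizes were chosen
to match the emulated designs while keeping the whole suite fast to rerun.

## Known limitations

* The empirical null is exchangeable-rank; screens with strong
  guide-quality structure would need a guide-aware null (out of scope, as
  are robust-rank-aggregation alternatives).
* p-values are raw, as in the screen procedure emulated; no
  multiple-testing correction is applied.
* The 4PL fit does not model the hook region of biphasic degradation
  curves; points beyond the hook should be excluded before fitting.
* FASTQ demultiplexing/guide alignment and FCS gating are upstream of this
  package; inputs are count tables and per-well summaries.
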