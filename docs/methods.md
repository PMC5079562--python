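# Methods

This note documents the models, conventions and design choices behind
`rhizoindic`. The package asks a practical question about soil 16S
amplicon data: which community summaries behave well enough — at
realistic sequencing depths — to serve as ecological indicators of soil
disturbance? It answers it with five linked analyses: sample-size
sufficiency of alpha-diversity indices, common-taxa identification,
composition variability, a paired differential screen, and
indicator-value analysis; all of them exercised on synthetic communities
with known ground truth.

## Alpha-diversity indices

For a count vector with proportions `p_i`:

- Shannon `H = -Σ p_i log_b p_i`, default base `b = 2` (bits), the
  convention of the QIIME-era toolchain most 16S studies used; base `e`
  is available. Downstream sample-size analysis is base-invariant
  because recovery depths compare a curve to a fraction of its own final
  value.
- Simpson is reported as the Gini-Simpson form `1 − Σ p_i²` (the
  probability two random reads differ), again the common toolchain
  default; inverse Simpson `1/Σ p_i²` is available.
- Chao1 `S_obs + F1²/(2 F2)` from singletons/doubletons, with the
  bias-corrected form `S_obs + F1(F1−1)/(2(F2+1))` used when `F2 = 0`
  or on request.
- ACE with rare-count threshold 10 (the standard convention; the
  threshold is a parameter), coverage `C = 1 − F1/N_rare`, and the
  coefficient-of-variation term floored at zero. Coverage zero (all
  rare individuals singletons) is an error, not a number.

## Rarefaction and sample-size sufficiency

Rarefaction is subsampling **without replacement** (multivariate
hypergeometric), not multinomial resampling: the curve at full depth then
reproduces the direct index exactly, which anchors the whole analysis.
Depth schedules are arithmetic, `min(k·step, max_depth)` for
`k = 1..n_steps`; two presets mirror the contrast under study — a deep
schedule for Shannon (step 250, 200 steps, to 50,000 reads) and a shallow
one for Simpson (step 80, 50 steps, capped at 3,600 reads; the cap wins
over the step count). Each depth averages 10 replicate subsamples by
default (replicate SD is retained); whether historical curves used
averaging or single draws is rarely documented, so the count is a
parameter.

For each sample the *final value* is the curve value at the deepest
evaluated depth — deliberately not an extrapolated asymptote. The
*recovery depth* `n_q` is the smallest scheduled depth from which the
curve stays at or above `q` times the final value (sustained,
last-crossing semantics: replicate noise can produce transient crossings,
and requiring the crossing to hold for all deeper depths makes the
statistic deterministic and conservative). The *asymptoticity ratio*
`(D_max − n_q)/D_max` measures how early the index stabilised; samples
can be filtered at ratio > 0.5 or > 0.7 (computed at q = 0.95) before
recovery depths are aggregated as mean ± 1.96·SD/√n. This is a
**between-sample** interval — it describes the dispersion of per-sample
recovery depths. A per-sample, rarefaction-replicate interval is a
different quantity; both are computable here and are never conflated.

## Taxon tables, unspecific groups, composition

Tables are taxa × samples counts with full seven-rank lineages.
Aggregation to a rank sums rows over shared lineage prefixes and
conserves per-sample totals. "Unspecific" catch-all labels
(`environmental samples`, `unclassified`, `No hits`, `Not assigned`) and
non-bacterial lineages are removed before any between-sample comparison:
such bins pool reads from heterogeneous groups and would bias
comparisons. Percentages are computed over the clearly-identified
bacterial reads at the rank in question (the raw-denominator variant is a
flag away). Composition is summarised per taxon as mean percent, sample
SD, and NSD = σ/x̄ (the coefficient of variation); NSD is flagged
undefined at mean zero rather than forced to a number.

Common-taxa analysis retains samples whose raw totals strictly exceed a
read threshold (typical thresholds 100 / 1,000 / 5,000 / 10,000), then
reports the union (everything detected) and the intersection (present in
every retained sample) of clearly-identified taxa per rank. "Common"
means presence (count > 0); no abundance floor is imposed.

## Paired differential screen

Treated samples are compared only to their own control, per rank:

1. restrict to taxa present in both members of the pair (after
   unspecific-group removal) — absence of a rare taxon from one sample is
   overwhelmingly a sampling artefact at these depths;
2. omnibus likelihood-ratio G-test (`G = 2 Σ O ln(O/E)`, df `K−1`) on
   the 2 × K common-taxa profile;
3. only if the omnibus rejects at α: per-taxon 2 × 2 post-hoc tests of
   the taxon against the sum of the other common taxa — two-sided Fisher
   exact and Pearson chi-square (no continuity correction by default;
   Williams and continuity corrections are options);
4. Holm-Bonferroni step-down across the K taxa of the (pair, level)
   family; a taxon is flagged when its Holm-adjusted smaller post-hoc
   p-value falls below α = 0.05.

The family for the multiplicity correction is the (pair, level) set of
common taxa. Alternatives (families spanning levels, or all pairs) are
defensible; per-(pair, level) is the narrowest family consistent with the
gating omnibus and is what the tally statistics assume. The omnibus gate
plus Holm makes the screen conservative: on exchangeable null pairs the
family-wise false-positive rate sits well below α (measured by the
acceptance script). Direction and magnitude (log2 proportion ratio and
percent-point difference) are relative to the common-taxa denominator.
Change summaries tally, per treatment / rank / collection time (t1 early,
t2 late), the number of significant taxa, the affected share, and the
mean |log2 ratio| — more aggressive treatments produce larger tallies,
consistently across ranks.

## Indicator values

For taxon *t* and group *g*: specificity `A = mean abundance in g /
Σ over groups of group means` and fidelity `B = fraction of g's samples
containing t`; the indicator value is `√(A·B)` by default (the later
square-root convention) or classic `A·B`. The two variants rank taxa
identically. Significance: permute group labels over samples; the
statistic is the taxon's best-group indicator value;
`p = (1 + #{permuted ≥ observed}) / (n_perm + 1)` (exact by the add-one
rule), with exhaustive enumeration of all distinct relabellings whenever
there are no more of them than requested permutations (then `p = hits /
#relabellings`, observed labelling included). The common-taxa-restricted
variant drops taxa absent from any sample before testing — indicators
driven by possibly-missed-by-chance absences are exactly the false
positives the paired screen is designed to avoid. No group-size
equalisation is applied beyond the group-mean definition of A (a
documented limitation; some formulations reweight groups).

## Synthetic communities

The generator emulates the statistical structure of classified soil
amplicon data, not reads:

- **Abundances**: log-normal, `exp(N(0, σ²))` normalised, default
  σ = 2 — a few dominant taxa and a heavy rare tail (most taxa below the
  mean share), matching the shape of soil communities with thousands of
  species. σ = 0 degenerates to uniform.
- **Taxonomy**: random seven-rank lineages whose labels embed their
  ancestor path (so equal prefixes always mean equal ancestors), with
  tens of phyla and roughly n/3 genera at n = 2,000 taxa; 30% of taxa by
  default carry unspecific labels at genus/species (the typical
  unclassifiable fraction), plus small Archaea (1%) and Eukaryota (2%)
  admixtures to exercise the domain filter. Taxa pooled into the same
  catch-all bin are merged, as a classifier would.
- **Pairs**: each pair draws a control composition centred on the base
  proportions and a treated composition centred on the fold-change
  perturbed proportions (multiply, renormalise), then multinomial counts
  at a fixed depth (default 10,000 reads, in the middle of the read-count
  range such studies analyse). Site-to-site variability is a
  Dirichlet-multinomial with one concentration parameter; the default is
  **no site noise** (concentration = ∞), because the paired screen's null
  calibration presumes treated/control exchangeability under no effects —
  finite concentrations are opt-in for studying robustness.

What the generator does **not** emulate: sequencing error, chimeras,
primer/region effects, phylogenetically correlated responses, or
compositional correlations between taxa beyond the Dirichlet. Passing
tests therefore certify the statistical machinery under the stated
sampling model, not classifier behaviour on real reads.

## Numerical conventions

- All randomness flows from explicit integer seeds through
  `numpy.random.Generator`; same seed, same output, bit for bit.
- Holm rejection is strict (`adjusted p < α`); the zero-row 2 × 2
  convention is Fisher p = 1 and chi-square undefined (NaN).
- Chao1's classic form falls back to bias-corrected when `F2 = 0`
  (logged); degenerate inputs (empty samples, zero-coverage ACE,
  zero-final-value curves, zero marginals) raise typed errors instead of
  returning numbers.
- Aggregated CIs use 1.96·SE by default with a t-quantile option.

## Problem sizes in the distributed checks

The test suite and the acceptance script run the full method at the
scale the analyses are designed for — 2,000-taxon communities, 50,000
reads for rarefaction, 10,000 reads per screened sample — with replicate
counts (20 communities, 500 null pairs, 20 power seeds, 200 IndVal
replicates) chosen so that Monte-Carlo standard errors are small relative
to the asserted margins.

## Known limitations

- Recovery depths are quantised to the depth schedule; a coarse step
  size inflates them upward by up to one step.
- The G-test's chi-square reference is asymptotic; with hundreds of
  sparse common-taxa cells it is conservative in our regime, but its
  small-sample behaviour is table-dependent (Williams correction
  available).
- IndVal's permutation test conditions on the observed group sizes; with
  very few samples the p-value granularity (1/#relabellings) limits
  attainable significance.
- Percent composition is compositional data; the screen works on
  within-pair proportions and does not attempt CLR-style transforms.
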