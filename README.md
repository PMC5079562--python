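# rhizoindic

Tools for finding **rhizobacterial ecological indicators** in 16S
amplicon taxon tables — for microbial ecologists who want to know which
community summaries are actually trustworthy at the sequencing depths
their soil samples have.

Soil health tracks the root-associated bacterial community, but the
standard summaries behave very differently with sample size. This
package implements the full chain of analyses needed to evaluate them:

- **Sample-size sufficiency of diversity indices.** For an index
  rarefaction curve, the recovery depth `n_q` is the smallest depth from
  which the curve stays above `q` × its final value, and the
  asymptoticity ratio `(D_max − n_q)/D_max` says how early it
  stabilised. Aggregated over samples (mean ± 1.96·SD/√n, with ratio
  \> 0.5 / \> 0.7 filters), these quantify how many reads Shannon
  `H = −Σ p_i log₂ p_i`, Gini-Simpson `1 − Σ p_i²`, observed richness,
  Chao1 and ACE need before their values mean anything.
- **Common-taxa analysis.** Union and intersection of
  clearly-identified bacterial taxa across samples above read
  thresholds, after removing "unspecific" catch-all groups
  (`unclassified`, `environmental samples`, `No hits`, `Not assigned`)
  and non-bacterial lineages.
- **Composition variability.** Per-taxon mean percent, SD and
  NSD = σ/x̄ across samples at every rank.
- **Paired differential screen.** Each treated soil against its own
  control: omnibus G-test (`G = 2 Σ O ln(O/E)`) on the common-taxa
  profile, gating per-taxon Fisher-exact / χ² post-hoc tests under
  Holm–Bonferroni at P < 0.05, with per-treatment / per-time change
  tallies as an aggregate stress indicator.
- **Indicator values.** IndVal = √(A·B) (specificity × fidelity) with
  an exact permutation test, including the common-taxa-restricted
  variant.
- **Synthetic communities with known ground truth** — log-normal
  abundances, realistic taxonomies with an unclassifiable fraction,
  paired control/treatment designs with configurable fold-changes — so
  every statistical claim above is testable end to end.

See `docs/methods.md` for the models, conventions and their rationale.

## Worked example

```python
import numpy as np
import rhizoindic as ri

# one synthetic soil community: 2,000 taxa, log-normal abundances
base = ri.draw_abundances(2000, lognormal_sigma=2.0, seed=7)
counts = np.random.default_rng(8).multinomial(50_000, base)

print(ri.shannon(counts), ri.gini_simpson(counts), ri.chao1(counts))
# 8.477 bits, 0.9932, 1760.9  (1,584 taxa observed)

curve = ri.rarefaction_curve(counts, ri.SHANNON_SCHEDULE, ri.shannon,
                             index_name="shannon", sample_id="soil01")
rec = ri.analyze_curve(curve)
print(rec.n95, rec.n99, rec.ratio95)
# 2000 11750 0.96
```

Shannon needs ~2,000 reads to come within 5% of its deep value and
~12,000 to come within 1% — while the same sample's Gini-Simpson curve
(shallow 80 × 50 schedule) recovers 99% by 160 reads. Simpson saturates
so early that it ignores the rare taxa; Shannon sees them but demands an
order of magnitude more sequencing.

The paired screen, on a pair where one clearly-identified taxon at 10%
abundance was quadrupled (10,000 reads per sample):

```python
res = ri.paired_differential(exp.table, pair, level="species")
# omnibus G = 1524.3 (df 523), p = 1.46e-98; 524 common taxa tested
# 3 taxa flagged; target: increase, log2 ratio 1.42, Holm p = 4.4e-251
```

The injected effect is recovered with the right direction; the log2
ratio (1.42 rather than 2.0) reflects the renormalisation a 10% taxon's
quadrupling imposes on closed compositions.

A `rhizoindic` command-line interface mirrors the library
(`simulate`, `diversity`, `rarefy`, `asymptoticity`, `composition`,
`common-taxa`, `diffcomp`, `indval`); every stage reads and writes TSV.

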