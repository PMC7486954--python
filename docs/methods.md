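# Methods

This note documents the models and numerical choices behind `mutacc`:
what each estimator assumes, what the synthetic generator does and does
not emulate, and where the design was genuinely open.

## Rate model

A mutation-accumulation line accumulates de novo substitutions as a
Poisson process over *site-divisions*. For line *i* with `callable_i`
confidently genotypable positions and `gen_i` cell divisions, a diploid
cell exposes `2 · callable_i · gen_i` site copies; the pooled estimator is

    mu = N / E,      E = ploidy · Σ_i callable_i · gen_i

with N the pooled accepted-mutation count. The diploid factor is part of
the exposure because every position can mutate independently on either
homolog, and the filters are designed around heterozygote detection
(the 1/3 alt-fraction minimum only makes sense for a diploid de novo
call).

Confidence intervals are exact Garwood intervals,

    low  = χ²(α/2, 2N) / 2E          (0 when N = 0)
    high = χ²(1 − α/2, 2(N+1)) / 2E,

which guarantee at-least-nominal coverage for every true rate — the
relevant property when organelle counts are as low as 2. A Wald
(normal) interval is available behind `method="normal"` for comparison;
it is anti-conservative below N ≈ 30.

Per-genome rates are products, U = G·µ and U_cds = C·µ, treating the
genome and coding sizes as known constants.

**Per-line heterogeneity.** The χ² test compares per-line counts with
expected counts under a shared rate. Two nulls are implemented:
`exposure` (default) weights the total by each line's share of
Σ callable·gen; `equal` splits it evenly. The two are identical when
exposures are equal and differ by a few χ² units on realistic tables.
Both are reported because neither convention is universal in the MA
literature, and on the bundled study table they give 80.25 and 64.73
(df = 14) respectively — the choice does not affect the conclusion that
among-line variation exceeds Poisson expectation.

**Organelle rates.** Organelle genomes are present in many copies per
cell; the exposure is `copies · organelle_length · Σ gen_i` with the
copy number estimated from relative read coverage
(`ploidy · cov_org / cov_nuc`) and treated as fixed (no error
propagation — the Poisson noise at single-digit counts dominates any
plausible copy-number uncertainty). Rate comparisons between
compartments use a 2×2 Pearson χ² of counts against remaining
exposures, without continuity correction, df = 1.

## Calling filters

A site is callable for a line when MQ ≥ 20 and depth is within
[20, 150] in *both* the line and the ancestor. The depth cap excludes
collapsed repeats; it is applied symmetrically to both samples because
a repeat collapsed in either alignment corrupts the genotype
comparison. A candidate in a line is accepted when, in order: MQ,
minimum depth, maximum depth, alt fraction ≥ 1/3 of total depth
(inclusive at exactly one third), distance to the nearest indel record
> 5 bp, alt allele absent from the ancestor, and absent from every
other line. The first failing criterion becomes the recorded rejection
reason, so every rejection has exactly one cause and synthetic-artifact
audits can be matched reason-for-reason.

The cross-sample uniqueness criterion operationalises what a manual
pileup inspection accomplishes: a variant shared by the ancestor or by
multiple independently propagated lines cannot be an independent de
novo event (it is either ancestral standing variation or a systematic
artifact). This loses genuinely recurrent de novo mutations; at
realistic rates (455 events over 1.7×10⁸ sites) the expected number of
recurrences is ≪ 1.

**Effect classification** translates the annotated reading frame on the
coding strand. Precedence when several annotations apply:
splice_region > start_lost > stop_gained > missense > synonymous > UTR
> intron > intergenic. The splice region is defined as ±3 bp around
each exon–intron junction; the width is a parameter
(`FilterParams.splice_window`) since annotation conventions vary, and 3
bp is the conventional core. A substitution destroying a terminal stop
codon is classed missense (no dedicated stop-lost class is kept, as it
is vanishingly rare at MA scale).

## Mutation spectrum and GC equilibrium

Substitutions are folded into six strand-symmetric classes (T→C ≡
A→G = A:T→G:C, etc.). With GCn and ATn the G:C and A:T site counts of
the reference space (callable subset when masks are supplied, whole
genome otherwise), the conditional rates are R1 = n(GC→AT)/GCn and
R2 = n(AT→GC)/ATn, and the mutation process alone drives the base
composition to the fixed point

    GC_eq = R2 / (R1 + R2),

where the two fluxes balance. GC_eq is invariant to the common
proportionality constant of R1 and R2, so counts can be divided by
fractions rather than site numbers. A forward simulation
(`simulate_gc_equilibrium`: independent two-state per-site chains with
hazards ∝ R1, R2) is used in tests to confirm the fixed point to within
one percentage point after ~10⁶ site-events.

The ts/tv ratio k is reported only when at least one transversion is
observed, and flagged undefined otherwise. The GC-bias test is an exact
two-sided binomial test of the two flux counts against 50:50. The CpG
analyses use a base-independence null with equal C and G frequency
(expected CpG dinucleotide fraction (GC/2)²) and, at the mutation
level, the fraction of C sites (either strand) in CG context.

## Codon bias and selection strength

ENC follows Wright: per amino acid with k synonyms observed n times,
F̂ = (nΣp̂² − 1)/(n − 1); ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆, the
averages taken within degeneracy classes, a missing 3-fold class (Ile
absent) imputed as the mean of the 2- and 4-fold averages, capped at
61. The finite-sample term makes ENC scale-*near*-invariant only:
multiplying all counts by a constant moves ENC at O(1/n), which the
tests assert at large n rather than exactly. Genes under 100 codons
are flagged low-confidence; genes with internal stops are excluded
from ENC.

Preferred codons are identified without correspondence analysis: genes
are ranked by ENC, the most- and least-biased 5% tails form high/low
sets, and per amino acid a two-way χ² contingency test (codon × set,
α = 0.01) followed by the largest positive enrichment picks the
preferred codon (ties or non-significance → none). This keeps the
5%-tail structure and the χ² criterion of the classical CodonW
workflow while replacing its ordination step, which adds nothing when
the goal is the preferred set itself.

Fop is the pooled frequency of preferred codons among codons of amino
acids that have one, over a gene subset (top-N by expression when an
expression table is supplied). For the eight two-codon amino acids
whose preferred codon is GC-ending (Phe, Tyr, His, Gln, Asn, Lys, Asp,
Glu), mutation towards the preferred codon runs at the AT→GC rate and
away at the GC→AT rate, so at mutation–selection–drift equilibrium the
preferred-codon frequency P satisfies P/(1−P) = e^S / b with
b = µ(GC→AT)/µ(AT→GC), giving

    S = ln[(P/(1−P)) · b]        and        Ne = S / 4s.

S is computed from the single pooled Fop over the eight families (not
per-family averaged): pooling matches how a single printed Fop maps to
a single S. The bias ratio b is used unrounded from the spectrum
module (0.38083…); rounding b to 3 decimals shifts S in the fourth
decimal. The estimator asserts that the preferred codons it is given
are GC-ending, since the equilibrium inversion is directional.

## Population-genetic syntheses

Nₑ = π_s/4µ assumes neutral mutation–drift equilibrium at synonymous
sites in a diploid. The clock rate is µ_year = d_s/2T (divergence
accumulates along two lineages). Generations per year in the wild
follow as g = µ_year/µ_gen with days/generation = 365/g; a lower bound
on the wild per-generation rate is µ_year divided by the maximal
generations per year (300, from the fastest observed lab division rate
of ~1.17/day). Note the two rate scales are measured independently —
µ_year from fossil-calibrated divergence, µ_gen from the MA
experiment — so g is a genuine inference, not an identity.

Bottleneck arithmetic: a culture founded by one cell that reaches N
cells in t days has made log₂N divisions (deterministic doubling, no
death — sufficient for generation counting). Harmonic-mean Nₑ is taken
over daily censuses of all cycles, including each cycle's founding
single cell (day 0) through day 13; the day-14 transfer census
coincides with the next founding dilution. At 1.17 divisions/day this
gives H ≈ 7.8 per 14-day cycle. The cross-species Nₑ–µ correlation is
Pearson's r on log₁₀ scales by default (the compilation spans five
orders of magnitude); a raw-scale mode exists.

## Synthetic generator

The generator emulates the statistical structure the estimators
assume, at desk scale:

- **Genome**: a single contig (default 1 Mb, GC 65.7%) with
  non-overlapping gene models (UTRs, 1–3 CDS exons, 60 bp introns),
  genes implanted as valid ORFs; intergenic composition is rebalanced
  after implanting so genome-wide GC hits the target within binomial
  noise.
- **Mutations**: per-line counts Poisson(2·L·gen·µ); class from the
  6-class spectrum; site uniform among matching reference bases;
  infinite-sites (unique positions per line, warning near saturation).
  Default weights (155, 84, 48, 52, 67, 49 for A:T→G:C, G:C→A:T,
  A:T→T:A, A:T→C:G, G:C→T:A, G:C→C:G) reconstruct the published pooled
  constraints: 207 AT→GC vs 151 GC→AT and ts/tv = 239/216 ≈ 1.11. The
  individual transition/transversion split within each flux is not
  published at desk scale, so it was fixed once to these values.
- **Variant calls**: true mutations appear heterozygous (alt depth
  binomial at 0.5, truncated into the callable/accepted region — the
  generator's truth is *callable* truth, so filter sensitivity is
  measured where a caller could see the event). Six artifact classes
  (low MQ, low/high depth, low alt fraction, indel-proximal, ancestral
  shared) are injected at Poisson counts and labelled in an audit
  table; each is constructed to fail exactly its own criterion.
- **Growth**: deterministic exponential doubling at 1.17 divisions/day
  in 14-day cycles (default 14 cycles → 229 generations/line,
  matching the study's 200–291 range); no death, no selection.
- **Codon usage**: two-codon families sit at the analytic equilibrium
  (P from S_true and b; neutral S = 0 outside a configurable
  high-expression stratum); other families get a third-base GC bias
  (default 0.842). Expression is log-normal with the high stratum
  shifted.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: read-level errors and mapping ambiguity
(depth and MQ are drawn, not aligned), linked or clustered mutations,
selection during propagation, context-dependent (e.g. CpG) rate
variation, indel mutations themselves, and real expression–bias
coupling beyond the two-stratum contrast.

## Numerical and scale choices

- Chi-square quantiles, binomial tests and correlations come from
  scipy.stats; the Garwood construction, spectrum folding, ENC and the
  S inversion are implemented here.
- Stochastic test scales were chosen to make Monte-Carlo error small
  against each tolerance: 500 draws per λ for CI coverage (binomial SE
  ~1% at 95%), 200 replicate experiments at 1 Mb/15 lines/µ = 10⁻⁷ for
  rate recovery (~600 mutations each), ~10⁵ pooled two-codon draws for
  S recovery (SE(S) ≈ 0.012 against a 0.05 band), and ~10⁶ site-events
  for the GC_eq fixed point (drift ≪ 1 percentage point).
- Degenerate inputs fail loudly: zero exposure, GC ∈ {0, 1},
  Fop ∈ {0, 1}, empty censuses and constant series raise or flag
  rather than returning infinities.
- All randomness flows through `numpy.random.Generator`; a
  `SimulationConfig.seed` makes a full synthetic run bit-for-bit
  reproducible, including the written VCF.

## Known limitations

- The heterogeneity χ² conventions implemented here need not match
  every published per-line test; with overdispersed counts the exact
  null expectation matters, and both implemented modes are reported.
- `estimate_generations` assumes a clean single-cell founding and no
  death; real censuses include counting error the model ignores.
- The effect classifier handles one transcript per gene and
  substitutions only.
- The preferred-codon caller needs tens of genes per tail; it is a
  genome-scale tool, not a per-gene one.
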