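# Methods

This note documents the models implemented in `domchemo`, their assumptions,
the defaults that matter, and the design choices made where the science
leaves room. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model

The pipeline starts from *assigned* peak lists: tables of molecular formulae
(CcHhOoNnSsPp compositions, no structural information) with one intensity
column per sample, plus sample metadata (lake ∈ {alpine, subarctic},
treatment ∈ {control, s_above, s_below}, timepoint in hours, replicate,
role ∈ {sample, blank}). Raw spectrum processing, peak picking and formula
assignment are instrument-vendor territory and out of scope; everything the
pipeline computes is defined on (formula, intensity) tables. Files are
comma-separated UTF-8 text with a header row. Intensities are non-negative
floats; 0 means "not detected or zeroed by a filter" (the two are
distinguished only in the dataset's provenance log).

## Formula validity

A formula is accepted when all of the following hold: element counts within
C 1–40, H 1–82, O 1–40, N 0–4, S 0–1, P 0–1; O ≤ C; 0.3 C ≤ H ≤ 2 C + 2;
O > 2 P + S; and, when two or more distinct heteroatom elements (N, S, P)
are present, the (N, S, P) signature is on a whitelist of multi-heteroatom
combinations (N·S·P, N₂·S, N₃·S, N₄·S, N₂·P, N₃·P, N·S₂, N₂·S₂, N₃·S₂,
N₄·S₂, S₂·P). Two interpretation choices:

* Formulae with zero or one heteroatom element are always allowed (subject
  to the count caps). The whitelist constrains *combinations*; CHO-N and
  CHO-S formulae dominate real lake-water assignments and cannot plausibly
  be excluded.
* Whitelist entries implying S = 2 are unreachable under the S ≤ 1 cap; the
  explicit element ranges win.

Validity is a pure function of the counts; invalid inputs return reasons
rather than raising.

## The QC cascade

Order-fixed, each stage idempotent, never increasing any intensity, each
recording itself in the provenance log:

1. **Validity screen** — rows failing the rules above are dropped.
2. **Blank/contaminant removal** — any formula with intensity > 0 in any
   blank sample, or present on a user-supplied contaminant list, is dropped
   from all samples. Blank columns are consumed here and removed.
3. **Intensity floor** — per sample, peaks strictly below 10⁻⁴ of the
   column sum are set to zero. Column sums are computed once, before any
   zeroing (a single pass, no iteration); a peak exactly at the floor is
   retained, following the strict inequality.
4. **Replicate presence** — within each (lake, treatment, timepoint) group,
   a formula present (intensity > 0, evaluated after flooring) in fewer than
   min(2, group size) replicates is zeroed across the group; rows all-zero
   everywhere are dropped. Groups with a lost replicate use their own size
   as the threshold rather than failing, since a rule demanding 2 of 2 is
   still evaluable; a strict mode raises instead.
5. **Normalization** — each column is divided by its sum, giving relative
   intensities; an all-zero sample column is an error naming the sample.

The brute-force reimplementation of this cascade in the test suite (plain
dictionary loops) is the correctness oracle; the pipeline must reproduce its
surviving formula set on thousands of randomized fixtures.

## Descriptors and classification

DBE = 1 + C − H/2 + N/2 + P/2. AI_mod = (1 + C − ½O − S − ½H) /
(C − ½O − N − S − P), clamped to 0 when the denominator is non-positive or
the numerator negative. NOSC = 4 − (4C + H − 3N − 2O + 5P − 2S)/C. These are
the standard forms used throughout FT-ICR MS DOM work.

The four classes are assigned in precedence order: H/C ≥ 2 → saturated;
else H/C ≥ 1.5 → unsaturated; else AI_mod > 0.5 → aromatic; else highly
unsaturated. Boundary ties follow the printed inequalities literally
(H/C = 1.5 is unsaturated; AI_mod = 0.5 is highly unsaturated). The aromatic
class conventionally ends at AI_mod = 0.67, above which compounds are
condensed aromatics; to keep the classification total these are assigned to
"aromatic" and flagged separately (`condensed_aromatic`). Note that AI_mod
can mathematically exceed 1 for very hydrogen-poor, nitrogen-rich
compositions; it is clamped below at 0 but deliberately not clamped above.

The eight categories refine the classes: saturated compounds split into
fatty acids CHO vs CHOX by heteroatom content; unsaturated and highly
unsaturated compounds split into oxygen-rich vs oxygen-poor at O/C = 0.5
(the community convention; configurable, since no canonical cutoff exists);
aromatics split into polyphenols (O/C ≥ 0.5) vs oxygen-poor polyphenols.

## Enrichment

Enrichment of a formula in a treatment is (I_T − I_C)/I_C × 100 on replicate
means of normalized relative intensities, with I_C = 0 and I_T > 0 mapped to
100 % ("new" compound) and both-zero undefined (excluded). "Enriched" means
any positive enrichment — no minimum fold change is imposed, though the
threshold is configurable. Controls are matched by lake (and timepoint when
one is requested; by default all timepoints are pooled into the means, and
the output metadata records which). The summary fraction divides the
novel-or-enriched count by the number of formulae detected in the lake-water
control.

## Chemodiversity

The index treats the DOM pool the way community phylogenetics treats a
species assemblage. One dendrogram is built on the union of all formulae in
the dataset and shared by all samples, so that all estimates live in a
common metric space:

* **Distance** — Gower's distance over five numeric descriptors (O/C, H/C,
  molecular mass, AI_mod, DBE; each contributing |xᵢ−xⱼ|/range) and one
  categorical (the eight-way category; 0/1), averaged unweighted. Constant
  numeric variables are dropped with a warning.
* **Tree** — average linkage (UPGMA), which yields an ultrametric dendrogram
  matching the phylogenetic analogy; `complete` and `ward` are accepted
  alternatives. Tie-breaking follows scipy's deterministic
  earliest-cluster-index rule, so runs are reproducible across platforms.
* **Statistic** — the default diversity of a compound set is the total
  branch length of the minimal subtree spanning it, excluding branches above
  the set's most recent common ancestor; a single compound has diversity 0.
  This is the canonical tree-based diversity measure (Faith-style). The mean
  pairwise cophenetic distance is implemented as an alternative
  (`statistic="cophenetic"`) since "pathlength" admits both readings.

Because pathlength grows with the number of compounds and detection depends
on total signal, two equalizations precede estimation, in this order:

1. **Intensity rarefaction** — per sample, compounds are drawn without
   replacement with probability proportional to raw intensity until the
   cumulative intensity first reaches the lowest per-sample total in the
   dataset (the crossing draw is kept, so the target may be overshot by one
   compound). Samples at the minimum keep everything. This needs raw
   (pre-normalization) intensities, which is why the QC stage also exports
   the filtered, unnormalized matrix.
2. **Fixed-size subsampling** — per iteration, min(subsample_size, set size)
   compounds are drawn uniformly without replacement and the statistic
   computed; defaults are 3000 compounds × 100 iterations. If a presence set
   is not larger than the subsample size, every iteration uses the whole set
   and the zero-variance estimate is flagged degenerate. Choose the
   subsample size below the smallest rarefied presence set if the
   between-sample comparison is the goal.

The estimates deliberately ignore intensity: they respond to the presence or
absence of chemically distinct moieties. Rescaling all samples by a common
factor leaves them bit-identical. Rao's quadratic entropy
Q = Σᵢⱼ dᵢⱼ pᵢ pⱼ on the same Gower matrix is provided as the
intensity-weighted counterpart; on synthetic data the two correlate
positively across samples.

Percent change versus control is computed per (lake, treatment, timepoint)
as 100 (mean_D_T − mean_D_C)/mean_D_C with means over replicates and
iterations, plus a per-treatment temporal trend (first to last timepoint of
the treatment's own estimates).

## Kinetics

**Bulk.** The reactivity continuum model treats DOC as a continuum of
compounds with first-order rates distributed Gamma(shape = ν, rate = α) at
t = 0. Integrating e^(−kt) over that distribution gives
DOC(t)/DOC(0) = (α/(α+t))^ν — this parameterization is the unique one with
that closed form, and it is the analytic bridge the generator and tests
exploit. α (time units) is the apparent initial age of the most reactive
compounds, ν (dimensionless) the predominance of recalcitrant material; the
instantaneous rate is k(t) = ν/(α+t), so k₀ = ν/α. Fitting is nonlinear
least squares from a 5 × 6 multi-start grid (α ∈ {0.01, 0.1, 1, 10, 100},
ν ∈ {10⁻⁶, 0.05, 0.1, 0.5, 1, 2}; both bounded below by 10⁻⁸; best residual
sum of squares wins) because the RSS surface is ridge-prone — in the
no-decay limit α and ν trade off along a plateau, and the near-zero ν start
is what lets a constant series resolve to ν → 0. Standard errors come from
the Jacobian at the optimum. An increasing series warns but is still fitted.

**Per compound.** First-order rates during the short incubations are the
slopes of ln(relative intensity) against time, fitted per replicate by
ordinary least squares — deterministic, closed-form and directly testable; a
compound is fitted in a replicate only if its intensity is positive at every
timepoint (≥ 3 timepoints), and is *validated* only when every replicate of
its group fits with slope p < 0.05 (configurable). The reported rate is the
mean of replicate slopes; negative rates are degradation, positive rates
accumulation of degradation by-products. Because the series are relative
intensities, all slopes within a sample share an additive offset equal to
the decay rate of the total signal; correlations with true per-compound
rates are unaffected, but absolute rates are relative to the bulk trend —
the same caveat applies to any normalized-intensity kinetics.

**Bacteria.** BGE = BP/(BP + BR) on carbon-unit rates, undefined (NaN) when
both are zero. A helper converts an oxygen drawdown slope to respiration
with a configurable respiratory quotient (default 1.0 mol CO₂ per mol O₂).

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, with
complete ground truth (per-formula origin label, true decay rates, true
(α, ν), true enrichment status per treatment).

* **Design** — 2 lakes × 3 treatments × 4 in situ timepoints (0, 6, 24,
  72 h) × 3 replicates, plus one blank per lake; long-term timepoints 0,
  0.5, 1, 3, 5, 7, 12, 22, 40, 58, 81 d.
* **Formula universe** — candidates are rejection-sampled over the allowed
  element ranges and drawn by category weights. The default core pool
  (2500 formulae) is dominated by highly unsaturated material with few
  polyphenols, as in clear-water alpine and subarctic lakes.
* **Overlap** — amended samples contain the core pool plus treatment
  additions; the default added count follows from the target shared
  fraction 0.865 (core/(core+added)), within the 85–88 % range typical of
  such experiments.
* **Amendment chemistry** — each added formula is either *nested* (a nearest
  chemical neighbour of one of ~12 core anchor compounds — soil DOM is
  chemically coherent, so additions pile up in a few neighbourhoods) or
  *novel* (drawn by category bias). Defaults: S-Above nestedness 0.85 with
  saturated/unsaturated, heteroatom-rich bias; S-Below nestedness 0.10 with
  polyphenolic/highly-unsaturated bias. These encode the mechanism the
  amendment design probes: local soil resembles what the lake already
  receives; below-treeline soil brings chemically novel moieties.
* **Enrichment of existing compounds** — a treatment-specific fraction of
  core formulae (8 % for S-Above, 28 % for S-Below) is intensity-boosted
  2.5×, so the novel-or-enriched fractions land in the ~25 % vs ~45 % regime
  the amendment contrast produces.
* **Kinetics** — per-compound rates are Gamma(shape = ν, rate = α) draws
  with α = 5 d, ν = 0.3 by default (a moderately reactive lake-water pool:
  ~13 % bulk DOC loss over 3 d, ~57 % over 81 d); 10 % of compounds
  accumulate instead of decaying. Draws are *stratified* by default —
  shuffled mid-probability Gamma quantiles — a variance-reduced sample with
  the exact marginal whose mixture of exponentials converges to the closed
  form far faster than i.i.d. draws (the 5000-compound mixture matches
  (α/(α+t))^ν to well under 1 % at all long-term timepoints, where an
  i.i.d. sample of that size would not).
* **Intensities** — per-formula base intensities are log-normal (σ = 1);
  replicate noise is multiplicative mean-1 log-normal with configurable CV
  (default 0.2), keeping zeros exact. Each sample column is then rescaled to
  a common injected-signal level — amended samples 10 % hot — mirroring
  FT-ICR MS practice where comparable SPE-DOM amounts are injected. Column
  scaling leaves normalized intensities, enrichment and rate fits untouched;
  it only keeps the intensity-rarefaction step exercised but mild.
* **Long-term DOC** — the bulk curve is the mixture sum of the per-compound
  exponentials, by default with equal initial carbon weights (so it
  converges to the closed form; intensity weights are available), plus an
  independently noised observed series for fitting tests.
* **Bacterial rates** — log-normal draws around treatment/lake means with
  S-Above sustaining higher production and growth efficiency than S-Below.

What the generator does *not* emulate: mass-dependent detection limits and
calibration drift, isotopologues, photodegradation and freeze–thaw
processing, correlated (non-log-normal) replicate structure, and chemically
structured decay (true rates are independent of a compound's descriptors).
Passing tests therefore demonstrate that the estimators recover known
structure of this statistical form — not that real soil amendments behave
this way.

## Problem sizes and determinism

The test suite and the acceptance script run the full pipeline at moderate
sizes (hundreds to ~1200 core formulae, 60-iteration chemodiversity with the
subsample set to about half the core pool) — large enough for stable Monte
Carlo behaviour on a single CPU, and the methods scale unchanged to
full-size tables. Every stochastic entry point takes an explicit seed;
sub-seeds are derived per sample so results do not depend on column order,
and a fixed master seed makes each stage bit-reproducible.

## Known limitations

* Blank subtraction is presence-based (any blank detection removes the
  formula); no abundance-ratio criterion is offered.
* The replicate-presence rule is applied per (lake, treatment, timepoint)
  group; applying it across the whole experiment instead would retain more
  formulae.
* Per-compound kinetics assume log-linear decay over four timepoints;
  compounds following other kinetics simply fail validation.
* Rao's Q uses the same Gower matrix as the dendrogram; it is a comparison
  index, not an independent measurement.
* The enrichment threshold (any positive change) makes the enriched set
  sensitive to normalization shifts when many compounds change at once.
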