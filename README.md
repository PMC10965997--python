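# domchemo

Molecular-level analysis of dissolved organic matter (DOM) for soil-amendment
experiments tracked by ultra-high-resolution mass spectrometry (FT-ICR MS).

Lakes above the treeline receive soil-derived organic matter whose chemistry
depends on where in the catchment it formed. When lake water is amended with
soil extracts — from above the treeline (S-Above) or from below it (S-Below) —
FT-ICR MS resolves thousands of molecular formulae whose fate can be followed
over incubation timepoints, alongside bulk dissolved organic carbon (DOC) and
bacterial activity. `domchemo` is the analysis layer for such experiments,
aimed at aquatic biogeochemists working with assigned peak tables:

* **Formula QC** — assignment-validity rules over CcHhOoNnSsPp compositions
  (element ranges C1–40 H1–82 O1–40 N0–4 S0–1 P0–1; O ≤ C;
  0.3 C ≤ H ≤ 2 C + 2; O > 2 P + S; a whitelist of multi-heteroatom
  combinations) and the peak-filtering cascade: blank/contaminant removal, an
  intensity floor (peaks < 0.01 % of the sample's summed intensity are set to
  zero), a replicate-presence rule (≥ 2 of 3 replicates), and normalization
  to relative intensities.
* **Molecular descriptors** — O/C, H/C, double-bond equivalents
  DBE = 1 + C − H/2 + N/2 + P/2, modified aromaticity index
  AI_mod = (1 + C − ½O − S − ½H) / (C − ½O − N − S − P), nominal oxidation
  state of carbon NOSC = 4 − (4C + H − 3N − 2O + 5P − 2S)/C, the four broad
  compound classes (saturated / unsaturated / highly unsaturated / aromatic)
  and the eight van Krevelen categories built on them.
* **Enrichment** — per-formula percent change of mean relative intensity in a
  treatment versus its lake-water control,
  (I_T − I_C)/I_C × 100, with compounds absent from the control ("new")
  enriched at 100 %; class and heteroatom summaries of the enriched sets.
* **Chemodiversity** — a presence/absence diversity index on a dendrogram of
  chemical similarity: Gower's distance over O/C, H/C, molecular mass,
  AI_mod, DBE and the categorical compound category; UPGMA clustering; and,
  per sample, the total branch length of the minimal subtree spanning the
  compounds present (pathlength diversity, in the spirit of Faith's
  phylogenetic diversity). Samples are first rarefied by intensity to the
  lowest total signal, then repeatedly subsampled to a fixed number of
  compounds (default 3000 compounds × 100 iterations). Rao's quadratic
  entropy Q = Σᵢⱼ dᵢⱼ pᵢ pⱼ is included as the intensity-weighted comparison.
* **Kinetics** — the reactivity continuum model of bulk DOC decay,
  DOC(t)/DOC(0) = (α/(α+t))^ν (a Gamma(shape = ν, rate = α) mixture of
  first-order decays; initial rate k₀ = ν/α), fitted by multi-start
  nonlinear least squares; per-compound first-order decay/accumulation rates
  from log-linear regression per replicate with cross-replicate validation;
  and bacterial growth efficiency BGE = BP/(BP + BR).
* **Synthetic data** — a generator that emulates the full experimental
  design (2 lakes × 3 treatments × 4 timepoints × triplicates + blanks,
  shared formula pool, class-biased soil additions, log-normal replicate
  noise, Gamma decay rates, long-term DOC series) with complete ground
  truth, so every stage is testable without instrument data.

## Worked example

```python
import domchemo as dc

cfg = dc.SimConfig(n_core_formulae=800, noise_cv=0.1, seed=11)
raw, truth = dc.generate_experiment(cfg)

clean = dc.qc_pipeline(raw)
print(f"post-QC matrix: {clean.intensities.shape[0]} formulae x "
      f"{clean.intensities.shape[1]} samples")

records = dc.enriched_set(clean, lake="subarctic", treatment="s_below")
frac = dc.novel_or_enriched_fraction(records)
print(f"S-Below novel-or-enriched: {records['enriched'].sum()} formulae "
      f"({100 * frac:.1f}% of the lake-water pool)")

bulk, _ = dc.generate_decay_series(truth, seed=11, noise_cv=0.01)
fit = dc.fit_rc_model(bulk["t_d"], bulk["doc_frac_observed"])
print(f"reactivity continuum: alpha = {fit.alpha:.2f} d, nu = {fit.nu:.3f}, "
      f"initial rate k0 = {fit.k0:.4f} /d")

rates = dc.fit_compound_rates(clean)
validated = rates[rates["validated"]]
print(f"first-order compound fits: {len(validated)} validated of {len(rates)}; "
      f"median rate {validated['rate_per_d'].median():.3f} /d")
```

prints

```
post-QC matrix: 1038 formulae x 72 samples
S-Below novel-or-enriched: 346 formulae (45.0% of the lake-water pool)
reactivity continuum: alpha = 5.01 d, nu = 0.300, initial rate k0 = 0.0599 /d
first-order compound fits: 242 validated of 5035; median rate -0.296 /d
```

Reading it: after QC, 1038 formulae survive across the 72 in situ samples.
In the subarctic S-Below amendment, 45 % of the formulae detected in plain
lake water are new or intensity-enriched — below-treeline soil contributes
heavily to the molecular pool. The long-term bulk DOC series is well
described by a reactivity continuum with apparent initial age α ≈ 5 d and
recalcitrance shape ν ≈ 0.30 (initial decay rate ≈ 0.06 d⁻¹; both match the
generator's ground truth). 242 compounds pass a significant first-order
decay fit in every replicate, with a median degradation rate of ≈ −0.3 d⁻¹.

The same pipeline is available from a shell:

```bash
domchemo simulate --seed 11 --out sim/
domchemo qc --in sim/peaks.csv --meta sim/metadata.csv --out qc/
domchemo describe --in qc/matrix.csv --out descriptors.csv
domchemo enrich --in qc/ --lake subarctic --treatment s_below --out enrich.csv
domchemo chemodiv --in qc/ --subsample 3000 --iters 100 --seed 11 --out chemodiv.csv
domchemo kinetics --doc sim/doc_longterm.csv --peaks qc/ --bp-br sim/bp_br.csv --out kinetics/
```

## Documentation

`docs/methods.md` describes the models, their assumptions, the defaults of
the synthetic-data generator and the numerical choices in detail.
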