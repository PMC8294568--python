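# mmpkit — ex vivo microbial metabolic phenotyping of SCFA production

Healthy people differ widely in which short-chain fatty acids (SCFAs —
acetate, propionate, butyrate) their gut microbiota produces from a given
dietary fiber. `mmpkit` implements an end-to-end analysis of that
heterogeneity for anyone working with ex vivo fecal fermentation assays and
16S community profiles:

1. **Production rates.** Fecal-slurry SCFA time courses (mM, measured by
   GC-FID in duplicate wells after spiking inulin, pectin or cellulose) are
   replicate-averaged; the production rate is the two-point slope between
   2 h and 4 h, minus the no-spike control slope — a net rate in mM/h.
   Replicate quality is summarized by the per-pair coefficient of variation.
2. **The Microbial Metabolic Phenotype (MMP).** A donor's vector of net
   rates over the fiber × SCFA grid, z-scored per column across the cohort.
   Donors are typed by UPGMA (average-linkage) clustering of their z-score
   rows; each cell is called a *high* (z ≥ 0) or *low* (z < 0) producer.
   Temporal stability over two visits is tested with a two-tailed Fisher
   exact test on the 2×2 high/low concordance table.
3. **Prediction from composition.** OTU count tables are depth-filtered
   (< 5,000 reads dropped), rarefied to the lowest remaining depth for
   diversity (Shannon, Jensen–Shannon distance), total-count normalized for
   relative abundance, optionally collapsed to a taxonomic rank, and fed to
   stratified 5-fold random forests that call high vs low producers,
   reporting a vertically averaged ROC, mean AUC and impurity importances.
4. **In vivo absorption model.** Luminal SCFA follows d[B]/dt = φ − k[B]:
   constant microbial production φ (the measured ex vivo rate) and
   first-order epithelial uptake k over a colonic transit τ. Closed forms
   give the absorbed and excreted mass balance; with zero initial
   concentration the absorbed fraction is `1 − (1 − e^{−kτ})/(kτ)`,
   independent of φ, so inter-donor differences in production translate
   linearly to differences in absorption. Two literature-derived uptake
   constants are bundled (dialysis bag, 0.0019; CaCo-2 monolayer, 0.091) and
   a two-phase variant models fermentable-substrate depletion at time t₁.
5. **Synthetic cohorts.** A seeded generator emulates the full study input —
   replicate SCFA time courses with realistic noise, latent phenotype types,
   two visits with tunable persistence, and OTU tables with planted producer
   taxa — with a ground-truth record, so every stage has a recovery test.

## Worked example

```bash
python analysis/01_simulate_cohort.py
python analysis/02_estimate_rates.py
python analysis/03_type_and_stability.py
python analysis/04_predict_from_otus.py
python analysis/05_absorption_model.py
```

On the default 40-donor cohort (seed 0) this prints, among other lines:

```
visit 1: 240 donor x fiber x SCFA rates; overall replicate CV 25.0% ...
UPGMA k=2 vs planted types: Rand index 0.950
stability over 240 donor x fiber:SCFA cells: 95% concordant, Fisher two-tailed p = 1.39e-47
OTU-level mean AUC 0.933; top importance: OTU001
CaCo monolayer constant (0.091): 39.2% of produced butyrate absorbed over a 12 h transit
dialysis bag constant (0.0019): 1.1% of produced butyrate absorbed over a 12 h transit
```

Reading: replicate scatter lands at the ~25% level planted by the
generator; average-linkage clustering of the z-scored phenotype matrix
recovers the two planted fiber-preference types almost perfectly; the
high/low phenotype is strongly concordant across the two simulated visits;
the planted propionate-producer OTU is both the top classifier feature and
sufficient for an AUC of 0.93; and under the CaCo-derived uptake constant
roughly 40% of butyrate produced during a 12 h transit is absorbed, while
under the dialysis-bag constant nearly all of it is excreted — the
absorbed quantity scales exactly linearly with each donor's measured
production rate either way.

The same steps are available as a CLI (`mmpkit simulate|rates|mmp|
stability|predict|absorb|phase|run`) for use on real tables; see
`mmpkit --help`. Sample IDs follow the `Donor-Condition-Timepoint` layout
with two explicit timepoint-coding dialects (`--dialect A|B`), selected
per file and never auto-detected.

## Layout

- `src/mmpkit/` — the library: `data_io`, `rates`, `mmp`, `community`,
  `absorption`, `simulate`, `pipeline`, `cli`.
- `analysis/` — numbered narrative drivers writing to `results/`.
- `tests/` — unit, property and acceptance suites.
- `docs/methods.md` — model, generator and design notes.
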