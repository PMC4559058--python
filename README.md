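# grainbeta

Multi-grain beta-diversity analysis of two-habitat community data, built
around the machinery used to compare ground-foraging ant communities of
oil-palm plantations and tropical forest: Hill-number alpha diversity, the
multi-assemblage overlap family C_qN and its beta complement, allometric
biomass weighting, hierarchical spatial-grain pooling, bootstrap standard
errors, standardized Z tests and Benjamini–Hochberg FDR control. A
synthetic-landscape generator with known ground truth (species-pool sizes
and overlap, rank-abundance model, spatial layout, body-mass allometry)
makes every stage testable without field data.

It is aimed at community ecologists (and anyone analysing site-by-species
abundance tables, e.g. microbiome count matrices) who want
alpha-independent similarity comparisons across nested sampling grains.

## The statistics at the core

For a relative-abundance vector *p* the Hill number of order *q* is

    ^qD = (Σᵢ pᵢ^q)^(1/(1−q)),      ^1D = exp(−Σᵢ pᵢ ln pᵢ)

so `q = 0` counts species, `q = 1` weights by frequency (exponential
Shannon, "common" species) and `q = 2` emphasises dominants (inverse
Simpson). For *N* equally weighted communities, gamma diversity is the
Hill number of the pooled mean proportions, alpha diversity its
equal-weight multi-community analogue, and `D_β = γ/α ∈ [1, N]`. The
overlap transform maps `D_β` onto [0, 1]:

    C_qN = [(1/D_β)^(q−1) − (1/N)^(q−1)] / [1 − (1/N)^(q−1)]   (q ≠ 1)
    C_1N = 1 − ln(D_β)/ln(N)

which reduces to the multi-assemblage Sørensen index at `q = 0`, the Horn
index at `q = 1` and the Morisita–Horn generalisation at `q = 2`. Beta
diversity on the overlap scale is `^qβ = 1 − C_qN`. Abundances may be
counts or, as in the ant study design, per-species biomass (counts ×
mean dry weight, with log–log allometric regression predicting weights
for species with fewer than three weighed specimens).

Sampling grains are nested by proximity pooling: plots (grain 1) are
paired into grain-2 units within ~5 km, and grain-2 units into grain-3
units within 45 km, conserving abundance exactly; unpairable plots are
recorded as omitted.

## Worked example

```python
from grainbeta import SyntheticTruth, AnalysisConfig, run_full_analysis

cfg = AnalysisConfig(truth=SyntheticTruth(), seed=1)
report = run_full_analysis(cfg)
print(report.summary.as_dict())
print(report.pairwise[report.pairwise.q == 0.0].to_string(index=False))
```

prints (default study-scale conditions: 26 + 21 plots, 105/181 species
pools sharing 63 species, ~550 individuals per plot):

```
{'n_species_oil_palm': 105, 'n_species_forest': 181, 'n_shared': 63,
 'n_union': 223, 'exclusive_pct_oil_palm': 40.0, 'exclusive_pct_forest': 65.2,
 'individuals_oil_palm': 14300.0, 'individuals_forest': 11550.0,
 'biomass_mg_oil_palm': 5678.310544669491, 'biomass_mg_forest': 6508.112440364651}

 grain   q  n_pairs  mean_similarity       se
     1 0.0      546         0.271886 0.006298
     2 0.0      130         0.338568 0.006090
     3 0.0       30         0.404985 0.005472
```

Reading: the two habitats share 63 of 223 species (40.0% of oil-palm
species occur only in oil palm, 65.2% of forest species only in forest),
and the mean between-habitat Sørensen similarity rises from 0.27 at the
plot grain to 0.40 at the largest grain — larger samples expose more of
the shared pool. `report.overlap` holds C_qN and `^qβ` per habitat ×
grain × q with bootstrap SEs; the contrast tables carry Z statistics and
BH-adjusted decisions.

The same pipeline runs from the shell:

```
grainbeta simulate --out land --seed 1
grainbeta run --seed 1 --out report          # simulates by default
grainbeta convert-biomass --counts land/counts.csv --traits land/traits.csv --out biomass.csv
```

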