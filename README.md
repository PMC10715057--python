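# gapregen

Spatial and vertical-layer analysis of woody regeneration in forest canopy
gaps, for forest ecologists working with fully mapped stem censuses.

When a canopy gap opens in a temperate forest, regeneration fills it both
horizontally (where stems establish) and vertically (which species climb
through the lower 0–5 m, medium 5–10 m and upper >10 m layers). `gapregen`
packages the standard quantitative toolkit for such studies:

* **Community metrics** — per-species importance values
  `IV_i = (RD_i + RF_i + RC_i) / 3`, where `RD_i = 100·n_i/Σn` (share of
  stems), `RC_i = 100·a_i/Σa` (share of basal area) and
  `RF_i = 100·f_i/Σf` (share of occupied 3 m quadrats); species richness;
  Shannon diversity `H = −Σ p_i ln p_i`; the fraction of species reaching
  the upper layer; and one-way ANOVA with Tukey HSD and compact letter
  displays for height comparisons across gap ages.
* **Point-pattern analysis** — Ripley's
  `K(r) = s/(n(n−1)) Σ_{m≠n} I(d_mn ≤ r) e_mn` and the pair correlation
  function `g(r)` estimated from annulus pair counts with translation
  (rectangles) or border (ellipses) edge correction `e`; the bivariate
  cross pair correlation `g12(r)`; and rank-based Monte Carlo envelopes
  (default 199 simulations, 2nd-extreme ranks = a 98% pointwise envelope,
  significance 0.02) classifying each distance as clustered/random/regular
  or attraction/independent/repulsion.
* **Kernel density rasters** — gap-centre-aligned stem-density surfaces
  (quartic kernel, 1 m search radius, stems m⁻²) per shade-tolerance ×
  layer group, averaged across replicate gaps.
* **Synthetic stem maps** — seeded Poisson, Thomas-cluster and hard-core
  generators plus six treatment presets (PYG/POG/PCK and SYG/SOG/SCK:
  young gaps, old gaps and closed stands in primary and secondary forest)
  so the whole pipeline is testable without field data.

Envelopes here are *pointwise*: with ~20 distance bins at level 0.02, about
one bin in three runs will fall outside the envelope under the null purely
by multiple testing. Interpret isolated single-bin exceedances cautiously.

## Worked example

```python
from gapregen import (DistanceGrid, GrowthForm, Layer, compute_iv,
                      csr_envelope, diversity, generate_stem_map,
                      get_preset, summarize_scales)

m = generate_stem_map(get_preset("SOG"), seed=7)   # old secondary-forest gap
iv = compute_iv(m, quadrat_side=3.0, include="trees")
print(iv.table.head(3).round(2).to_string(index=False))
d = diversity(m, include="trees")
print(f"tree richness {d.richness}, Shannon H = {d.shannon:.2f} nats")
```

prints

```
             species   n  basal_area_m2  quadrats    RD   RF    RC    IV
  Betula platyphylla 180           1.19        35 14.45 9.09 14.82 12.78
Fraxinus mandshurica 177           0.86        38 14.21 9.87 10.70 11.59
   Populus davidiana  88           1.38        29  7.06 7.53 17.19 10.59
```

so birch leads this gap with 12.8% of the combined stem-count, frequency
and basal-area shares, and the 14 tree species mix to H = 2.37 nats.
Testing the spatial arrangement of lower- versus upper-layer trees in a
closed primary stand (`examples/03_univariate_point_patterns.py`):

```
lower layer (1517 trees): clustered 70%, random 30%, regular 0%
  g(1 m) = 1.32, envelope [0.97, 1.04] -> clustered
upper layer (43 trees): clustered 0%, random 100%, regular 0%
  g(1 m) = 1.32, envelope [0.00, 2.33] -> random
```

Lower-layer regeneration is aggregated at small scales while the sparse
canopy layer is indistinguishable from randomness — note how the envelope
width adapts to the point count. The `examples/` directory has one short
script per capability (simulation, metrics, univariate and bivariate
envelopes, KDE, full pipeline), and the `gapregen` command exposes the
same pipeline from the shell (`gapregen run-all --config cfg.yaml`).

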