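# phylofd

Functional versus phylogenetic diversity in forest communities: does the
phylogeny of a species pool carry information about ecosystem functioning
beyond what measured functional traits already explain?

`phylofd` is a Python library (with a thin CLI) for the community-ecology
workflow that answers this question on forest-inventory-style data:

* **Diversity indices per plot** — functional dispersion (FDis, the
  basal-area-weighted mean distance of species to the weighted centroid in
  standardized trait space), phylogenetic species variability (PSV, one
  minus the mean phylogenetic correlation among the species present), and
  community-weighted trait means (CWM). All three are mathematically
  independent of species richness; monocultures take FDis = PSV = 0 by
  convention.
* **Phylogenetic signal per trait** — maximum-likelihood Pagel's λ under
  Brownian motion on an ultrametric chronogram, with 95% confidence
  intervals from a parametric bootstrap (default 1000 simulations), and
  Moran's I phylogenetic correlograms over eight patristic-distance
  classes with permutation tests (999 permutations), so signal can be
  localized in evolutionary time.
* **Variance partitioning** — the explained variance of (log)
  productivity split between an FD block and a PD block using
  Ezekiel-adjusted R² Venn fractions, with Freedman–Lane permutation
  tests (999 permutations of residuals under the reduced model) for the
  two testable unique fractions; the shared fraction cannot be tested.
* **Synthetic data** — Yule chronograms, λ-scaled Brownian traits,
  truncated-Poisson communities with log-normal basal areas, and a linear
  productivity response, so the entire pipeline is exercised end-to-end
  without any external data.

## The model in brief

For a trait vector **x** over *n* species on an ultrametric tree with
Brownian covariance **V** (V<sub>ij</sub> = shared root-to-MRCA time),
Pagel's λ rescales off-diagonal covariance:

> **x** ~ N(z₀·**1**, σ²·**V**(λ)),  V(λ) = λ·V + (1−λ)·T·I

λ is estimated by maximizing the profile likelihood over λ ∈ [10⁻⁷, 1],
with z₀ and σ² profiled out by generalized least squares. Moran's I for a
binary weight matrix **W** selecting species pairs in a distance class is

> I = (n/S₀) · Σᵢⱼ wᵢⱼ(xᵢ−x̄)(xⱼ−x̄) / Σᵢ(xᵢ−x̄)²,  E[I] = −1/(n−1).

The two-block partition of productivity y on blocks X₁ (FDis) and X₂
(PSV) uses adjusted R²: unique-X₁ [a] = R²ₐ(X₁∪X₂) − R²ₐ(X₂), shared
[b] = R²ₐ(X₁) + R²ₐ(X₂) − R²ₐ(X₁∪X₂), unique-X₂ [c] by symmetry, and
residual [d] = 1 − R²ₐ(X₁∪X₂).

## Worked example

```python
from phylofd import (SimConfig, simulate_dataset, estimate_lambda,
                     varpart_two, fit_productivity_model)

bundle = simulate_dataset(SimConfig(n_plots=500, seed=42))
table = bundle.plot_table          # per-plot FDis, PSV, CWM_N, covariates, response

fit = estimate_lambda(bundle.traits["Wd"], bundle.tree, n_boot=1000, seed=1)
print(f"Wd: lambda_hat={fit.lambda_hat:.4f}  95% CI ({fit.ci_low:.4f}; {fit.ci_high:.4f})")

vp = varpart_two(table["log_productivity"], table[["FDis"]], table[["PSV"]],
                 n_perm=999, seed=2)
print(vp.frac_a, vp.frac_b, vp.frac_c, vp.frac_d, vp.p_a, vp.p_c)
```

prints

```
Wd: lambda_hat=0.7954  95% CI (0.3280; 0.9315)
0.1025 0.1724 0.0037 0.7214 0.001 0.068
```

The wood-density trait was generated with λ = 0.7929, and the ML fit
recovers 0.7954 with a CI spanning roughly (0.33, 0.93) — wide, as
bootstrap CIs for λ on ~60-species trees typically are. The partition
says FDis uniquely explains ~10% of productivity variance, PSV uniquely
only ~0.4% (not significant), and ~17% is shared — the FD⊃PD asymmetry
this kind of analysis is designed to expose. The full covariate model
(`fit_productivity_model`) reaches R²ₐ ≈ 0.43 on the same data, with
every term except PSV significant at the 0.001 permutation floor.

## CLI

```bash
phylofd simulate --out data/ --seed 1                  # synthetic bundle
phylofd indices  --tree data/tree.nwk --traits data/traits.csv \
                 --community data/community.csv --out indices.csv
phylofd signal   --tree data/tree.nwk --traits data/traits.csv \
                 --out-prefix signal --seed 2          # lambda + correlograms
phylofd varpart  --table data/plots.csv --out vp.json --seed 3
phylofd run-all  --out run/ --seed 4                   # all of the above
```

Outputs are CSV/JSON with a `.meta.json` sidecar recording version, seed
and configuration hash.

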