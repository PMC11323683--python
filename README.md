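# spatialipod

Mean-shift outlier detection and robust coefficient estimation for the
**spatial error model** (SEM).

Geographic and areal data — disease rates by county, life expectancy by
country — carry spatially autocorrelated disturbances: the SEM writes them
as ξ = μWξ + ε with a spatial weight matrix W and autoregressive parameter
μ. Classical multiple-outlier detectors assume independent errors and fail
on such data. This package implements **Spatial-Θ-IPOD**: it whitens the
regression with the GLS transform (I − μ̂W) and then runs the
thresholding-based iterative procedure for outlier detection (Θ-IPOD) on
the whitened problem, flagging observations and returning a robust β̂ in
one pass.

## The model and the algorithm

The contaminated SEM is

```
y = Xβ + γ + ξ,   ξ = μWξ + ε,   ε ~ N(0, σ²I),
```

where a nonzero γᵢ marks observation *i* as an outlier. With B = I − μ̂W
the transformed model ỹ = X̃β + γ̃ + τ (ỹ = By, X̃ = BX, γ̃ = Bγ) has
independent errors, and γ̃ is estimated by iterating

```
γ̃ ← Θ(H̃γ̃ + (I − H̃)ỹ; λᵢ),   λᵢ = λ√(1 − h̃ᵢ),
```

for a threshold rule Θ (soft or hard), H̃ the hat matrix of X̃. The level λ
is tuned over a decreasing grid by a modified BIC,
BIC*(λ) = m·log(RSS/m) + k(log m + 1), m = n − p, k = #flagged + 1.
When μ is unknown it is estimated beforehand — by Gaussian maximum
likelihood (`sem_mle`) or by robustified-likelihood Fisher scoring with a
bounded influence function ψ (`romle_fit`; Cauchy, Welsch, Insha or
logistic).

## Worked example

```python
import numpy as np
from spatialipod import Scenario, make_dataset, spatial_ipod

data = make_dataset(Scenario(n=200, p=5, n_outliers=15, seed=21))
fit = spatial_ipod(data.X, data.y, data.w, rule="soft", mu=0.7)
print(fit.outlier_idx.tolist())
print(np.round(fit.beta_hat, 3))
```

prints

```
[0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16, 43, 109]
[1.007 1.009 1.015 0.998 0.973]
```

All 15 planted outliers (rows 0–14) are flagged — zero masking — along
with a few extra rows: sites adjacent to the planted block genuinely carry
part of the shift on the whitened scale, and BIC* trades a little swamping
for protection against masking. The coefficient estimate stays within a
few percent of the truth (β = 1) despite 7.5% gross contamination.

The `examples/` directory has one short script per capability: threshold
rules and induced penalties, spatial detection, SEM estimation (MLE vs
robust scoring), and a small Monte-Carlo benchmark. A thin CLI mirrors the
library:

```
spatialipod simulate --n 500 --p 15 --outliers 50 --out-dir sim/
spatialipod detect --x sim/X.csv --y sim/y.csv --w sim/W.csv --rule soft
spatialipod benchmark --p 15 --outliers 50 --n-reps 200 --out bench.csv
```

`detect` also reads GeoDa GAL/GWT weight files (`--w-format gal|gwt`).

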