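# Methods

## Model

The package estimates the contaminated spatial error model

y = Xβ + γ + ξ,  ξ = μWξ + ε,  ε ~ N(0, σ²I),

with X ∈ ℝ^{n×p} full column rank (n > p), W an n×n nonnegative spatial
weight matrix with zero diagonal (usually row-standardized), μ the spatial
autoregressive parameter, and γ a sparse mean-shift vector whose support is
the outlier set. Writing B(μ) = I − μW, the disturbance covariance is
σ²(BᵀB)⁻¹; note that any factor S with SᵀS = BᵀB whitens the errors, and
the code uses S = B itself (the symmetric inverse square root is available
as `omega_inv_sqrt` and is used only in verification).

## Thresholding and the induced penalty

A threshold rule Θ(·; λ) is odd, monotone, shrinking and unbounded. The
soft rule Θ(x) = sgn(x)(|x| − λ)₊ and hard rule Θ(x) = x·1{|x| > λ} are
built in; the registry accepts any rule satisfying the axioms. The boundary
|x| = λ is assigned to the zero branch for both rules (a measure-zero
choice). Each rule owns the penalty produced by the inverse-integral
construction P_Θ(θ; λ) = ∫₀^{|θ|}(Θ⁻¹(u) − u)du, stored in closed form
(soft: λ|θ|; hard: λ|θ| − θ²/2 capped at λ²/2); numeric quadrature of the
construction exists only as a test oracle.

## The non-spatial solver

For fixed λ, γ is a fixed point of γ ← Θ(Hγ + (I−H)y; λᵢ) with
per-coordinate λᵢ = λ√(1 − hᵢ); H is held as an orthonormal basis Q of
col(X) so one iteration costs O(np). Coordinates with hᵢ numerically 1
would have λᵢ = 0 and always flag; they are pinned to γᵢ = 0 and reported
in diagnostics. Convergence is ‖Δγ‖∞ < 1e−8 within 500 iterations (both
configurable); under the soft rule the penalized objective decreases
monotonically, under the hard rule 2-cycles can occur and are resolved by
keeping the lower-objective member. Non-convergence is flagged on the
returned fit, never raised.

## Tuning λ

λ runs over 100 linearly spaced values (the endpoints are fixed by the
method: from ‖(I−H)y/√diag(I−H)‖∞ down to 0; the count and spacing are this
package's choice) in decreasing order with warm starts. Each candidate is
scored by BIC*(λ) = m log(RSS/m) + k(log m + 1), m = n − p,
k = #{γ̂ᵢ ≠ 0} + 1, with RSS = ‖(I−H)(y − γ̂(λ))‖² evaluated at the
penalized estimate γ̂(λ). The winning support is then refitted by
support-restricted least squares — equivalently OLS on the unflagged rows,
one free shift per flagged observation — which supplies the reported γ̂ and
β̂ (for the hard rule the fixed point already equals this refit). Ties go
to the larger λ.

Two guards keep the selection well-posed:

* saturated fits (RSS numerically zero) get a −∞ sentinel and are excluded;
* supports larger than min(n/2, m − 2m/(log m + 1) − 1) are inadmissible.
  The second bound is where BIC*'s expected log-RSS gain from deleting a
  *clean* observation overtakes its per-flag penalty; past it the criterion
  is unbounded below and would always prefer near-saturation. The n/2 term
  is the usual 50% breakdown bound.

Even inside these bounds BIC* is mildly liberal: on clean data the selected
fit is empty in ≈95–97% of replicates (n ≥ 100), i.e. a false-flag rate of
a few percent, and global subset enumeration can exploit this slack on
supports the one-dimensional path never visits. This is the known cost of
an RSS-based criterion for mean-shift selection; masking protection is
bought with a little swamping.

## Spatial detection

`spatial_ipod` runs: (1) obtain μ̂ — user-supplied, or robustified-
likelihood scoring (`romle_fit`) by default; (2) GLS-transform; (3) run the
λ-path selection on (X̃, ỹ) with H̃ from X̃; (4) report γ̃̂ (transformed
scale, the default report), the back-transform B⁻¹γ̃̂ (original scale), the
flagged set and β̂. μ̂ is estimated once and held fixed along the λ path;
re-estimation after outlier removal is a possible extension, not done here.
With μ = 0 every step reduces exactly to the non-spatial method.

A mean shift at site i appears at i *and* its graph neighbours on the
transformed scale (γ̃ = Bγ), so neighbouring sites of a contaminated block
are legitimately flagged there — elevated swamping around outlier clusters
is a property of the model, not an artifact.

## SEM estimation

`sem_mle` profiles β and σ² analytically and line-searches μ on its
admissible interval (1/λ_min(W), 1/λ_max(W)), intersected with (−1, 1) for
row-standardized W; log-determinants use the cached eigenvalues of W. A
boundary hit is reported as non-convergence.

`romle_fit` alternates Fisher-scoring steps:
s_β = X̃ᵀψ(r)/σ̂ with information E[ψ′]·X̃ᵀX̃/σ̂², and
s_μ = −K·tr(B⁻¹W) + ψ(r)ᵀWB⁻¹ψ(r) with information
K·(tr(G²) + tr(GᵀG)), G = WB⁻¹, where r = B(y − Xβ)/σ̂ and
K = ∫ψ²(r)φ(r)dr under the standard-normal reference density
(Gauss–Hermite, 80 nodes; E[ψ′] via Stein's identity E[Zψ(Z)]). σ̂ is
refreshed each sweep by the normalized MAD of the whitened residuals
(maximum-likelihood scale when ψ is the identity, which makes the scoring
reduce exactly to likelihood scoring). Steps are damped at the interval
boundary; five consecutive growing steps trigger a fallback to the Gaussian
MLE with `converged=False`.

ψ families and tuning constants (conventional ≈95%-efficiency values;
the source literature prints none): Cauchy r/(1+(r/c)²), c = 2.385;
Welsch r·exp(−(r/c)²), c = 2.985; Insha r(1+(r/c)⁴)⁻², c = 4.0;
logistic c·tanh(r/c), c = 1.205; identity ("none").

**Limitation — contiguous mean shifts.** A block of shifted sites that are
mutual neighbours on the graph is observationally close to *extra spatial
correlation*: its whitened residual signature is a locally positively
associated cluster, exactly what the μ-score measures. On the benchmark
contamination (50 adjacent shifted sites on a chain) the robust μ-score has
no root near the true value for any ψ family — μ̂ drifts to ≈0.96 and
detection after whitening with that μ̂ fails. This is a structural
identifiability limit, not a numerical one. Consequently the simulation
benchmark passes the *known* scenario μ to the spatial detectors by default
(`mu_mode="true"`; the algorithm explicitly admits a known μ), with
`mu_mode="estimate"` available to study the degradation. On clean data, and
for scattered or innovation-type contamination of moderate size, `romle_fit`
recovers μ well (mean |μ̂ − 0.7| ≪ 0.05 at n = 500).

## Synthetic data

`make_dataset` draws X = UΣ^{1/2} with U_ij ~ U(−5, 5) iid and Σ the p×p
equicorrelation matrix (ρ = 0.5; symmetric square root in closed form);
optionally overwrites the first O rows with the constant leverage vector
L·[1,…,1]; plants γᵢ = 8 at the first O sites; and solves (I − μW)ξ = ε
exactly with μ = 0.7, σ² = 0.2. W is the chain-graph kernel
w_ij = 0.5^{|i−j|}, row-standardized by default (a switch disables this for
sensitivity checks). Defaults are the benchmark conditions: n = 500,
p ∈ {15, 50}, O ∈ {10, 20, 50}, L ∈ {none, 15, 20}. All randomness flows
from the scenario seed (design first, then ε); identical seeds give
bit-identical data.

What the generator does *not* emulate: irregular spatial graphs, spatially
varying leverage, heteroskedastic or heavy-tailed innovations, missing
data. Passing tests therefore demonstrate correctness of the machinery and
behaviour under the stated generative model, not performance on real
geographies.

With the row-standardized chain W at these parameters the spatial error ξ
has standard deviation ≈0.6, so a shift of 8 is ≈14σ; the *non-spatial*
detector then also detects near-perfectly, and the spatial advantage shows
in swamping/efficiency rather than masking. (With the raw kernel instead,
I − 0.7W is near-singular and every method fails; see the admissibility
interval above.)

## Benchmark conventions

Masking and swamping are averaged over replicates; JD is the percentage of
replicates with zero masking; MSE of β is the per-coordinate convention
(1/p)‖β̂ − β‖² averaged over replicates (this is the convention that puts a
per-coordinate error of ~10⁻³ on the 10⁻⁶ scale). Replicate k of scenario s
derives its seed deterministically from (master seed, s, k), so adding or
reordering methods never perturbs the data stream; Monte-Carlo standard
errors accompany every cell. The runner defaults to 200 replicates
(recorded in the output); the acceptance script uses 100/40/30 per quantity
to fit a single-CPU run. Per-replicate method failures are logged, counted
and excluded from means; flagging nothing is not a failure.

## Numerical choices

* Hat matrix via economy QR with column pivoting; rank deficiency is an
  error naming the dependent columns. Leverage clipped to [0, 1].
* Dense linear algebra throughout (n in the hundreds); the weight-matrix
  eigenvalues are computed once per W and cached (symmetric similarity
  when W was standardized from a symmetric kernel).
* λ grid starts a hair (1 + 1e−8) above λ_max so the first fit is robustly
  the null fit; if every grid point is inadmissible the null fit is
  returned with a warning.
* Degenerate inputs: empty vectors pass through thresholding; zero weight
  rows survive row-standardization (reported as isolated units); W = 0
  reduces the SEM MLE to OLS.

## Known limitations

p > n designs and longitudinal error structures are out of scope. μ is not
identifiable under spatially contiguous mean-shift contamination (above).
BIC* retains a small-sample liberal bias toward flagging 1–2 extra points.
The hard rule handles leverage blocks better than soft (the soft shrinkage
can mask a leverage cluster whose common level the fit absorbs); the soft
rule is the default for plain data analysis, and benchmarks run both.
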