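# Methods

## Model

The package solves the 1D reaction–diffusion equation

    ∂C/∂t = D ∂²C/∂x² + C · r(C)

with either the logistic rate `r(C) = ρ(1 − C/K)` or the quadratic Allee
rate `r(C) = ρ(C/K + β)(1 − C/K)`. Densities are never clipped: values
above `K` simply receive a negative rate, and for `β < 0` the rate is
negative below the critical density `C_T = −βK`. Classification
(`strong`/`weak`/`borderline`/`logistic`) follows the sign of `β`.

Characteristic scales used throughout: front width `w = √(D/ρ)`,
leading-edge decay rate `a = √(ρ/D)`, and front speeds

* logistic (pulled): `v = 2√(Dρ)`;
* Allee, `β < 1/2` (pushed): `v = √(Dρ/2)(1 + 2β)` — the exact
  Nagumo-family speed, confirmed numerically (0.7069 vs 1/√2 at `β = 0`);
* Allee, `β ≥ 1/2` (pulled): `v = 2√(Dρβ)`.

The pushed-front formula is standard front-selection theory; it is used
for grid/horizon sizing and cross-checks.

## Numerics

Method of lines on a uniform cell-centred grid: central second differences,
explicit Euler, automatic step `dt = min(0.4·dx²/2D, 0.1/ρ)` (a user `dt`
violating `dx²/2D` is refused). Outer boundaries are no-flux by default
(absorbing optional). Excised nodes are removed from the stencil by a
masked-flux Laplacian, which imposes no-flux conditions exactly at the
excision contour. Round-off negativity is clamped to zero and counted;
anything below `−10⁻⁹K` aborts. A boundary guard aborts when the solution
reaches an outer edge that started empty (disabled automatically for
edge-anchored seeds, and for post-resection runs in `zero_fill` mode,
where refilling the cavity back to the edge is legitimate).

Default resolution is 10 nodes per front width. Convergence is monotone
from below: the FK benchmark gives speeds 1.958 / 1.968 / 1.970 at
`dx = 0.2 / 0.1 / 0.05` over short horizons and 1.9878 at `dx = 0.05`,
`t = 150`.

### Front diagnostics

`front_position` interpolates the rightmost `K/2` crossing. `front_speed`
is a least-squares slope over a window (default: final third) and reports
`R²`. `tail_decay_rate` offers two estimators:

* `exponential` (default): plain log-linear fit over densities in
  `[10⁻⁶K, 10⁻²K]`. Exact on ideal exponentials (`C = e^{−2x}` → 2.0), but
  on a *simulated* pulled front it underestimates `a` by ≈ 9%: the
  finite-time leading edge carries the universal algebraic prefactor
  `(x − x₀)e^{−a(x−x₀)}`, which contributes `−1/⟨x − x₀⟩` to the measured
  slope in that window.
* `pulled_edge`: fits `ln C = c + ln(x − x₀) − a(x − x₀)`, removing that
  bias (1.034 on the FK benchmark). Use this one on simulated fronts.

## Resection and remission delay

`resect` zeroes the density where `C > δ`, with interpolated contour
endpoints. Two representations of the cavity are provided:
`excise_no_flux` deactivates the nodes (no-flux at the contour, no
repopulation) and `zero_fill` keeps them active at zero density.

**The two modes are *not* interchangeable quantitatively.** With the
cavity open, the sub-δ residual tail loses roughly half its mass by
back-diffusion before the recurrent front forms; because the delay scales
as the inverse square of the residual amplitude, measured delays differ by
a factor ≈ 3.7 (β = 0, δ = 0.1: τ = 65 vs 237 edge-anchored; 58 vs 215 in
the symmetric two-tail geometry). The qualitative picture — lag phase,
recurrence, δ⁻² scaling — is mode-independent, and `zero_fill` is always
the slower of the two. All default studies use `excise_no_flux`.

The default intervention time grows the front for **30 front widths**
before resecting. Shorter growth (e.g. 10 widths) leaves the sub-δ leading
edge unrelaxed; the resulting tail-mass deficit grows as δ shrinks and
steepens the measured τ(δ) slope from −2.05 to −2.13.

Two delay estimators:

* `front_offset` (default): mean of `t_post(x*) − t_unperturbed(x*)` over
  reference positions from the late quarter of the post-resection front
  trajectory. The unperturbed reference run is simulated only long enough
  to fit its linear asymptote (fit `R² ≈ 1 − 10⁻¹⁰`); later passage times
  are extrapolated.
* `mass_offset`: horizontal offset between the linear late-time regimes of
  the two total-mass curves at matched mass levels.

The two agree within a few percent on borderline-Allee runs. `τ = ∞`
records strong-Allee extinction (no front ever re-forms and the mass
decays). Threshold scans share one grown pre-resection state across δ,
size the grid and horizons from the closed-form τ estimate, and integrate
post-resection runs in chunks, stopping once the recurrent front has
travelled 15 front widths.

## Dispersing-tail theory

For the β = 0 model the residual tail `δe^{−ax}` first disperses
diffusively. The short-time closed form

    C(x,t) = (δ/2)[1 − erf((ρt − x)/(2√(Dt)))] e^{−ax+ρt}

is implemented verbatim (stably, via the scaled complementary error
function); note it is a *short-time* approximation — its exponent grows
like `(3/4)ρt` at late times, where the Gaussian form

    C(x,t) = δ/(2√(πρt)) · e^{−x²/(4Dt)},   mass δ√(D/ρ)

takes over. The Gaussian matches a numerical pure-diffusion solve of the
tail within 5% (sup norm) at `t = 100`.

Balancing the Gaussian's diffusive decay against the quadratic
proliferation gain gives the remission-time estimate. Two variants are
shipped (they differ by exactly π², depending on where the balance
constant is fixed):

* `eq11_as_printed`: `τ = (1/(πρ)) (K/δ)²`
* `eq10_rebalanced`: `τ = (π/ρ) (K/δ)²` (re-solving the term balance at
  `x = 0`)

Both scale exactly as δ⁻². Simulated delays fall between them
(simulated/`eq11_as_printed` ≈ 1.7–1.9 across the δ decade, constant
within 13%).

### Strong Allee divergence threshold

For `β = −0.05`, resecting below `C_T = 0.05` guarantees elimination
(verified: monotone mass decay). The *divergence threshold* of τ(δ) is
however much larger than `C_T`: the dispersing tail's peak density falls
below growth-sustaining levels long before a front can nucleate, so
residuals at `δ = 0.1` also go extinct (peak density drops to ~3·10⁻³ C_T;
mass ratio 10⁻⁷ over the horizon). Empirically τ is finite for
`δ ≳ 0.24` (τ = 34 at δ = 0.25, τ = 13.5 at δ = 0.3) and infinite below.
The acceptance test asserting a finite delay at δ = 0.1 is left failing on
purpose as a specification of behaviour this model does not produce.

## Growth-rate estimation pipeline

1. **Segmentation**: cells are textured, backgrounds smooth, so the mask
   is `local_std(frame, window) > threshold` with a per-frame Otsu
   threshold. The estimate is invariant to global intensity offsets. The
   mask rim dilates by about half the window; with the default 9 px window
   and 30 px disks that is ≈ +2.8 percentage points at 20% coverage, so
   validation against the synthetic generator uses `window_px = 3`
   (errors ≤ 0.2 pp at 1–20% coverage). Keep larger windows for real
   imagery whose texture has longer correlation lengths.
2. **Confluency** `A(t)`: mask mean per frame.
3. **Window rates**: sliding 30 h linear fits of `A` vs `t` give slopes
   `b(T)`; the per-cell rate sample is `b(T)/A(T)` (vectorised for
   uniformly sampled series).
4. **Binning**: samples pooled in 2.5% coverage bins; the SEM uses an
   effective sample size (per series and bin, the span of contributing
   window starts divided by the window length) because overlapping windows
   are strongly correlated.
5. **Allee fit**: weighted least squares of the quadratic law. The window
   slope estimates the *secant* growth over `[T, T + ΔT]`, not the
   instantaneous rate at `A(T)`; fitting the raw law to windowed data
   shifts the apparent maximum by ≈ `r·ΔT/2`. The fit therefore
   forward-models the windowed estimator: it integrates the candidate
   `r(A)` over ΔT (RK4) and compares predicted secant rates to the binned
   ones. A nested logistic fit is compared by AIC and flagged when
   preferred (the null for monotone data).

With ground truth `ρ = 0.02/h, K = 0.9, β = 0.05`, 12 series, 5% noise and
240 h acquisitions, the pipeline recovers `β` within ±0.05 and the
interior-maximum location within one bin in ≥ 95/100 seeded replicates.
96 h acquisitions are too short for maximum-location recovery — the
cultures never pass `A* = K(1−β)/2 ≈ 0.43`.

## Synthetic data: realism and limits

* `synth_confluency`: integrates `dA/dt = A·r(A)` (RK45, rtol 10⁻⁹) per
  seeding density (0.5–20% initial coverage), then applies multiplicative
  log-normal noise; values above 1 are capped and flagged. Deterministic
  per seed. *Limits*: noise is i.i.d. per frame (no drift, no
  segmentation-error autocorrelation); all series share one rate curve (no
  biological replicate variability).
* `synth_images`: cells are non-overlapping textured disks (zero-mean
  speckle on a smooth background with a gentle intensity gradient); disk
  *count* tracks the target coverage, so the ground-truth mask is exact
  and coverage is quantised at one disk's area. Disks persist across
  frames. *Limits*: no cell morphology, motility, division events,
  confluent contact, or focus drift — the generator validates
  segmentation and coverage statistics, not cell tracking.
* `synth_tail_profile`: the canonical post-resection state `δe^{−ax}`
  (x ≥ 0) with known mass `δ/a`, for solver- and theory-level oracles.

## Limitations

* 1D, isotropic, constant `D` and `ρ`; no density-dependent motility, no
  tissue heterogeneity, no 2D/3D geometry.
* Explicit Euler is first-order in time; acceptable because the diffusive
  CFL step is already far below the reaction time scale (halving `dt`
  changes the FK benchmark by < 10⁻³).
* Pulled-front speeds converge slowly in time (−3/(2t) Bramson shift):
  finite-horizon measurements sit ~0.5–1% below the asymptote.
* Delay estimates at very small δ require large domains and long horizons;
  the scan machinery sizes these automatically from the closed-form τ but
  costs grow as δ⁻².
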