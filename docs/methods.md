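# Methods

## Model

A chromatin domain (CD) is a chain of `N` nucleosome beads whose equilibrium
conformation obeys the fractal size scaling

    ⟨[R(n) − R(m)]²⟩ = b_eff² |n − m|^(2/d_f),        b_eff = ⟨R⟩_CD N^(−1/d_f),

with fractal dimension `d_f ∈ (1, 3]`. The chain fluctuates in a viscoelastic
medium with power-law memory friction `γ(t) = γ_α t^(−α)/Γ(1−α)`,
`α ∈ (0, 1]`, via a generalized Langevin equation whose thermal noise obeys
the fluctuation–dissipation relation; free motion in this medium is
fractional Brownian motion with MSD ∝ `t^α`. Long-range intra-domain
interactions are not modelled as an explicit force field: they enter only
through the size scaling, which fixes the equilibrium variance of each cosine
normal mode after a linearization (preaveraging) approximation,

    ⟨X_p²⟩ = ⟨R²⟩_CD / (2 A_{d_f}) · p^(−1−2/d_f),
    A_{d_f} = π^(1+2/d_f) Γ(1+2/d_f) sin(π/d_f),

and mode stiffnesses `k_p = 3k_BT / (2N⟨X_p²⟩)` (`k_0 = 0`). Each mode then
relaxes with a Mittag-Leffler autocorrelation

    C_p(t) = ⟨X_p²⟩ · E_α(−p^(1+2/d_f) (t/τ)^α),
    τ = [4N⟨R⟩²_CD / (3 A_{d_f} D_EGFP)]^(1/α),

the centre of mass subdiffuses with exponent `α`, and the position-averaged
nucleosome MSD at `t ≪ τ` is the closed-form power law

    MSD(t) = [2 B_{d_f,α} ⟨R²⟩_CD / (A_{d_f} Γ(1+α))] (t/τ)^(2α/(2+d_f)),
    B_{d_f,α} = (d_f/2) · Γ(1+α)^(d_f/(2+d_f)) · Γ(d_f/(2+d_f)).

The grouping of `B_{d_f,α}` is fixed two independent ways: analytically, it
is exactly the constant produced by converting the mode sum (exponential
relaxation surrogate, `cos² → 1/2`) into an integral via the Mellin identity
`∫ u^(s−1)(1−e^(−cu))du = −Γ(s)c^(−s)`; numerically, the mode-sum oracle
reproduces the closed-form prefactor to better than 1% as `t → 0` (tested).

**Friction convention.** Friction enters every formula only through the
reference diffusivity: `γ_α = 4k_BT/D_EGFP`, treating a nucleosome with its
fluorescent tag as having four times the friction of an EGFP monomer. This is
dimensionally loose for `α < 1` (the published analysis adopts it on the
grounds that `1 ≤ 1/Γ(1+α) < 1.13`); we keep the convention rather than
"fixing" it, and consequently no temperature parameter is exposed — `k_BT`
cancels everywhere.

## Parameters

| parameter | meaning | units | default | why |
|---|---|---|---|---|
| `alpha` | medium memory exponent | — | assumption, 0.8–0.9 typical | FCS in nuclei reports ≈0.8; not identifiable from short-time MSD alone |
| `d_f` | fractal dimension of the domain | — | inferred | 2 = ideal chain, 3 = fractal globule |
| `n_nucleosomes` | beads per domain | — | 5000 | 1 Mb at 200 bp/nucleosome; TADs span ~0.1–5 Mb |
| `r_rms` | RMS domain size `⟨R⟩_CD` | µm | inferred | super-resolution imaging gives 0.1–0.5 µm |
| `d_egfp` | EGFP diffusivity in nucleoplasm | µm²/s | 20.6 | FCS reference measurement |
| `frame_interval` | imaging frame time | s | 0.05 | reference imaging conditions |
| fit window | lags used in the power-law fit | s | [0.05, 0.5] | the measured MSD range; `t = 0` always excluded |

`alpha` is always an *assumption* of the inversion, never estimated: a
short-time fit determines only `(D_app, β)`, and `β = 2α/(2+d_f)` leaves
`(α, d_f)` on a one-parameter ridge. `alpha_sweep` makes that ridge explicit.
The optional surface-monomer hydrodynamic correction `d_f = c(2α/β − 2)`
accepts `1 ≤ c < 1.09`; full intra-domain hydrodynamic coupling instead gives
`β = 2α/3` independent of `d_f` (the `hydrodynamics` flag of
`subdiffusion_exponent`).

## Estimators

The ensemble MSD is **origin-anchored**: displacements are taken from each
track's first frame, `MSD(t_i) = (3/2)·M_i^(−1) Σ_j [(x_i−x_0)² + (y_i−y_0)²]`,
matching the estimator used on the imaging data; 3/2 converts the 2D
projection to a 3D value under isotropy (exact in expectation for the
simulator, which is isotropic by construction). The per-lag SEM is the sample
standard deviation of the per-track scaled squared displacements divided by
`√M_i` — the published analysis states only that the SEM was small, so this
standard definition is our choice. A conventional time-averaged estimator is
included for comparison only and is never used for inference.

The power-law fit is nonlinear least squares on `(t, MSD)` initialized from a
log-log linear regression, unweighted by default (SEM weighting optional).
Standard errors come from the fit covariance; the uncertainty on `d_f` is the
delta-method image `|∂d_f/∂β| σ_β = (2cα/β²) σ_β`.

## Simulator

Synthetic experiments are generated **in mode space with exact covariances**,
never by discretized Langevin integration, so sampled statistics match the
theory with no step-size bias to argue about:

* centre of mass: fractional Brownian motion, sampled by Davies-Harte
  circulant embedding of the increment covariance (Cholesky fallback if an
  embedding is not PSD);
* internal modes: stationary Gaussian processes with autocovariance
  `C_p(|Δt|)/3` per axis, sampled by dense Cholesky factorization of the
  Toeplitz covariance (tracks are tens of frames, so this is exact and
  cheap; factors are cached across tracks and seeds), with a ≤1e−10 relative
  diagonal jitter escalation for numerically semi-definite Mittag-Leffler
  covariances;
* bead reconstruction: `R(n,t) = X_0(t) + 2Σ_p cos(pπn/N) X_p(t)`, truncated
  at `n_modes` (default `min(N, 512)`); the neglected equilibrated tail
  `4Σ_{p>P}⟨X_p²⟩ ≈ (d_f/A_{d_f})⟨R²⟩ P^(−2/d_f)` is checked and warned about
  by the mode-sum evaluator;
* imaging: drop z, add i.i.d. Gaussian localization noise per axis
  (default σ = 15 nm, a typical single-molecule figure — there is no
  measured value to adopt, so set it deliberately), one seed for everything.

The mode relaxation kernel is switchable: `"ml"` (exact Mittag-Leffler, the
model's own dynamics, default) or `"exp"` (the exponential surrogate
`E_α(−x) ≈ exp[−x/Γ(1+α)]` under which the closed-form MSD is exact).

What the generator deliberately does **not** emulate: photobleaching and
blinking, track-linking errors, drift, ATP-driven non-equilibrium noise, and
inter-domain heterogeneity (every track samples the same domain parameters).
Passing recovery tests therefore validate the estimator/inversion chain under
the model's own assumptions, not robustness to those real-data effects.

## Numerical choices

* **Mittag-Leffler.** Taylor series for `|z| < 5` with a largest-term guard
  (`>1e12` triggers fallback) against double-precision cancellation at small
  `α`; otherwise the complete-monotonicity spectral integral after the
  substitution `s = u^(1/α)`, which removes the endpoint singularity
  exactly. Verified against the `α = 1` and `α = 1/2` closed forms and
  60-digit arbitrary-precision series values; absolute error ≲1e−13.
* **Fit initialization.** Log-log regression start point; `curve_fit`
  refines. Ties/degenerate inputs: windows with <3 positive-lag points or
  non-positive MSD raise immediately.
* **Valid ranges.** `d_f ≤ 1` is a hard error (`A_{d_f} → 0`); `d_f > 3` is
  admitted only in flagged sweep rows, where the formulas remain finite.
* **Units.** Lengths µm (sizes reported in nm), times s, `D_app` in µm²/s^β.

## Validation and its limits

The closed-form short-time law is an asymptotic statement. Measured against
the brute-force mode sum (P = 4000, exponential kernel, position-averaged,
CoM excluded), pointwise agreement is ≲5% only for `t ≲ 0.01 τ`; the
crossover deficit grows to ~5–16% at `t = 0.05 τ` depending on `(α, d_f)`
(worst for small α and small d_f), and P = 4000 truncation alone contributes
~4% near `t = 10⁻³ τ` at `d_f = 3`. Tests assert the measured behaviour
(5% to `0.01 τ`, 10% to `0.05 τ` at the reference parameters) and the ≤1%
prefactor agreement at `t → 0`.

End-to-end parameter recovery (simulate → ensemble MSD → fit → invert) is run
at (α = 0.9, d_f = 2.09, R = 268 nm, N = 5000), 2000 tracks × 11 frames,
three seeds. The validation window uses 1 ms frames, placing lags at
`t/τ ≈ 4·10⁻⁴–4·10⁻³`, deep inside the asymptotic regime, with
`n_modes = 4000` and no localization noise — parameter-recovery claims are
about the inference chain, so the window must sit where the inverted formula
is valid. Recovery is β within ±0.03 per seed, and median d_f within ±0.15
and median R within ±15% across seeds; the residual central bias
(β +0.009, R +9%) is real crossover physics — the centre-of-mass term and
discrete low modes push the local slope above `2α/(2+d_f)`.

At the reference imaging conditions (50 ms frames, lags 0.05–0.5 s) the same
ground-truth model yields a *fitted* exponent ≈0.48, not 0.44: the fit window
reaches `0.19 τ`, where the crossover toward centre-of-mass motion is far
from negligible. Structural parameters inverted from 50-ms-window fits
therefore carry a systematic bias of the same origin (size overestimated by
tens of percent for this ground truth); this is an intrinsic property of
inverting an asymptotic law at finite lag times, and applies equally to real
measurements analysed this way.

**Reference-value consistency.** Inverting the published interior/periphery
fits reproduces the published fractal dimensions (1.64, 2.09, 2.10, 2.62) and
relaxation times (4.65, 2.69, 1.31, 1.01 s) exactly at printed precision. The
domain sizes we compute (376, 263, 187, 142 nm) differ from one published
tabulation (358, 268, 191, 166 nm) by −5% to +17%. The two columns of that
tabulation cannot both follow from the stated formulas: the relaxation time
is a deterministic function of the size, `τ = [4N⟨R⟩²/(3A D_EGFP)]^(1/α)`,
and all four published relaxation times match *our* sizes to printed
precision while none matches the published sizes. We therefore report the
computed sizes and treat the published size column as containing evaluation
or transcription errors; no alternative reading of the constants we tested
(regrouped Γ factors, rounded intermediates, surface-monomer correction)
reproduces it consistently.

## Known limitations

* `α` must be assumed; joint inference of `(α, d_f)` would need lags beyond
  `τ` (the MSD crossover to exponent `α`), which short tracks do not reach.
* The linearization approximation replaces long-range interactions by mean
  equilibrium mode variances; it presumes thermal equilibrium within the
  domain and excludes ATP-driven activity.
* Localization noise is not deconvolved from the MSD before fitting; at 15 nm
  noise and 50 ms frames it inflates the first lag by ~1.3×10⁻³ µm².
* The inversion inherits the asymptotic law's finite-lag bias quantified
  above.
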