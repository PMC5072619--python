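# chromdyn

**Chromatin-domain structure from single-nucleosome dynamics.**

Mammalian genomes are partitioned into submegabase chromatin domains (CDs,
including TADs). Live-cell single-nucleosome imaging shows that nucleosome
motion is subdiffusive: the ensemble mean squared displacement follows

```
MSD(t) = D_app · t^β,   0 < β < 1.
```

`chromdyn` implements a polymer model that links this dynamic measurement to
domain *structure*. A CD is a chain of `N` nucleosomes with a fractal
equilibrium conformation, `⟨R⟩_CD ∼ N^(1/d_f)` (`d_f = 2`: ideal chain,
`d_f = 3`: fractal globule), fluctuating in a viscoelastic nucleoplasm with
power-law memory friction `γ(t) ∼ t^(−α)` (a generalized Langevin equation,
consistent with fractional Brownian motion). After a linearization
(preaveraging) approximation the normal modes `X_p` relax with Mittag-Leffler
kernels, and the short-time (`t ≪ τ`) nucleosome MSD is an exact power law
with

```
β     = 2α / (2 + d_f)
D_app = C_{d_f,α} · (3 D_EGFP / 4N)^(2/(2+d_f)) · (⟨R²⟩_CD)^(d_f/(2+d_f))
```

so a fitted `(D_app, β)` can be inverted — under assumed `α`, `N` and the
reference diffusivity `D_EGFP` — into the fractal dimension, the RMS domain
size and the relaxation time of nucleosome fluctuations:

```
d_f    = 2α/β − 2
⟨R⟩_CD = (D_app / C_{d_f,α})^((2+d_f)/(2d_f)) · (4N / 3D_EGFP)^(1/d_f)
τ      = [4N ⟨R⟩²_CD / (3 A_{d_f} D_EGFP)]^(1/α)
```

The package provides:

* `chromdyn.theory` — closed-form and numerical (mode-sum) forward theory,
  including the structural constants `A_{d_f}`, `B_{d_f,α}`, `C_{d_f,α}` and a
  careful Mittag-Leffler evaluator;
* `chromdyn.inversion` — power-law fitting of MSD curves (statsmodels-style
  `SubdiffusionModel(...).fit()` → results with `summary()`, `estimate_domain`,
  `alpha_sweep`, `ncd_sweep`, `plot_fit`);
* `chromdyn.trajectories` — track containers, delimited-text I/O and the
  origin-anchored ensemble MSD estimator with the 3/2 isotropy projection;
* `chromdyn.simulate` — an exact-covariance mode-space simulator of synthetic
  2D tracking experiments (Davies-Harte fractional Brownian centre of mass,
  stationary Mittag-Leffler modes, localization noise) for end-to-end
  validation;
* a `chromdyn` command-line tool tying these into reproducible workflows.

## Worked example

Invert the published HeLa nuclear-interior fit `MSD = 0.018 t^0.44 µm²`
assuming `α = 0.8`, a 1-Mb domain (`N = 5000` nucleosomes) and
`D_EGFP = 20.6 µm²/s`:

```sh
$ chromdyn estimate 0.018 0.44 --alpha 0.8
alpha=0.8 N_CD=5000 D_EGFP=20.6 c=1
d_f     = 1.64
<R>_CD  = 376 nm
tau     = 4.65 s
```

Interior chromatin is loosely folded (`d_f = 1.64`, between a straight fiber
and an ideal chain), domains are a few hundred nanometres across, and
nucleosome fluctuations equilibrate within seconds. The same command on the
periphery fit (`0.013 t^0.39`) gives `d_f = 2.10`, i.e. heterochromatin-rich
peripheral domains are more compact — the central structural conclusion the
model extracts from imaging. `chromdyn table1` prints both regions at
`α = 0.8` and `0.9` in one table; `chromdyn alpha-sweep` and
`chromdyn ncd-sweep` scan the assumptions.

The same pipeline runs end to end on synthetic data:

```python
from chromdyn import (FractalDomainModel, SimulationConfig,
                      simulate_tracking_experiment, SubdiffusionModel)

model = FractalDomainModel(alpha=0.9, d_f=2.09, n_nucleosomes=5000, r_rms=0.268)
cfg = SimulationConfig(model=model, n_tracks=2000, frames_per_track=11,
                       frame_interval=0.001, n_modes=4000,
                       localization_sigma=0.0, seed=101)
tracks = simulate_tracking_experiment(cfg)
res = SubdiffusionModel.from_tracks(tracks).fit(window=(0.001, 0.010))
print(res.fit.beta)                       # 0.4455 (truth: 0.44)
print(res.estimate_domain(alpha=0.9))     # d_f 2.04, R 284 nm (truth: 2.09, 268 nm)
```

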