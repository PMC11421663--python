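# Methods

This note records the model, the numerical design choices, and the known
limitations of `blunmix`.

## Physical model

The package unmixes *changes* in broadband optical attenuation into changes in
chromophore concentrations using the differential form of the modified
Beer–Lambert law. For a measured attenuation change ΔA(λ) (natural-log
convention, ΔA = −ln(I/I₀)) over an effective optical pathlength *l*
(default 1, i.e. concentrations are reported in concentration × pathlength
units):

```
ΔA(λ) = −l · [ Σᵢ Δcᵢ · μₐⁱ(λ) + Δ(s·μs)(λ) ]
```

* `μₐⁱ(λ)` — specific absorption spectrum of chromophore *i* (the columns of a
  `ChromophoreBasis`). Stock chromophore sets cover oxy-/deoxy-hemoglobin,
  cytochrome-c-oxidase redox signals, water and fat.
* `Δ(s·μs)(λ)` — the change in the scattering loss term between the
  measurement and the baseline state. Each state's scattering is modelled as a
  power law `s · (λ/500 nm)^−b` with weight `s ∈ [0, 100]` and power
  `b ∈ [0, 5]`, so the net term is `s₂·u^−b₂ − s₁·u^−b₁` with `u = λ/500`.

Two model variants exist: **linear** (scattering change neglected) and
**scattering** (the four scattering parameters fit jointly with the
concentrations).

### Identifiability

Only the *net* scattering curve `s₂u^−b₂ − s₁u^−b₁` enters the data. Any
(s₁,b₁,s₂,b₂) producing the same net curve is equivalent — in particular every
pair with `s₁=s₂, b₁=b₂` is an exact zero. Fits are therefore judged on the
reproduced attenuation and the concentration changes, never on individual
scattering parameter values. Near-equal exponent pairs (b₁≈b₂) are the
hardest regime: the two power-law columns become collinear and the problem
has long, shallow valleys.

## Solvers

**Linear.** Closed-form pseudoinverse of the scaled basis, `Δc = pinv(−l·B)·ΔA`.
Rank deficiency of the basis is an error at construction time and re-checked
at solve time; the solver never returns a silent minimum-norm answer for an
underdetermined system.

**Scattering.** Bounded trust-region nonlinear least squares (scipy TRF) over
(Δc, s₁, b₁, s₂, b₂) with an analytic Jacobian, multistarted as follows:

1. *Warm start.* Δc initialised at the linear solution, scattering parameters
   at the midpoints of their bounds with s₁=s₂, b₁=b₂ (zero net scattering).
   The starting residual therefore equals the linear fit's residual.
2. *Global exponent search (variable projection).* For fixed (b₁,b₂) the
   model is linear in (Δc, s₁, s₂), so these are profiled out by a
   box-constrained linear solve (BVLS) on a full (b₁,b₂) grid. Bounding the
   weights during profiling is essential: unconstrained profiling finds
   out-of-bounds representations (e.g. s≈770 in near-collinear cells) that
   are useless once clipped. The best grid cells are kept under a diversity
   rule (at least two grid steps apart in either exponent, because
   near-degenerate data produces several basins of almost equal profiled
   cost), and each kept cell's exponents are refined by a bounded 2-D solve
   on the profiled residual before joint polishing.
3. *Candidate selection.* Every start point (including the unpolished warm
   start) and every polished solution is a candidate; the winner has the
   lexicographically smallest (spectral MAE, sum of squares). Ranking by the
   reported metric (MAE) rather than the optimised one (SSE) guarantees the
   nesting invariant below even on noisy data, where the two optima differ.
4. *Final variable-projection refine.* If the best candidate's MAE is still
   above the numerical noise floor, its two exponents get one more bounded
   2-D refine on the profiled residual. The joint 6-parameter polish can
   stall in the ill-conditioned valley around the optimum; the profiled
   2-parameter problem is far better conditioned there and typically closes
   the last few orders of magnitude in one short solve.

Early exits stop the multistart loop once the best candidate reaches the
machine floor (SSE ≤ n·10⁻²⁴) or a spectral MAE of 10⁻⁹·max(1, mean|ΔA|).

### Model comparison and the nesting invariant

`compare_models` fits both variants and reports
`r = (MAE_scatter − MAE_linear) / MAE_linear` (negative r = the scattering
model fits better). Two design points:

* **Degenerate r.** On data the linear model fits to machine precision, r is
  a 0/0 limit of two noise-floor numbers. When `MAE_linear ≤ 1e−12` the
  comparison reports `r = 0` with `degenerate=True` instead of a meaningless
  ratio.
* **Strict nesting.** The linear reference is the *unconstrained*
  pseudoinverse, so the scattering fit inside `compare_models` runs without
  concentration bounds (scattering parameters stay bounded — they only add
  degrees of freedom). With default bounds a linear solution lying outside
  them would be clipped at warm start and the invariant
  `MAE_scatter ≤ MAE_linear` could fail spuriously. Standalone
  `solve_nonlinear` keeps concentration bounds on by default.

## Training data generation

Two strategies build surrogate training sets:

* **Strategy (a), generative:** parameters are drawn uniformly from
  physiological ranges and spectra are synthesized by the forward model. The
  (spectrum, parameters) pairs are exactly forward-consistent by
  construction — regenerating a spectrum from its stored targets is bitwise
  identical.
* **Strategy (b), solver-distilled:** spectra come from measurements (or the
  pseudo-real generator) and the targets are the *classical solver's
  outputs* on those spectra. The surrogate then imitates the solver on the
  real input distribution, including its behaviour on noise. On noiseless
  linear data the two coincide with the planted truth.

Sampling ranges default to the stock bounds (hemoglobins ±0.5 mM·cm⁻¹,
cytochrome signals ±0.25, water/fat ±0.1 volume fraction, s ∈ [0,100],
b ∈ [0,5]); `derive_ranges_from_fits` can instead widen/derive ranges from a
batch of classical fits on pilot data.

### Pseudo-real generator

`generate_pseudo_real` produces seeded fixtures in two modes:

* **Time series** (transmission spectroscopy): a smooth
  hypoxia-like excursion profile drives the hemoglobin and cytochrome
  concentrations over time, optional distinct before/after scattering states,
  optional Gaussian intensity noise, baseline at the first timepoint.
* **Spatial cube** (reflectance imaging): three tissue regions (background
  plus two planted contrast regions, one hemoglobin-dominant and one with the
  cytochrome signal pushed the other way) with a blood-vessel pixel used as
  the spatial baseline. Region labels and planted concentration changes are
  returned as ground truth.

The generator is for exercising the pipeline, not for realism: it uses
synthetic smooth chromophore spectra, uniform pathlength, wavelength-
independent Gaussian noise, and piecewise-constant spatial structure. None of
the shipped spectra are measured extinction coefficients; real analyses must
load a measured extinction table via `load_spectrum_table`/`load_basis_manifest`.

## Surrogate

A plain NumPy multilayer perceptron (no deep-learning framework): Adam,
mini-batch MSE on z-scored inputs/targets, early stopping with best-weights
restore, activations ELU / Hardshrink(0.5) / LeakyReLU(0.01). Training is
bitwise deterministic for a fixed seed. `random_search` tunes
(depth, width, learning rate, activation, batch size) over a log-uniform /
categorical space and returns the trial table. Shipped presets cover both
acquisition conventions × both training strategies. Checkpoints are HDF5 and
round-trip bitwise.

## Problem sizes

Stock configurations: 244 wavelengths (740–900 nm, 3 chromophores + 4
scattering parameters) for broadband NIRS; ~120 wavelengths (530–750 nm,
6 chromophores) for hyperspectral imaging. Typical timings on one CPU core:
linear solve ≪ 1 ms; local nonlinear solve ~100 ms; global-search nonlinear
solve ~0.4 s; surrogate inference microseconds per spectrum when batched
(see `scripts/benchmark_inference.py`).

## Limitations

* The pathlength *l* is a single scalar; wavelength-dependent pathlength
  (differential pathlength factor spectra) is out of scope.
* Scattering parameters are reported but not individually identifiable (see
  above); downstream code must not interpret s₁ or b₁ alone.
* ENVI and vendor file formats are not read; I/O is CSV/TSV tables, YAML
  manifests and HDF5 containers.
* The surrogate's accuracy is only certified on the distribution it was
  trained on; out-of-range spectra degrade silently (no extrapolation guard).
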