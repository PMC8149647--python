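# Methods

## The imaging model

A thin transparent object at the plane `z = 0` is described by its complex
transmission

    U_obj(x, y) = A(x, y) · exp(j φ(x, y)),     A ∈ [0, 1],  φ ∈ [0, 2π),

illuminated by a unit-amplitude coherent plane wave.  The field at a sensor
a distance `z` away follows from the angular spectrum of plane waves,

    U(x, y; z) = F⁻¹{ P(ν; λ, z) · F(U_obj) },
    P(ν; λ, z) = exp( (2πjz/λ) · sqrt(1 − (λν_x)² − (λν_y)²) ),

an exact scalar propagator (no paraxial approximation).  The sensor records
only the intensity `H = |U|²` — the Gabor in-line hologram.  Because the
detected phase is lost, naive backpropagation `P_{λ,−z} H` superimposes the
conjugate (twin) image on the object; recovering `A` and `φ` from a single
`H` is the ill-posed inverse problem this package solves.

Discretization: spatial frequencies live on the DFT lattice with spacing
`1/(N·Δ)`, DC at index 0.  Spatial frequencies beyond the propagating band
(`(λν)² > 1`) are zeroed by default; an exponential-decay policy is
available.  Propagation on the native grid is a circular convolution;
`pad_factor = 2` pads by edge replication (so a unit background stays
physical) and crops back, and is the default for the hologram simulator.
The `propagate`/`transfer_function` implementation is validated in the test
suite against direct summation of the first Rayleigh–Sommerfeld integral
(agreement ~1e−14 on band-limited sources, NRMS 6e−3 on a hard-edged disc)
and of the Fresnel integral (5e−5 on a smooth object).

## The reconstruction

The solver fits an under-parameterized *deep decoder* network through the
forward model to the single measured hologram:

    L(w) = mean( ( |P_{λ,z}( c · A_w · e^{j φ_w} )|² − H )² )  +  decay,

where `(φ_w, A_w)` are the network's two output channels and `c ≥ 1` is a
training-time amplitude multiplier (below).  The network maps a *fixed*
random tensor `B0` (16×16×256 by default, i.i.d. `N(0, 0.1²)`) through `d`
identical layers — twofold bilinear upsampling, a 1×1 convolution, ReLU,
and per-channel normalization with learnable scale/shift — to a 512×512
two-channel image; phase is bounded by `2π·sigmoid`, amplitude by `sigmoid`.
All trainable scalars (1×1-conv weights, output weights, normalization
scales and shifts) total 330,752 for the default shape — fewer than the
2·512² = 524,288 output values.  This under-parameterization is the image
prior: the network can only express images assembled from few channel-mixed,
progressively upsampled feature maps, which favors natural, piecewise-smooth
objects over twin-image fringes.

Three regularizers are combined:

1. **Decoupled weight decay** (AdamW): every trainable parameter is shrunk
   by the factor `(1 − α·η)` per step, independent of the loss gradient
   (α = learning rate 0.01, η = weight decay 0.002 by default).  The
   contract is tested literally: a step at zero gradient multiplies all
   weights by exactly `(1 − αη)`.
2. **Bounded outputs**: the sigmoid mappings enforce the physical ranges at
   every iteration, for any weights.
3. **Scheduled random perturbation**: every 500 iterations fresh Gaussian
   noise (σ = 0.02) is added to the stored base tensor (never accumulated),
   and the amplitude multiplier `c` alternates between 1.3 and 1.4
   (starting at 1.3).  The perturbations kick the iterate off whatever
   narrow minimum it is settling into; the loss trace shows spikes at each
   event with a downward trend between them.

After the main stage an optional refinement stage (5,000 iterations by
default) continues with the weight decay reduced tenfold and the
perturbation disabled.  The refinement stage runs with `c = 1`: during the
main stage the network represents the object's amplitude at roughly `1/c`
of its physical scale (the effective amplitude seen by the forward model is
`c·A_w`), and since the returned object is always decoded at coefficient 1,
the refinement stage is where the amplitude channel re-calibrates.  Neither
stage uses early stopping; the iteration budget is fixed.

Optimizer moments use the conventional β₁ = 0.9, β₂ = 0.999, ε = 1e−8,
recorded in each run's config snapshot.  Weight decay applies to all
trainable parameters, including the normalization scales and shifts.

The forward and backward passes are written directly in NumPy: the
architecture is small and fixed, so the exact gradients of the loss through
the intensity, the linear propagator (adjoint `F⁻¹ diag(conj P) F`), the
sigmoid outputs, the channel normalization, the 1×1 convolutions, and the
bilinear upsampling (a separable linear operator with an explicit adjoint)
are short closed forms.  They are verified against central finite
differences in the test suite (relative agreement ~1e−8).

### Numerical conventions

- Channel normalization divides by `std + ε` (ε = 1e−5), statistics over
  the spatial positions of each channel; constant channels collapse to the
  shift parameter.
- Bilinear upsampling uses the half-pixel (corner-alignment off) convention
  with edge clamping, so results are reproducible across frameworks.
- 1×1-conv weights initialize uniform fan-in, `U(±1/√k_in)`; the fixed
  input tensor is `N(0, 0.1²)`; normalization starts at scale 1, shift 0.
- The solver always fits on the native (unpadded) grid, matching the
  physical 512×512 crop of a real capture; padded propagation is a
  simulation-side tool.
- A NaN loss aborts with the iteration index rather than running on.
- Identical inputs and seed reproduce the loss history bit-for-bit.

### Phase gauge and evaluation

An intensity measurement fixes the object phase only up to an additive
constant (a global phase factor drops out of `|U|²`), and weight decay
biases the sigmoid phase channel toward its midpoint π.  All phase-SSIM
comparisons therefore gauge-align first (`metrics.align_phase`): the
circular-mean offset between reconstruction and reference is removed and
the deviation re-wrapped continuously.  The alignment is applied to every
method identically; amplitude comparisons clip to [0, 1] and use SSIM with
a uniform 7×7 window, k₁ = 0.01, k₂ = 0.03 (data range 1 for amplitudes,
2π for phases).

### Phase-only variant

The classical physics-informed deep-image-prior baseline assumes a
transparent object: the decoder emits one phase channel and the amplitude
is the constant matrix filled with `s = mean(background)`.  It is optimized
by plain Adam (no weight decay by default, though the flag is honored; no
perturbation; 20,000 iterations by default).  It performs well on genuinely
pure-phase objects and degrades when the object absorbs — the mismatch
leaks into the phase estimate — which is the motivation for fitting both
channels.

## Baselines

- **Backpropagation**: `P_{λ,−z} H`, split into modulus and wrapped phase.
  The twin image is left in place; every method is compared against this.
- **Multi-height phase recovery (MHPR)**: alternating projections over
  holograms at several distances.  Initialization is `sqrt(H₁)` with zero
  phase at the first plane; each round sweeps forward plane-to-plane and
  wraps back to the first (a circular sweep), replacing the modulus with
  the measurement and keeping the evolved phase; 20 rounds by default, then
  backpropagation to the object plane.  The residual at the first plane
  (measured on return, before projecting) decreases monotonically on
  noise-free stacks.  Relaxation is not used; plane ordering and round
  count are free choices of this implementation.

## The synthetic study

The simulator emulates the reference geometry: λ = 532.2 nm, object plane
300 µm from the sensor, 1.12 µm pitch, and 50 µm spacing for six-plane
stacks (the experimental-config template uses the source's 532.3 nm line).
Phantoms are pure functions of `(parameters, seed)`:

- `blobs` — smooth cell-like phase bumps (excursion ≤ π) with spatially
  correlated absorption dips; the default test object.  The ≤ π excursion
  avoids the wrapped-phase ambiguity, which no method here attempts to
  resolve.
- `bars` / `grating` — periodic line pairs (8 px / 4 px period).
- `usaf_like` — isolated three-bar groups at decreasing scales.

Simulated holograms propagate with 2× edge padding (then crop) to suppress
wraparound, and carry an optional additive Gaussian detection-noise term
clipped at zero.  The blur ladder uses σ = 0, e⁰, e¹, e², e³ with kernel
support `d(σ) = 6·round(σ) + 1` (round half-up); the contrast ladder scales
deviations about the image mean by c = 1, 0.75, 0.5, 0.25, 0, clipped to
[0, 1] (the mean-preserving reading of "contrast reduction").

What the synthetic study does *not* model: partial coherence, speckle,
sensor nonlinearity and quantization, mechanical drift between stack
planes, thick or axially extended objects, and wrapped phase.  Passing the
synthetic tests therefore demonstrates the correctness of the optics, the
network, and the optimization contracts, and the *relative* ordering of
methods under ideal coherent imaging — not performance on real captures.

## Scaled problem sizes

The full-scale configuration (512×512 hologram, 5-layer/256-channel
decoder, 30,000–35,000 iterations) is what one would run on real data.
The package's own studies and tests run a reduced configuration chosen as a
faithful miniature: 64×64 holograms, an 8×8-input, 3-layer, 64-channel
decoder, 2,000 main iterations plus 500 refinement.  At this scale the
reduced decoder is *not* under-parameterized (12,800 parameters for 8,192
output values); the under-parameterization claim is asserted only for the
default network, and the scaled runs rely on the remaining regularizers.
Orderings observed at this scale (regularized fit beats backpropagation;
beats the unregularized ablation; six-plane MHPR beats single-shot
backpropagation; phase-only succeeds on pure-phase objects and fails under
absorption) reproduce the full-scale behavior qualitatively.  The amplitude
orderings are robust across specimen seeds.  Phase recovery at this budget
is hit-or-miss per specimen: most runs beat backpropagation on both
gauge-aligned SSIM and RMSE, but an occasional run converges to a
conjugate-dominated (twin) phase solution — for weakly scattering objects
the hologram is nearly invariant under phase sign flip, and 2,000
iterations of perturbation are not always enough to escape the wrong
basin; the full-scale 30,000-iteration recipe and the stronger
under-parameterization of the 512×512 network are what make phase recovery
reliable.  Windowed SSIM of mostly-flat phase maps is additionally noisy
in itself (its luminance term penalizes smooth residual background offsets
while rewarding flat-but-uncorrelated noise).  The acceptance study
therefore reports both phase indices, averaged over three specimens, and
the per-specimen spread should be expected to be large.

## Known limitations

- Phase unwrapping is out of scope; objects with phase excursions beyond π
  reconstruct with artifacts.
- The solver's loss is a circular convolution on the native grid; objects
  with significant energy at the crop border will alias.
- The amplitude multiplier makes the *training-time* amplitude scale
  conventional; runs without a refinement stage return amplitudes biased
  low by ~1/c.
- MHPR assumes perfectly registered, identically normalized planes.
- The NumPy implementation is single-process; a full-scale 512×512 run is
  minutes-per-thousand-iterations on one CPU core.
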