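# Methods

## Imaging model

The package models single-plane, scalar, time-gated reflection imaging
through one effective aberrating layer. A focused beam is scanned over the
field of illumination (FOI) at the diffraction-limited interval
δ_d = λ/2α; for each scan position **r**ᵢ the de-scanned camera field over
the field of detection (FOD) is

    E_cam(r_cam; r_i) = Σ_r P_o(r_cam − r) · O(r) · P_i(r − r_i) + E_M,

with O(**r**) the complex amplitude reflectance (|O| ≤ 1), and P_i, P_o the
amplitude PSFs obtained as centered inverse DFTs of the pupil functions
mask·e^{iφ_{i,o}(**k**)} on the NA disk |**k**| < 2πα/λ. Time gating is
modelled implicitly: E_M is the *time-gated* multiple-scattering residue,
drawn i.i.d. circular complex Gaussian per pixel per frame ("white
speckle"), with variance calibrated so that the mean confocal signal
intensity divided by the mean noise intensity equals the requested
single-to-multiple-scattering ratio (ssmr). The lab-frame field follows
from the de-scan relation E_lab(**r**_o; **r**ᵢ) = E_cam(**r**_o − **r**ᵢ; **r**ᵢ).

Assumptions and non-goals: scalar diffraction (no vectorial high-NA
polarisation), a single sample plane (no depth-resolved scattering), one
effective pupil screen per isoplanatic patch, no interferogram synthesis
(the model starts from complex fields), no motion or phase drift between
frames.

### Discretisation

The simulation lives on a periodic square grid (circular convolutions; the
brute-force oracle uses the same circular indexing, so the two agree to
rounding). Default sampling is Nyquist for the field: pixel pitch
δ_d/2, scan step δ_d = 2 pixels, so de-scan shifts are exact integer rolls
and never interpolate. All DFTs are unitary and centered (zero frequency
and spatial origin at index n//2); the k-grid spacing is δk = 2π/L for
field side L. The NA mask is the *open* disk |**k**| < 2πα/λ: with the
scan lattice sampled exactly at the pupil Nyquist rate, the open disk is
alias-free, and the scan-lattice reflection matrix factorises exactly as
R̃ = diag(e^{iφ_o}) Õ diag(e^{iφ_i}) for shift-invariant screens (verified
to 1e−15 in the tests). The coarse solver k-grid is the central crop of
the fine simulation k-grid, so truth screens and retrieved maps share one
grid without interpolation.

## CLASS solver

Anti-diagonal sums R_CLASS(Δk) = Σ_{k_i} R̃(k_i+Δk; k_i) are taken over the
full difference set (no wrap-around). The phase increments are

    φ_i-step(k_i) = arg Σ_{k_o} R̃(k_o; k_i)* · R_CLASS(k_o − k_i)
    φ_o-step(k_o) = arg Σ_{k_i} R̃(k_o; k_i)* · R_CLASS(k_o − k_i)

i.e. every matrix entry is correlated against the CLASS spectrum at its own
momentum difference. Written this way both estimators weight each term by
|Õ(Δk)|² — no object phase enters — so they apply to diffuse (complex
reflectance) objects as well as to real-valued targets. The increments are
applied multiplicatively (phase-only: per-entry moduli are preserved
exactly) and accumulate across iterations; the negated accumulated phases
are the estimated pupil aberrations.

**Update order.** The two increments are applied *sequentially*: the input
increment is applied and the spectrum recomputed before the output
increment is estimated. Estimating both sides from the same spectrum
double-counts the shared (confocal-channel) component of the correlations
and measurably overshoots: on the 64×64 Siemens-star instance the
simultaneous variant needs ~98 iterations and shows relative objective dips
up to 7×10⁻⁴, while the sequential variant converges in ~65 with a strictly
non-decreasing objective and identical recovery. The objective is the total
confocal intensity Σ|diag R_c|², computed cheaply from the folded CLASS
spectrum.

**Stopping.** Convergence is declared when the piston-removed RMS of both
increments falls below `tol_rms_rad` (default 0.01 rad) *and* the objective
has stagnated (relative change < 10⁻⁶). The second condition matters: on
some realisations the first iterations take small but *growing* steps while
the coherent sum bootstraps (measured increments 0.006 → 0.14 rad over ~30
iterations before collapsing at the optimum), and an increment-only test
can fire during that phase. `max_iter` defaults to 50; heavily noisy data
(ssmr ≈ 0.08) benefits from 100–200.

**Degeneracies.** Piston trades against the object's global phase and a
linear pupil tilt against a global image shift; neither affects any
intensity. All comparisons between phase maps therefore remove piston and
the best-fit tilt (found as the sub-pixel peak of the focus formed by the
masked phasor difference) and use circular statistics: RMS of the wrapped
aligned difference, and the Pearson correlation of the unit-circle
embedding (cos, sin) of the aligned maps — plain Pearson on wrapped values
is biased by 2π flips at the branch cut, and for near-uniform wrapped
screens has a spurious baseline. Strehl ratios use the simulated flat-pupil
reference on the same grid; "corrected Strehl" is the on-axis pupil average
of the aligned residual (the raw grid-sampled peak under-reads by up to
~30 % from sub-pixel tilt alone).

## Locally varying correction

Tiles partition the scan grid (cores), optionally expanded by an overlap
margin; each tile's output window extends the subregion by half the FOD per
side (side √FOD + √FOI, capped at the periodic grid extent). The tile
matrix is rectangular (window pixels × subregion scan positions); zero
columns are appended at window pixels that were never illuminated,
preserving spatial registration, and the square matrix is transformed with
δk = 2π/(√FOD + √FOI) on both sides. This keeps the full FOD-supported
mode set N_c = π(√FOD/2δ_d)² available per tile regardless of subregion
size.

Because the padded input side is a unitary mixture of only N_i real
columns, the two-sided estimator loses the per-side split (the sum
φ_i + φ_o stays exactly determined — verified at coherence 0.994 — but a
gauge function can migrate between sides). Optical reciprocity supplies the
missing constraint: by default only the output step is estimated (rows are
never padded) and φ_i(**k**) := φ_o(−**k**) is mirrored onto the input
side. The two-sided sequential path remains available
(`reciprocity=False`) and, with a single unpadded tile, reduces exactly to
the global solver.

Two numerical points discovered during validation:

* **Intensity normalisation.** Correcting a column-selected matrix from the
  right dilutes the corrected diagonal by the illuminated-column fraction
  N_i/N_o (measured exactly: 0.25 at quarter tiling, 1/16 at 1/16 tiling).
  Per-tile corrected intensities are renormalised by N_i/N_o so the
  isoplanatic-size sweep compares subregion sizes on one scale; the
  remaining few-percent residue is absorbed by the sweep's plateau
  tolerance (`rel_tol = 0.03`).
* **Specular objects.** For a strictly real, DC-dominated reflectance the
  confocal channel of the step correlations estimates the *sum*
  φ_i + φ_o on both sides; the mirrored update then double-applies the
  symmetric component and stalls (measured saturation at embedding Pearson
  ~0.7–0.8). Diffuse reflectance — per-pixel random phase, the realistic
  regime for tissue, where speckle-like single-scattered returns carry the
  correction signal — removes the effect. The anisoplanatic fixture is
  therefore diffuse; the global Siemens-star fixture stays real like a
  physical resolution target.

Stitching blends per-tile images with raised-cosine weights over the
overlap margins, explicitly normalised to a partition of unity (zero margin
degrades to crop-and-abut). `estimate_isoplanatic_size` sweeps candidate
subregion sides and returns the *largest* side whose mean corrected
intensity is within `rel_tol` of the maximum, flagging plateaus: corrected
intensity saturates for subregions at or below the isoplanatic size and
drops steeply above it (~3× for the two-patch fixture).

**Winner-take-all caveat.** On a mixture of exactly two large noise-free
patches, a single oversized correction does not converge to a useless
average: the coherent-gain iteration locks onto whichever patch is
marginally stronger and recovers *its* screen well, while the other half of
the image stays aberrated and the total corrected intensity is ~3× below
the tiled result. Mode-averaging failure (a smooth, useless map) is
expected instead when many patches share the FOI under strong
multiple-scattering noise, where no single patch can bootstrap. The
intensity criterion — not map correlation — is therefore the reliable
detector of an oversized subregion, and is what the patch-size estimator
uses.

## Synthetic data and what passing tests show

Pupil screens come from two generators: Zernike sums (Noll-normalised) for
smooth low-order aberrations, and "bandlimited speckle" — the argument of a
Gaussian random field smoothed to a correlation length ℓ — for the
complex, speckle-like maps characteristic of bone. The effective mode count
is defined as NA-disk area over correlation area, M = πk_NA²/ℓ²; at the
default M = 500 on the ~800-sample solver mask the screen is close to
per-sample random, i.e. aberration complexity comparable to the correction
capacity, which is the hard regime. This is a statistical stand-in, not a
physical model of any particular medium.

Default study conditions (fixtures): 64×64 object grid at pitch 0.225 µm
(λ = 0.9 µm, NA 1.0, field 14.4 µm), 32×32 scan positions at δ_d = 0.45 µm,
FOD equal to the full field; reciprocal screen pairs φ_o(**k**) = φ_i(−**k**);
ssmr 0.08 for the noisy fixture (the through-skull regime); the
anisoplanatic fixture has two independent screen pairs on the left/right
halves (7.2 µm patches) of a diffuse filament phantom over a 0.3-amplitude
diffuse background that balances the retrieval signal between patches.
These sizes keep the full suite under two minutes on one CPU; they are
~5× smaller per side than the instrument's typical fields, so absolute
mode counts are scaled down while all dimensionless regimes (modes ≈
capacity, ssmr, patch/FOI ratios) match.

What the synthetic model does *not* emulate: depth-resolved gating and
defocus, spatially correlated multiple scattering, frame-to-frame motion
and phase drift, detector noise, and vectorial effects. Passing tests
demonstrate the correctness and internal consistency of the algorithms
under the stated model, not performance on real tissue.

## Numerical conventions

Angles in radians, lengths in µm, spatial frequencies in rad/µm,
everywhere. arg(0) := 0 in the phase steps (dark or masked-out modes are a
no-op); phases outside the NA mask are never updated. Piston/tilt removal
is applied only for reporting and comparison, never inside the iteration.
`wrap_phase` maps to (−π, π]. HDF5 containers store complex64 stacks with
full metadata and optional ground truth; a format-version field guards
round trips. Identical seeds give bit-identical stacks, and the solver is
deterministic, so every CLI run is reproducible from its logged
configuration.
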