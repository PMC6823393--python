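# Methods

`minwave` quantifies the self-organization of the *E. coli* Min system
(MinC/MinD/MinE) reconstituted in cell-free expression reactions: surface
waves on supported lipid bilayers (SLBs), oscillations of a membrane-bound
reporter inside liposomes, the coupling of those oscillations to vesicle
shape, and the kinetics of cell-free protein synthesis quantified by
targeted LC-MS. Because raw imaging data of such experiments are rarely
deposited, the package ships a synthetic-data generator whose ground truth
drives every test; this note records the models, the parameter choices,
and what the synthetic conditions do and do not establish.

## Liposome segmentation and tracking

The membrane-dye channel is processed per frame:

1. **Background correction** — white top-hat with a disk of radius 4 px
   (image minus its grayscale opening). The membrane ring is thinner than
   the structuring element so it survives; broad background is removed.
   An alternative reading of "background correction by opening" would
   *replace* the image by its opening, which deletes the thin ring; the
   top-hat reading is therefore used.
2. **Ridge enhancement** — a bank of rotated anisotropic
   Laplacian-of-Gaussian kernels, SDs 3 px along the filter axis and
   0.1 px across, 12 orientations over [0°, 180°) (15° steps keep the
   worst-case angular mismatch at 7.5°, small against the 3-px axial SD).
   The per-pixel maximum over orientations is the ridge response. Two
   discretization choices matter: the kernel support is 11×11 (a nominal
   10-px size rounded up to odd so a sample row lies on the filter axis —
   an even grid straddles axis-aligned ridges and the zero-integral
   profile cancels), and the pixel aperture is folded into the SDs
   (σ_eff² = σ² + 1/12, the variance of a unit pixel box) because a
   zero-mean profile narrower than one pixel otherwise vanishes under
   area sampling. With the nominal 0.1-px cross SD the bank retains a
   grid-anisotropy of ~10% between off-axis orientations; a cross SD of
   ≈0.8 px brings rotation covariance under 5% and is available via
   `sd_across`.
3. **Seeded watershed** — the ridge response is flooded from two markers,
   the seed and the image border, so the membrane ridge acts as the
   barrier between basins. The seed's basin, hole-filled, is the
   segmentation. A basin touching the border means the ridge did not
   close and is reported as a failure rather than returned.
4. **Seed propagation** — frame t+1's seed is frame t's mask eroded by a
   disk of radius max(1, round(0.15·D_eq)), D_eq = 2√(area/π). The 15%
   fraction is scale-free; if erosion empties the mask a 3×3 square at
   the centroid guarantees a non-empty seed. Tracking is declared lost
   when consecutive masks stop overlapping.

## Kymographs, traces and shape

The reporter (GFP) channel is smoothed with a 10×10-px Gaussian kernel of
SD 1.2 px. The perimeter of each mask is traced with Moore-neighbor
boundary following, starting at the topmost-then-leftmost boundary pixel
and proceeding clockwise (image coordinates, y down); this start anchor
fixes the kymograph column origin and the sign convention for circling
direction. Row t of the perimeter kymograph holds the smoothed reporter
sampled along that path, linearly resampled to the longest circumference
of the movie so rows stay aligned when the vesicle deforms.

Membrane and lumen traces use regions the figures of such experiments
imply but rarely define: the membrane band is the 3 px inside the mask
boundary, the lumen is the mask eroded by band+2 px; both are
configurable, and 3 px matches the ring width at the magnifications the
generator emulates.

Shape metrics: elongation is the major/minor axis ratio of the
moment-equivalent ellipse — the square root of the eigenvalue ratio of
the pixel-coordinate covariance, with +1/12 px² on the diagonal (the
variance of a unit pixel) so 1-px-thick masks stay finite. The
normalized perimeter is the circumference of the equal-area circle,
π·√(4A/π). The phase lag between elongation and the lumen signal is the
lag maximizing the circular cross-correlation of the mean-subtracted
series, searched within half the dominant oscillation period (the
cross-correlation of periodic series is itself periodic; without that
restriction the reported lag is ambiguous modulo the period). Positive
lag means elongation leads.

## Wave metrics

**Standing waves.** Every pixel's mean-subtracted temporal
autocorrelation (linear, FFT-computed, lag-0 normalized) is scanned for
its first local maximum at positive lag with prominence ≥ 0.1; the
median of the qualifying lags times the frame interval is the period.
Lags are integer frame counts: at a 2-s interval a 47-s truth is
reported as 46 or 48 s, which the ±4 s reproducibility of such
measurements absorbs. The prominence threshold is configurable since
"first peak if existing" admits interpretations.

**Traveling waves.** A kymograph is sampled every 1 px (bilinear) along
a user-chosen line in the propagation direction. Crests form parallel
stripes; with rows = time and columns = space a stripe at Hough angle θ
has slope −tan θ columns per row, so velocity = median |tan θ| ×
pixel_size / frame_interval over the Hough peaks within ±5° of the
dominant angle. Wavelength comes from the spacing of the parallel-line
family: the ρ-accumulator column at the dominant angle (0.5° angular,
1 px radial resolution) is lightly smoothed (σ = 2 bins, against vote
smearing from edge jitter) and its peaks' median consecutive spacing,
divided by |cos θ|, converted by the pixel size, is the wavelength.
Reading the family off a single angle column avoids the side-lobes that
strong lines cast at neighboring angles, which otherwise contaminate
spacing estimates.

Edge detection before the Hough transform is the rising flank of the
signal along the space axis: the signed Sobel derivative, thresholded by
Otsu on its positive part and thinned to per-row local maxima. Using
only rising flanks marks each wave crest exactly once per wavelength; a
gradient-magnitude edge map would mark both flanks of a symmetric wave
and halve the apparent spacing. Before the Sobel step the kymograph is
denoised with a Gaussian whose scale adapts to the stripe period
(period/12, clipped to [1, 5] px, with the period taken from the spatial
power spectrum): pixel noise otherwise dominates the derivative of
long-wavelength, low-gradient waves. For movies with small-scale
structure (e.g., an FtsZ channel with filament speckle) an explicit
8-px-radius Gaussian preblur of the movie is applied first.

**Oscillation-mode classification.** The phase of the shared dominant
temporal frequency (column-averaged power spectrum, DC excluded, peak
required to exceed 3× the median spectral floor) is computed per
perimeter column. Pulsing: circular SD of phases < 30°. Circling: the
unwrapped phase advances monotonically (Spearman |ρ| > 0.9 against
column index) through more than ~1.2π. Pole-to-pole: doubled phases
concentrate (R₂ > 0.7) while raw phases do not (R₁ < 0.6) and each
antiphase group is internally coherent. Anything else, or no dominant
peak, is undetermined. Thresholds are classifier tuning, not claims
about the biology; they were chosen on noiseless generator output and
then verified at SNR 5.

## Expression kinetics and LC-MS calibration

Concentration time courses follow the phenomenological sigmoid
y(t) = k′ + k·tⁿ/(tⁿ + Kⁿ) with baseline k′ (µM), final yield k (µM),
half-rise time K (min) and steepness n ≥ 1. Two derived quantities:
the expression lifespan T_plateau = 2K/n + K (where the tangent at t = K
meets the plateau level k′ + k) and the apparent translation rate
v = kn/(4K), the slope at t = K. These identities are exercised as
property tests over random valid models.

Fitting is nonlinear least squares (optionally 1/σ²-weighted — the
default is unweighted since weighting is usually unstated in such
analyses), initialized at k′ = min y, k = max y − min y, K = the time of
half rise, n = 4, with bounds k ≥ 0, K > 0, n ∈ [1, 20] and five
jittered restarts to guard against the flat-n direction of the
objective.

Calibration curves are straight lines fitted by weighted least squares
with instrumental variance weights w_i = 1/σ_i² per concentration level
(zero σ replaced by the smallest positive σ in the set, flagged).
Sample concentrations are (intensity/IS_ratio − intercept)/slope ×
dilution, where IS_ratio normalizes to an internal-standard peptide
(e.g., EF-Tu TTLTAAITTVLAK); extrapolation outside the calibrated range
is flagged. Protein concentration is reported from the most C-terminal
quantified peptide, with a warning when coverage stops well before the
C-terminus (as for MinC, where no C-proximal peptide is detectable).

## Synthetic data generator

The generator produces the statistical structure the analysis assumes,
not microscope physics:

* **Liposome scenes** — a circular (or area-preserving elliptical,
  semi-axes r√e and r/√e) cross-section; channel 0 is a membrane ring
  with a radial Gaussian profile of SD membrane_width/2, constant in
  time; channel 1 splits a fixed reporter budget between a ring
  component and a uniform lumen. Pulsing: the membrane fraction is
  (1 + cos 2πt/T)/2, spatially uniform. Pole-to-pole: constant total
  membrane binding split between two antiphase hemispheres whose poles
  sit on the major axis. Circling: a von Mises hotspot (κ = 4)
  advancing one turn per period. The angular weights have unit mean so
  membrane + lumen fractions sum to exactly 1 — the conservation
  invariant the tests check. Oscillation amplitudes are free parameters
  of the generator, not measurements.
* **SLB waves** — traveling: baseline + A(1 + cos 2π(x′ − vt)/λ))/2
  along direction x′; standing: separable spatial × temporal raised
  cosines. Optional spatially correlated speckle emulates filament
  clutter.
* **Kinetics** — the sigmoid model plus i.i.d. Gaussian noise at given
  timepoints and replicate counts.

All channels are blurred with a Gaussian PSF and degraded with mixed
Poisson/Gaussian read noise, everything drawn from one per-call
generator seeded by `seed` (identical spec + seed ⇒ bit-identical
stacks). Not modeled: photobleaching, 3-D projection of the vesicle,
membrane fluctuations, uneven illumination. Passing tests therefore
demonstrate estimator correctness under the stated noise and geometry,
not robustness to every artifact of real microscopy.

Default study conditions used in the recovery experiments: SNR 5
(amplitude/read-noise SD), 2-s frame interval, 150 frames for traveling
waves and 200 for standing waves; kinetics at 7 timepoints
(0–300 min), 3 replicates, 1 µM noise, 100 seeded simulations, with
generating parameters set to the reported MinD/MinE yields, lifespans
and translation rates. Problem sizes (256-px fields, 16-row strips for
the line-kymograph targets where the wave is invariant across rows)
are chosen so the full suite and the acceptance script run in minutes
on a single core.

## Known limitations

* The segmentation handles one liposome per run (seeded tracking), with
  no sub-pixel contour refinement.
* Wavelength/velocity need a user-chosen line roughly along the
  propagation direction, ≥ 2–3 wavelengths long, as in the manual
  workflow it reproduces.
* The mode classifier assumes a single dominant frequency; mixed or
  switching modes return the dominant regime or `undetermined`.
* Kinetic parameter recovery at low signal-to-noise (MinE-like: 5 µM
  yield against 1 µM noise) carries a downward bias of order 10% in the
  lifespan median at the 7-timepoint design; the yield is unbiased.
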