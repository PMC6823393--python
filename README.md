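# minwave

Quantitative analysis of Min-protein self-organization in cell-free
systems: liposome segmentation and tracking, perimeter kymographs and
shape metrics, surface-wave wavelength/velocity/period estimation, and
cell-free expression-kinetics fitting with LC-MS calibration — plus a
synthetic microscopy/kinetics generator that provides ground truth for
every stage.

## Who this is for

The *E. coli* Min system (MinC/MinD/MinE) self-organizes into traveling
and standing waves on supported lipid bilayers (SLBs) and into pulsing,
pole-to-pole and circling oscillations inside liposomes, where it can
also deform the membrane. Labs reconstituting these dynamics from
cell-free expressed proteins need the same small set of measurements
every time: where is the vesicle membrane frame by frame, how does a
GFP reporter partition between membrane and lumen, what are the wave's
wavelength, velocity and period, and how fast and how much protein did
the expression reaction make. `minwave` implements that pipeline as a
tested Python library with a CLI.

## The models at the core

* **Segmentation** — white top-hat background correction (disk r = 4 px),
  an oriented elongated Laplacian-of-Gaussian filter bank (SDs 3 and
  0.1 px, max-projected over 12 orientations), seeded watershed with the
  image border as counter-marker, and frame-to-frame seed propagation by
  size-dependent erosion.
* **Wave metrics** — standing-wave period as the median over pixels of
  the first temporal-autocorrelation peak; traveling-wave wavelength and
  velocity from a line kymograph via Sobel edge detection and a linear
  Hough transform (stripe slope → velocity, parallel-line spacing →
  wavelength).
* **Shape** — elongation as the axis ratio of the moment-equivalent
  ellipse; normalized perimeter π·√(4A/π); phase lag between elongation
  and the lumen reporter signal.
* **Kinetics** — the expression sigmoid y = k′ + k·tⁿ/(tⁿ + Kⁿ) with
  lifespan T_plateau = 2K/n + K and translation rate v = kn/(4K);
  calibration by 1/σ²-weighted linear regression with internal-standard
  normalization.

See `docs/methods.md` for assumptions, parameter defaults and numerical
choices.

## Worked example

Generate a traveling-wave movie at a known ground truth and re-measure it:

```python
import minwave as mw

spec = mw.SlbWaveSpec(image_size=(16, 256), pixel_size=1.0,   # µm/px
                      frame_interval=2.0, n_frames=150,        # s
                      wavelength=43.0, velocity=0.49,          # µm, µm/s
                      noise=mw.NoiseModel(gaussian_sd=20.0), seed=1)
stack = mw.render_slb_movie(spec)
kymo = mw.line_kymograph(stack, (8, 0), (8, 255))
est = mw.estimate_traveling_wave(kymo)
print(f"wavelength {est.wavelength:.1f} µm, velocity {est.velocity:.2f} µm/s")
```

prints

```
wavelength 43.5 µm, velocity 0.49 µm/s
```

— the estimator recovers the generating wavelength (43 µm) and velocity
(0.49 µm/s) from a movie with signal-to-noise 5; the residual ~1 µm
reflects the 1-px Hough radial resolution. The same round trip works for
liposome scenes:

```python
spec = mw.LiposomeSceneSpec(mode="circling", period=50.0, n_frames=100,
                            noise=mw.NoiseModel(gaussian_sd=5.0), seed=0)
stack, truth = mw.render_liposome_movie(spec)

import numpy as np
seed = np.zeros(spec.image_size, bool); seed[40:56, 40:56] = True
masks = mw.track_liposome(stack, mw.SeedMask(0, seed))
smoothed = np.stack([mw.smooth_reporter(f) for f in stack.channel(1)])
paths = [mw.perimeter_path(m) for m in masks]
kymo = mw.build_kymograph(paths, smoothed, spec.pixel_size, spec.frame_interval)
print(mw.classify_oscillation_mode(kymo).label)   # -> circling
```

The CLI mirrors the library: `minwave synth liposome|slb|kinetics`,
`minwave segment`, `minwave kymo`, `minwave waves standing|traveling`,
`minwave kinetics fit|calibrate|quantify`, `minwave run`.

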