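# holoscan

Wide-field lensfree colour microscopy reconstruction: wavelength-scanning
pixel super-resolution with multi-wavelength phase retrieval per R/G/B
band, followed by YUV-space chroma smoothing that removes the rainbow
artifacts of coherent colour holography while preserving brightness
detail. A physically faithful forward simulator generates the hologram
stacks, so the whole pipeline is testable without experimental data.

## How it works

1. **Acquisition model** (`holoscan.synthetic_scene`) — a thin object is
   illuminated by plane waves at 3 bands × 7 wavelengths
   (R 606–642 nm, G 512–548 nm, B 452–488 nm, 6 nm spacing). Each
   wavelength's field is propagated ~1 mm to the sensor by the angular
   spectrum method, and the intensity is integrated over full-fill-factor
   1.85 µm pixels (optional Poisson shot noise), giving 21 low-resolution
   holograms.
2. **Reconstruction** (`holoscan.reconstruct`) — per band: upsampled
   back-propagations of all holograms seed an object estimate, which is
   then refined Gerchberg–Saxton style. Each iteration visits the band's
   wavelengths in turn: propagate to the sensor, constrain every 4×4
   block's mean intensity to the measured hologram (preserving intra-block
   super-resolved detail and all phases), back-propagate, and rescale the
   retrieved phase by the wavelength ratio before moving on. Wavelength
   diversity both suppresses the twin image and recovers detail finer
   than the sensor pitch.
3. **Colour** (`holoscan.colour`) — the three band intensities compose an
   RGB image; converting to YUV (BT.601), mean-filtering only U and V and
   converting back removes rainbow artifacts with the luminance plane
   bit-untouched. A Y-replacement ablation baseline is included.
4. **Metrics** (`holoscan.metrics`) — Michelson contrast of three-bar
   targets, smallest resolved width over a USAF-style ladder, recovery
   fidelity (Pearson r / NRMSE), and a background chroma-artifact score.

`holoscan.field_optics` provides the shared primitives (sampled complex
fields, angular-spectrum kernels with hard evanescent cutoff, tilt
carriers, phase rescaling).

## CLI

```bash
holoscan simulate    --config config.yaml --phantom usaf_ladder --seed 1
holoscan reconstruct --config config.yaml
holoscan colourize   --config config.yaml [--ablation-y]
holoscan evaluate    --config config.yaml [--threshold 0.15]
```

Stages share a fixed run layout (`<run>/holograms`, `/truth`, `/recon`,
`/colour`, `/reports`); see `holoscan/cli_io.py` for the format details
(16-bit TIFF holograms + YAML sidecar, 32-bit float TIFF reconstructions,
PNG colour outputs, JSON reports). A starting config can be produced with
`python -c "from holoscan.cli_io import *; save_config(default_config(), 'config.yaml')"`.

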