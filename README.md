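# vesiclebud

Quantitative image analysis for time-lapse microscopy of budding giant
vesicles. A pear-shaped vesicle cross-section is decomposed into two
superimposed circles (mother section and bud section); assuming rotational
symmetry about the center-center axis, the package reconstructs the surface
area and volume of the corresponding two-sphere union, tracks the neck
angle and the center distance over time, and tests statistically whether
the relative surface area grows while the relative volume is conserved.

A first-class synthetic-data module generates ground-truthed budding
movies (phase-contrast-like rendering: dark membrane ring, bright halo,
paler bud, noise, defocused frames), so the entire pipeline is verifiable
without any external data.

## Layout

| module                   | contents                                                              |
| ------------------------ | --------------------------------------------------------------------- |
| `vesiclebud.geometry`    | exact two-sphere union geometry: classification, neck plane/radius/angle, surface area, volume, Monte-Carlo volume oracle |
| `vesiclebud.contours`    | frame I/O, contour extraction with sub-pixel ridge refinement, neck detection by signed curvature, Taubin circle fit, bootstrap two-circle decomposition, focus QC |
| `vesiclebud.series`      | normalized time series (`S_rel`, `V_rel`, relative radii, theta, d), Mann-Whitney U (exact enumeration or tie-corrected normal approximation), first-vs-final window comparison, Spearman theta-d correlation |
| `vesiclebud.synthetic`   | constraint-based trajectory simulator (volume retention + area ramp + bud-ratio path), frame renderer, movie writer, measurement-noise model |
| `vesiclebud.pipeline` / `vesiclebud.cli` | end-to-end analysis, configuration, logging, plots, CLI |

## CLI

```sh
# generate a ground-truthed synthetic movie (TIFF stack + truth.csv + manifest.json)
vesiclebud simulate --out movie/ --seed 0

# analyze a movie (multi-page TIFF or a directory of numbered PNG/TIFF frames)
vesiclebud analyze --input movie/movie.tif --out results/ \
    --um-per-px 0.08 --s-per-frame 10

# compare analysis output against the simulation ground truth
vesiclebud evaluate --truth movie/truth.csv --results results/
```

`analyze` writes `fits.csv` (per-frame circle parameters in pixel units),
`series.csv` (normalized series), `stats.json` (U-test verdicts and the
theta-d correlation), plots, and a log of per-frame QC decisions. Without
`--um-per-px` / `--s-per-frame` the outputs are in pixel and frame units.
Exit codes: 0 ok, 1 configuration error, 2 input error, 3 insufficient
data. All commands are deterministic given config + seed.

Options may also be given as a JSON config file (`--config`); command-line
flags take precedence.

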