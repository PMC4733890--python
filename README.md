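# retinosign

Analysis of dense microelectrode retinotopic mapping data: Gaussian
distance-weighted interpolation of receptive-field eccentricity and polar
angle onto a regular cortical grid, computation of the local **visual field
sign** (mirror vs. nonmirror image representation of the hemifield),
parcellation of the sign map into candidate cortical areas, landmark-based
warping between the cortex-photo and flatmount frames, and the matching
figure conventions (contour maps, arrow diagrams, sign overlays).  A
synthetic-cortex generator with known ground truth (areal geometry, sign
labels, borders) supports end-to-end recovery tests.

## How it works

Each responsive penetration is a 7-number record: cortical site `(x, y)` in
mm plus receptive-field center eccentricity `r`, polar angle `theta`, and
ellipse `(l, w, phi)` in degrees.  After normalizing every hemisphere to a
right-hemisphere / left-hemifield convention, `r` and `theta` are
interpolated to a grid with weights `w(d) = epsilon + exp(-alpha d^2)`,
gradients are estimated with ~0.5 mm central differences, and the field sign
angle `lambda` is the clockwise angle from grad r to grad theta: near 90 deg
means nonmirror, near 270 deg mirror, near 0/180 indeterminate (gray).
Connected components of uniform sign form the parcellation; borders are
traced at half-cell resolution.

## Command line

```sh
# generate a synthetic 5-strip alternating-sign cortex and sample it
retinosign simulate --out table.txt --n-strips 5 --scatter-sd 2 --seed 1

# full pipeline: grids, field sign map, parcellation, SVG figures
retinosign run-all --table table.txt --outdir out/

# individual stages
retinosign interpolate --table table.txt --outdir out/
retinosign fieldsign   --table table.txt --outdir out/
retinosign parcel      --table table.txt --outdir out/
retinosign plot        --table table.txt --outdir out/
retinosign warp --pairs lesions.txt --table table.txt --out warped.txt
```

All outputs are plain text (grid matrices with headers, border polylines,
the resolved run configuration, a log with seed and versions) plus SVG
figures.  Parameters can also be given in a flat `key = value` config file
(`--config`); command-line flags override it.  Exit codes: 0 ok, 2 input
error, 3 numerical failure.

## Library

```python
from retinosign.rf_data import read_rf_table, normalize_hemisphere
from retinosign.cli import RunConfig, analyze_table

table = normalize_hemisphere(read_rf_table("table.txt"))
results = analyze_table(table, RunConfig(alpha=1.0, epsilon=0.15))
results["fieldsign"].sign_class   # +1 nonmirror / -1 mirror / 0 gray
results["parcellation"].borders   # sign-transition polylines (mm)
```

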