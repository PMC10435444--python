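# vinespec

Vineyard water status from on-the-go NIR spectroscopy.

Irrigation scheduling in precision viticulture needs spatially dense, timely
estimates of vine water stress. The reference measure — stem water potential
(Ψs, in MPa; negative, with more negative values meaning more stress) — comes
from a pressure bomb and is slow, destructive, and sparse. An alternative is
to drive a vehicle along the rows with an NIR spectrometer pointed at the
canopy: leaf reflectance in the 900–2100 nm window carries water-absorption
features (O–H overtones and combination bands near 978, 1454 and
1930–1940 nm) that deepen with leaf water content, and a regression model can
turn block-averaged spectra into Ψs estimates and water-status maps.

`vinespec` implements that whole workflow as a tested, reusable library and
CLI, for chemometricians and plant-phenotyping researchers:

- **synthetic campaigns** (`vinespec.synthetic`) — georeferenced spectral
  streams from two virtual sensors (a 501-channel, 1100–2100 nm bench
  instrument and a 118-channel, 900–1860 nm micro-spectrometer), leaf optics
  with monotone Ψs-dependent water bands, non-leaf interference frames (canopy
  gaps, wires, wood, pipes, berries), a randomized-block layout with three
  irrigation treatments, and per-date Ψs references with a seasonal drying
  trend;
- **acquisition replay** (`vinespec.acquisition`) — dark/white referencing,
  reflectance calibration R = (S−D)/(W−D), leaf-signature capture, GPS
  pairing, and streaming cosine filtering, with the field workflow enforced as
  a state machine;
- **filtering** (`vinespec.filtering`) — cosine screening against the leaf
  signature (threshold 0.985), point-in-polygon allocation to replication
  blocks, per-block averaging;
- **preprocessing** (`vinespec.preprocessing`) — standard normal variate and
  Savitzky–Golay derivatives;
- **chemometrics** (`vinespec.chemometrics`) — PLS1 regression written out as
  the NIPALS recursion (not a library call), ten-fold venetian-blind
  cross-validation with the first-local-minimum rule for choosing the number
  of latent variables, VIP wavelength importance, per-date external
  validation, and the R²/RMSE metric family (calibration / CV / prediction);
- **mapping** (`vinespec.mapping`) — thin-plate-spline interpolation of point
  Ψs values into a classified (≤5 zones) water-status surface, with GeoJSON
  and CSV raster output.

## The model core

Given preprocessed spectra X (n samples × p channels) and responses y (Ψs),
NIPALS PLS1 extracts components a = 1..A:

    w_a = X'y / ‖X'y‖,   t_a = X w_a,   q_a = t_a'y / t_a't_a,
    p_a = X't_a / t_a't_a,   X ← X − t_a p_a',   y ← y − q_a t_a

and the regression vector is b = W(P'W)⁻¹q, so ŷ = (X − x̄)b + ȳ. The number
of latent variables A is the first local minimum of RMSECV over interleaved
ten-fold cross-validation (every 10th sample in the same fold; centering
refitted inside each training fold). Wavelength importance is

    VIP_j = sqrt( p · Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a ),  SSY_a = q_a² t_a't_a,

normalized so mean(VIP²) = 1; channels with VIP > 1 are influential.

## Worked example

```python
from vinespec.pipeline import RunConfig, run_all

result = run_all(RunConfig(seed=0))
print("\n".join(result.log))
```

prints

```
config checksum cd1887e5d613
simulated 6 passes, 216 psi references
filtered 19440 frames: 15608 accepted, 3832 rejected, 29 outside blocks
calibration: 3 LV, R2c=0.916 RMSEC=0.084 MPa, R2cv=0.908 RMSECV=0.088 MPa
external validation: R2p=0.929 RMSEP=0.071 MPa
map 2021-09-15: r=0.965 RMSD=0.021 MPa class agreement=0.809 over 544 cells
```

Reading this: the simulated season is six measurement dates over a 12-block
(4 replicates × 3 irrigation treatments) plot, 36 Ψs references per date. Of
the 19 440 on-the-go frames, the cosine screen accepts 15 608 as true leaf
spectra; block-mean spectra paired with the per-group references give 216
samples. The cross-validated model keeps 3 latent variables and recovers Ψs
with R²cv = 0.91 and RMSECV = 0.088 MPa; the per-date external hold-out
(7 samples per date, extremes shielded, 42 total) gives R²p = 0.93 at
RMSEP = 0.071 MPa. The final line compares the predicted water-status map of
the last date against the map interpolated from the reference measurements:
cell-wise correlation 0.97 and 81% agreement over three irrigation-decision
zones. VIP scores above 1 concentrate near the 978 nm and 1454 nm water bands
and at the 1860 nm sensor edge (the shoulder of the 1935 nm combination
band) — e.g. `result.vip.scores` peaks at the 900 nm edge, 1023 nm, 1400 and
1515 nm, and 1859 nm.

The same pipeline runs stage-by-stage from the shell:

```
vinespec simulate --seed 3 --out run/sim
vinespec acquire-replay --stream run/sim/stream_2021-07-07.txt \
    --dark run/sim/dark_2021-07-07.txt --white run/sim/white_2021-07-07.txt \
    --signature run/sim/signature_2021-07-07.txt --gps run/sim/gps_2021-07-07.txt \
    --out run/session
vinespec filter --session run/session --layout run/sim/layout.geojson \
    --refs run/sim/references.csv --date 2021-07-07 --out run/samples.csv
vinespec train --samples run/samples.csv --out run/model.json
vinespec predict --model run/model.json --session run/session --out run/pred.csv
vinespec map --points run/pred.csv --classes 3 --smoothing 300 --out run/map.geojson
```

or in one shot: `vinespec run-all --seed 0 --out run/`.

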