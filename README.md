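# poppyspread

Tools for analysing how a human settlement (an introduction point) and
hiking trails (spreading corridors) shape the colonisation of a plant
species across a coastal Arctic landscape. The package was built around the
spread of the Svalbard poppy (*Papaver dahlianum*) from a coastal station
along its trail network, but every stage works on any projected-metre
dataset of occurrence records, a DEM, a water mask and trail polylines — or
on the bundled synthetic-landscape generator, so the whole pipeline runs
with no external data.

It is aimed at spatial ecologists and invasion modellers who want a tested,
scriptable version of four analyses that are usually glued together ad hoc:

1. **Establishment-kernel fitting** (`poppyspread.kernels`). From a transect
   abundance survey, establishment distances are built under two source
   assumptions: *local spread* (each individual's source is its nearest
   neighbour) and *trail spread* (each off-trail individual's source is the
   nearest on-trail individual). Six candidate distance distributions
   (log-normal, Cauchy, exponential, exponential power, chi-square,
   Rayleigh) are fitted by maximum likelihood and ranked by histogram SSE
   with BIC as tiebreaker; each fit reports its mean establishment distance
   (closed form; the Cauchy reports its median) and skewness.

2. **Stochastic spread simulation** (`poppyspread.spread`). On a 5-m
   occupancy grid, the annual establishment probability is the FFT
   convolution of the occupied state with the discretised kernel,
   P_e(x, y) = Σ_sources pdf(z)·Δ, and a cell establishes when P_e exceeds
   a fresh Uniform(0, 1) threshold T_e(x, y) (Bernoulli establishment).
   Establishment is limited to suitable cells (no water, elevation below
   the highest observed occurrence) and is irreversible. Two scenarios are
   compared — local kernel only vs. an additional trail kernel applied from
   on-trail sources — and evaluated against presence surveys with the
   sensitivity TP/(TP+FA).

3. **Density attribution** (`poppyspread.density`). A Gaussian KDE of the
   occurrence records, min-max normalised to [0, 1], is regressed on
   z-scored distance-from-station, distance-from-trail, elevation and the
   station×trail interaction (gaussian or poisson GLM), with adjusted
   (pseudo-)R² and leave-one-out partial R² per predictor. Distance
   profiles, trail-distance classes and the paired Wilcoxon test for
   on-trail vs off-trail transect abundances live here too.

4. **Terrain preference** (`poppyspread.terrain`). Rec. 709 relative
   luminance of a 10-cm orthomosaic serves as a gravel-vs-vegetation
   brightness index; a joint-shift randomisation test translates the whole
   observed point pattern rigidly by random offsets (≤ 10 m per axis),
   preserving its internal geometry, and compares median luminance between
   observed and shifted patterns: p = #{medY_i ≥ medY_0}/n over n = 1000
   iterations including the observed one.

`poppyspread.synth` generates complete synthetic study areas (DEM, sea +
lakes, station, two trails, ground-truth spread, systematic and
T-shaped-transect surveys, a 10-cm UAV-style scene) as pure functions of a
seed, and `poppyspread.spatial_core` holds the shared grid/raster/vector
primitives and I/O (ESRI ASCII grid, minimal GeoTIFF, CSV, GeoJSON).

## Worked example

```sh
poppyspread synth make --out data/ --seed 4
poppyspread kernels fit --survey data/transect_2023.csv --assumption local --out fits_local.json
poppyspread kernels fit --survey data/transect_2023.csv --assumption trail --out fits_trail.json
poppyspread spread run --landscape data/ --local-fits fits_local.json \
    --trail-fits fits_trail.json --scenario trail_effect --end 2018 \
    --replicates 3 --seed 7 --out arrival.tif
poppyspread spread evaluate --arrival arrival.tif --obs data/survey_2018.csv \
    --year 2018 --block 250 --out sens.json
```

On this seed the fitted kernels show the corridor effect the model is built
around: the best local-spread kernel (Rayleigh) has a mean establishment
distance of **1.60 m**, while the best trail-spread kernel (exponential
power) has a mean of **24.66 m** — an order of magnitude faster spread when
the trail acts as the source. The trail-effect simulation then covers most
observed presence blocks (`sens.json` reports `"sensitivity": 0.6` with 3
replicates over 90 simulated years; more replicates push coverage up).
The same data drive the density GLM,

```sh
poppyspread density glm --dem data/dem.tif --trails data/trails.geojson \
    --station data/station.geojson --points data/survey_2018.csv \
    --family gaussian --out glm.json
```

which on this seed explains R² = 0.72 of the normalised density with
negative distance-from-station (−0.27) and distance-from-trail (−0.19)
effects, and the terrain test,

```sh
poppyspread terrain test --ortho data/ortho_rgb.tif \
    --scene-spec data/scene_spec.json --points data/poppies_uav.csv \
    --n 500 --seed 3 --out rand.json
```

detects the generator's built-in preference for bright (gravelly) pixels
with p = 0.006.

Everything the CLI does is a thin wrapper over library functions
(`make_landscape`, `rank_fits`, `run_simulation`, `fit_density_glm`,
`randomisation_test`, ...), which are the recommended interface for
scripted analyses.

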