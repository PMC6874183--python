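# mucheck

Volume-based secondary monitor-unit (MU) verification for single-field-uniform-dose
(SFUD) pencil-beam-scanning proton beams.

The tool approximates a target as an equivalent cuboid defined by its volume
and its beam's-eye-view (BEV) projected area, looks up empirically tabulated
factors, and computes the MU for each beam as

```
MU = prescribed_dose / (OF(area, width) x DF(range) x AGF(gap) x calibration)
```

where the SOBP width is `volume / area`, the beam range is the mean
water-equivalent depth (WED) of the distal target surface (plus the
range-shifter water-equivalent thickness, default 4.1 cm, for shifted beams),
`OF` is the output factor (cGy/MU) tabulated against BEV area and SOBP width
at a 20 cm reference depth, `DF` is the depth factor normalized at 20 cm, and
`AGF` is the air-gap factor for range-shifted delivery normalized at the 1 cm
reference gap.  Computed MUs are compared against TPS-prescribed MUs as
`100 x (calc - tps) / tps` and summarized per treatment site.

Because commissioned beam data cannot ship with the package, a self-consistent
analytic toy beam model (`mucheck.beam_model`) stands in for the treatment
planning system: it generates factor tables by simulating cuboid targets
(including the canonical 125 cm^3 cube translated through water and swept over
air gaps), and produces synthetic voxelized cases whose ground-truth MUs come
from an independent per-ray, layer-by-layer dose engine.  The toy model makes
no claim of matching any clinical beam line; it exists so the whole pipeline
can be validated end-to-end offline.

## Layout

| module | contents |
|---|---|
| `mucheck.geometry` | voxel masks, density grids, beam geometry; BEV ray tracing, projected area, water-equivalent depth, distal-surface WED, air gap |
| `mucheck.factors` | OF/DF/AGF tables, CSV + YAML sidecar I/O, validation, interpolation (bilinear / PCHIP, clamp-with-warning outside the grid) |
| `mucheck.beam_model` | analytic Bragg curves, NNLS SOBP flattening, factor-table generation, synthetic case generation with ground-truth MUs |
| `mucheck.mu_calc` | the cuboid model, MU computation, TPS comparison, per-site summary statistics |
| `mucheck.io_cli` | JSON case format, CSV/JSON reports, optional DICOM RTSTRUCT ingestion, the `mucheck` CLI |

## CLI

```bash
# build toy factor tables (CSV + factors.yaml sidecar)
mucheck gen-factors --out tables/

# generate synthetic cases with toy-engine ground-truth MUs
mucheck gen-cases --n 20 --seed 1 --out cases/           # ellipsoids/blobs
mucheck gen-cases --n 0 --seed 1 --nodes --out cases/    # cuboid node bundle

# verify one beam / a directory of beams
mucheck calc --case cases/pelvis_000.json --factors tables/ --out result.json
mucheck batch --cases cases/ --factors tables/ --report report.csv --json report.json
```

Exit codes: 0 success, 2 validation error, 3 when `--strict` is set and any
table lookup had to be clamped to its boundary.

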