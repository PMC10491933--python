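# vesselqpi

Simulated oblique-illumination differential phase contrast (DPC) imaging and
refractive-index (RI) vessel morphometry, end to end:

1. **phantom** — seeded synthetic RI volumes: tubular vessels with
   elevated-RI walls in a 1.3440 background medium, lumens partially filled
   with non-overlapping cell inclusions, optional localized wall breaks and
   fiber-like high-RI wall segments.
2. **optics** — weak-object forward model for four-azimuth DPC acquisition
   (Poisson photon noise), transfer-function construction,
   Tikhonov-regularized phase recovery, and the linear phase ↔ RI
   conversion `Δn = λ·Δφ / (2π·Δz)`.
3. **segmentation** — widest-lumen-slice selection, label-mask TIFF I/O,
   Canny-based blood-cell detection and the `%Fill` statistic.
4. **morphometry** — medial-axis wall-thickness distributions,
   inscribed-circle lumen diameter, the strict `> 20 μm` inclusion filter
   and wall-RI summary statistics.
5. **breakprofile** — geodesic (along-wall) distance from break endpoints,
   20 μm moving mean/SD profiles and the `<50 / 50–350 / >350 μm` region
   classification.
6. **stats** — per-animal aggregation, two-sided unpaired t-test (pooled
   by default, Welch optional) and the two-sided variance F-test.

A pipeline orchestrator and a CLI tie the stages together with full seeded
reproducibility (same config + seed ⇒ byte-identical outputs).

## Conventions to be aware of

- DPC images are sum-normalized: `(I_a − I_b) / (I_a + I_b)`.
- The transfer function has no DC response, so recovered phase is mean-zero;
  recovered RI maps are re-anchored so the background median equals the
  medium RI (1.3440). Absolute wall-RI values carry a band-pass bias that
  shrinks with the Tikhonov `alpha`; group *differences* are preserved.
- `%Fill` divides by the vessel-interior area (wall excluded).
- Geodesic break distances use the 8-connected in-mask pixel graph with
  unit/√2 step weights; each wall pixel takes the minimum distance over the
  break endpoints of its own connected component.
- Region boundaries at exactly 50/350 μm classify as the middle region;
  the moving window is centered.

## CLI

```bash
vesselqpi run --config examples/cohort.yaml --seed 7 --outdir scratch/run7
# or stage by stage:
vesselqpi simulate  --config examples/cohort.yaml --outdir scratch/run7
vesselqpi reconstruct --config examples/cohort.yaml --outdir scratch/run7
...
```

The config is a YAML rendering of `vesselqpi.config.RunConfig`; see
`examples/cohort.yaml`. Outputs per run: phantom RI stacks and label stacks
(32-bit float / 8-bit TIFF), recovered RI slices, mask TIFFs,
`vessel_metrics.csv`, per-vessel break-profile CSV/JSON,
`group_comparisons.csv/.json`, and a `run_manifest.json` with SHA-256
digests of every artifact.

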