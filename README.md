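# sfex — stress fiber extraction from fluorescence micrographs

Actin stress fibers are contractile bundles of F-actin that dominate the
cytoskeleton of adherent cells. Quantifying them from fluorescence
micrographs (e.g. phalloidin-labelled TIRF images) is hard to automate:
fibers cross and converge, bright puncta and diffuse background clutter
the image, and intensities vary severalfold between fibers. `sfex`
implements an automated extraction pipeline for this problem, aimed at
cell biologists who want per-fiber geometry (length, width, orientation)
and network-level statistics from 2D single-channel images without
manual tracing.

## Method

The pipeline has four stages:

1. **Anisotropic enhancement.** The *line filter transform* (LFT)
   rotates a line probe of half-length *r* through orientations
   θ ∈ (−90°, 90°] at every pixel and records the maximal directional
   mean intensity `L_int(x,y) = max_θ mean_t I(x + t cos θ, y + t sin θ)`
   together with the preferred orientation `L_ori`. The *orientation
   filter transform* (OFT) then scores orientational coherence: each
   neighbor's response is treated as an orientation-doubled vector and
   paired with a probe direction α via `ρ cos 2(θ − α)`; the OFT output
   is the magnitude of the summed pairings along the α maximizing the
   absolute sum. Lines gain contrast; isotropic blobs and noise do not.
2. **Segmentation.** Otsu's threshold on the OFT map, morphological
   skeletonization, and removal of junction regions (branch points, their
   neighbors, and crossing debris) yield a pool of unbranched *filament
   fragments*, each with a propagation direction at both termini.
3. **Reconstruction.** Fragment termini are re-paired under four
   geometric criteria — similarity `D(φ_i, φ_j) ≤ φ_max`, proximity
   `‖d_ij‖ ≤ d_max`, continuity `|φ_i − φ_ij| ≤ ψ_max`, and an
   inner-fragment (bridge) test that rejects a direct connection when a
   third fragment can bridge the pair — with candidates ranked by the
   normalized cost
   `C = w_a Δθ/max Δθ + w_g Δθ_gap/max Δθ_gap`. Greedy pairing to a fixed
   point assembles whole fiber centerlines.
4. **Quantification.** Fiber width from the image-gradient maximum along
   Euclidean distance-map levels around a trace (width = 2 × the level
   with the highest mean gradient); per-pixel orientation fields;
   actin-density profiles versus distance from the cell edge; and
   benchmark scoring of detected versus ground-truth filaments
   (false-positive ratio `1 − M/D`, false-negative ratio `1 − M/G`).

A synthetic-phantom generator renders ground-truth filament scenes
(arcs + straight fibers, Gaussian PSF σ = 72 nm at 108 nm/px) corrupted
with additive Gaussian noise at a requested peak signal-to-noise ratio
(PSNR = 20 log₁₀(peak/σ_noise)), so the whole pipeline is testable and
benchmarkable without any external data.

## Worked example

Generate the shipped 9-filament benchmark scene at 25 dB PSNR and run
the full pipeline on it:

```bash
sfex phantom -o scene
# -> 9 filaments, PSNR 25.00 dB -> scene

cat > run.yaml <<'YAML'
phantom: {benchmark: true, psnr: 25.0, seed: 7}
measure_widths: true
YAML
sfex run -c run.yaml -o out
# -> 9 fiber traces -> out
```

`out/manifest.json` reports the run summary:

```
n_fragments: 28, n_traces: 9, n_truth_filaments: 9,
false_positive_ratio: 0.0, false_negative_ratio: 0.0
```

28 unbranched fragments were re-assembled into exactly the 9 ground-truth
fibers (no spurious or missed detections at this noise level), and
`out/fibers.csv` lists per-fiber geometry, e.g.

```
fiber_id,n_fragments,length_px,length_um,width_px,width_um
0,5,234.57,25.33,2.0,0.216
```

— a 25 μm fiber assembled from 5 fragments; its width estimate of 2 px
is the floor value expected for these diffraction-limited phantom lines
(PSF σ ≈ 0.67 px). The same pipeline runs on real micrographs with
`sfex run -i image.tif -o out`.

The library API mirrors the stages: `sfex.make_phantom`, `sfex.enhance`,
`sfex.binarize`, `sfex.skeletonize_and_fragment`, `sfex.reconstruct`,
`sfex.estimate_width`, `sfex.match_and_score`, `sfex.sensitivity_scan`.

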