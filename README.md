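# ringcorr

Correlation-based quantification of membrane periodic skeleton (MPS)
periodicity — and of the relative positioning of two periodic targets —
in super-resolution microscopy images.

The MPS spaces actin rings ~190 nm apart along axons, and many membrane
proteins follow that lattice either in phase with the rings or in the gaps
between them.  `ringcorr` quantifies this without hand-picked line
profiles: a masked image is tiled into grids, each grid is reduced to 1-D
intensity profiles over a sweep of angles, and normalized correlograms
turn every grid into a small set of interpretable numbers.

For a centred profile n′ of length N (population standard deviation σ):

    A(k)      = Σ_{i=1..N−k} n′_i n′_{i+k}        k = 0 … N−1
    A_norm(k) = A(k) / (N σ²)

* **amplitude** — autocorrelation at the second maximum minus the first
  minimum: the periodicity level of the grid (0 = aperiodic);
* **frequency** — lag of the second maximum, in nm: the detected period;
* **shift** (two channels) — lag S of the dominant near-zero maximum of
  the two-sided cross-correlogram `C_norm(k) = C(k)/(N σ₁σ₂)`, folded via
  `L = (F₁+F₂)/4`, `S′ = L − |(S mod 2L) − L|` and classified
  **Overlapping** (S′ < L/2) or **Alternating** (S′ ≥ L/2).

A built-in simulator generates synthetic STED-like images (rings every
200 nm along a skeletonized backbone, tunable point density, kernel,
noise, signal variance, and periodic localization percentage) so the whole
validation study runs from code alone — no microscope data required.

## Worked example

Simulate a two-channel image whose channels alternate (channel 2's rings
sit half a period from channel 1's), then analyze it:

```
ringcorr simulate --pattern alternating --plp 85 --seed 42 --out-dir demo
ringcorr analyze demo/image.tif --mask demo/mask.tif \
    --pixels-per-um 100 --out-dir demo/results
```

`demo/results/per_grid.csv`:

```
grid_index,best_angle_deg,amp_ch1,freq_ch1_nm,amp_ch2,freq_ch2_nm,shift_nm,L_nm,norm_shift_nm,pattern_class
0,4,0.821789,200,0.692129,200,100,100,100,Alternating
1,9,0.697364,200,0.827276,200,90,100,90,Alternating
2,10,0.717614,200,0.700045,200,-90,100,90,Alternating
3,,0.187402,210,0,,,,,
```

Three grids detect the generated 200 nm period in both channels with high
amplitudes (0.69–0.83) and a cross-correlation shift of ±90–100 nm —
half a period, so each is classified Alternating, matching the ground
truth.  The last grid (a sliver at the axon end) fails the 170–230 nm
frequency filter in channel 2, degrades to amplitude 0, and is excluded
from classification.  A `per_angle.csv` audit table and a `manifest.json`
(config, input hashes, version, seed) accompany every run.

The same operations are available as a library:

```python
from ringcorr import SimulationConfig, analyze_image, simulate_pair, synthetic_axon_mask

mask = synthetic_axon_mask(length_um=20, seed=1)
img, truth = simulate_pair(mask, SimulationConfig(), "alternating", 85, 85, seed=42)
result = analyze_image(img)       # result.per_grid is a pandas DataFrame
```

## Scope

`ringcorr` is an analysis and simulation library with a CLI; it does not
include an interactive viewer or GUI mask editor.  Masks can be produced
by thresholding (`make_mask`) or supplied as 8-bit TIFFs from any source.
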