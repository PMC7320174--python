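# zring

Quantification of FtsZ ring treadmilling dynamics on supported lipid
bilayers, for in-vitro reconstitution experiments imaged by TIRF
microscopy — together with the two companion assays such studies lean
on: QCM-D membrane-coverage analysis and colorimetric GTPase-activity
quantification.

## The problem

Membrane-anchored FtsZ (the bacterial tubulin that organises cell
division) self-organises on supported bilayers into rotating rings
("vortices"). The rotation is treadmilling: filaments grow at one end
and shrink at the other, so the pattern moves although no subunit does.
The observable is a time-lapse movie of a ring; the quantity of interest
is the circumferential treadmilling velocity *v* (nm/s), compared across
GTPase-domain mutants and membrane-anchor variants.

`zring` implements the full measurement chain:

1. **Kymograph construction** (`zring.kymo`). A ring is defined by two
   clicked coordinates (treated as a diameter); intensity is sampled by
   bilinear interpolation along three concentric circular trajectories
   (radius r − 1, r, r + 1 px) and averaged, giving a time × arc-position
   matrix whose columns wrap cyclically. Temporal block averaging and
   phase-correlation drift correction come first.
2. **Stripe-slope estimation** (`zring.slope`). A treadmilling ring
   produces diagonal stripes of slope *s* (columns/row). The automatic
   estimator smooths with a 2nd-order Savitzky–Golay filter, applies
   CLAHE, then analyses half-overlapping vertical windows of 50 time
   rows: the dominant temporal frequency f* (cycles/row) is located in
   the column-summed power spectrum, the per-column phase φ(j) of the
   DFT at f* is unwrapped around the ring, and

   s = −2π f* / (dφ/dj).

   Windows failing quality gates (dominant-power fraction, phase-fit R²,
   phase residual, integer phase winding) are rejected; a ring with no
   accepted window is flagged static — the phenotype of
   GTPase-dead mutants. A manual two-point estimator and an independent
   brute-force stripe-alignment search are provided for cross-validation.
3. **Physical velocities** (`zring.velocity`).
   v = s · (arc nm/column) / (s/row), plus ring-diameter estimation
   from the angular-averaged radial profile and static/dynamic
   classification.
4. **QCM-D coverage** (`zring.qcmd`). Sauerbrey conversion
   Δm = −C·Δf/n (C = 17.7 ng cm⁻² Hz⁻¹, 5 MHz crystal, 9th overtone),
   supported-lipid-bilayer formation check (−25 ± 1 Hz plateau), binding
   shifts as plateau-minus-baseline medians, and fold changes between
   constructs.
5. **GTPase activity** (`zring.gtpase`). Linear Pi standard curve (1:2
   serial dilution from 40 µM), absorbance → [Pi] inversion, initial-rate
   fit, dilution correction, turnover and normalization to a reference.
6. **Statistics** (`zring.stats`). Notched-boxplot summaries
   (notch = 1.58·IQR/√n) and two-sided Welch t-tests, from raw samples or
   from printed summary statistics (mean, SD, n).
7. **Synthetic ground truth** (`zring.simulate`). A rotating
   cos²-patterned annulus rendered with a Gaussian PSF, photobleaching,
   drift and Poisson noise; QCM-D traces with the vesicle-rupture
   overshoot; phosphate-release plates. Every analysis stage is validated
   against these generators.

## Worked example

```bash
zring run --seed 7 --out demo
```

simulates three rings treadmilling at the default 35 nm/s, runs the full
kymograph → Fourier-phase → velocity chain, and writes `velocities.csv`:

```
ring_id,velocity_nm_s,speed_nm_s,diameter_nm,static,n_windows_accepted
ring_00,34.926,34.926,971.06,False,3
ring_01,34.922,34.922,973.11,False,4
ring_02,34.881,34.881,971.25,False,3
```

Each ring's recovered speed is within 0.4 % of the 35 nm/s ground truth
and the diameter within half a pixel of the true 1000 nm. The same run
analyses a simulated QCM-D trace (`qcmd_result.json`):

```
slb_check: pass, plateau −25.05 Hz     # SLB formed (−25 ± 1 Hz criterion)
protein_shift: −12.00 Hz → 212.3 ng/cm²  # Sauerbrey coverage of the bound protein
```

and a phosphate-release plate (`gtpase_result.json`), recovering the
simulated 0.05 µM/s hydrolysis rate exactly at zero noise. The library
API mirrors this flow; see `zring.analyze_ring_movie` for the one-call
version on any `MovieStack` + `RingROI`.

As a statistics example, the velocity difference between a wild-type
chimera (35 ± 13 nm/s, n = 1359) and a GTPase point mutant
(25 ± 6 nm/s, n = 216) can be tested directly from the summaries:

```python
>>> import zring
>>> zring.welch_t_from_summary(35, 13, 1359, 25, 6, 216).p
4.9e-61   # significant at any conventional alpha
```

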