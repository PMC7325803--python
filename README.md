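# retinoconn

Quantification of short-association-fiber (U-fiber) connectivity between the
retinotopically defined primary (V1) and secondary (V2) visual cortical
areas, for researchers combining diffusion-MRI tractography with
phase-encoded fMRI retinotopy.

U-fibers are short white-matter fibers running just below the gray–white
boundary that connect adjacent cortical areas. Because V1 and V2 are both
retinotopically organized, their U-fiber connectivity is expected to link
retinotopically *corresponding* locations. `retinoconn` implements the full
quantification chain needed to test that prediction, together with a
synthetic-study generator that provides every input with known ground truth,
so the whole pipeline is testable without scanner data.

## What the package computes

**Retinotopy.** Phase-encoded runs (expanding ring for eccentricity,
rotating ray for polar angle; 8.25 cycles per run) are analyzed by Fourier
transform: after discarding the first quarter stimulus cycle and regressing
out slow drift (DCT basis, cutoffs 1/120 Hz polar and 1/72 Hz eccentricity),
the response phase φ of each vertex at the stimulus frequency *f* encodes its
preferred visual-field position, with the convention that
`A·cos(2πft − φ)` has phase +φ. Runs with opposite stimulus direction carry
phases `φ + δ` and `−φ + δ` for an unknown common hemodynamic delay δ;
conjugating the reversed-run coefficient and averaging the complex values
cancels δ exactly. Visual field sign (the orientation of the
(eccentricity, polar-angle) mapping, sign of the normal component of
∇ecc × ∇pol) distinguishes V1 from V2 (mirror vs non-mirror representation).
Each area is then split into six retinotopic segments: polar angle into two
bins, eccentricity into three, after min–max scaling per area.

**Connectivity.** A tractogram (TCK, mm coordinates) is filtered against a
label volume holding the 6 + 6 segments and a CSF mask: a streamline is
retained iff its endpoints fall in a V1 segment *i* and a V2 segment *j*
(order ignored) and no point traverses CSF. Retained counts form a 6×6
matrix **C** per hemisphere; connectivity strength is reported as the
percentage `100·C_ij / ΣC`. Diagonal cells are *retinotopic* connections,
off-diagonal cells *non-retinotopic*. A proximity matrix holds the per-cell
mean reciprocal streamline length `⟨1/L⟩` (larger = shorter fibers).

**Inference.** Per hemisphere *h*, the diagonal and off-diagonal percentage
shares give a difference `d_h`; the observed statistic is the paired t over
hemispheres, `t = mean(d) / (sd(d)/√H)`. The null distribution is built by
exhaustively enumerating all `2^H` within-hemisphere swaps of the
retinotopic/non-retinotopic totals (64 assignments for H = 6, identity
included); the one-tailed p is the fraction of permutation t values ≥ the
observed t. Reliability across acquisitions is quantified element-wise by
ICC(2,1) (two-way random effects, single measure, absolute agreement) and
the coefficient of variation, and absolute streamline counts feed a 2×2
repeated-measures ANOVA (connection type × coil). Quality control includes
voxel-wise temporal SNR (temporal mean / temporal SD of b = 0 series) with
ROI aggregation, and the analytic echo-time model
`gain = exp(ΔTE/T2) − 1`, `extra time = (1 + gain)² − 1`.

## Worked example

```python
from retinoconn.pipeline import run_demo

results = run_demo("demo_out", seed=7)
print(results["acquisitions"]["headcoil"]["summary"])
```

```
Retinotopic V1-V2 connectivity, restricted permutation t-test
==============================================================
hemispheres:            6
retinotopic share:         76.26 %
non-retinotopic share:     23.74 %
observed t:               10.856
permutations:           64  (2^6, identity included)
one-tailed p:           0.0156   (min achievable 0.0156)
reject at alpha=0.05:   True
```

The demo simulates six hemispheres end to end: BOLD runs are generated, the
segments are *recovered* from the noisy phase maps (not copied from ground
truth), rasterized, and used to quantify two simulated acquisitions of 1000
streamlines each. With the default diagonal-preference 0.7 the expected
retinotopic share is 100·(0.7 + 0.3/6) = 75%; here 76.26% is recovered and
the permutation test rejects at its minimum achievable p = 1/64 ≈ 0.016,
i.e. the observed t exceeds every other within-hemisphere swap. The results
bundle also contains the ICC/CoV reliability matrices between the two
acquisitions, the 2×2 repeated-measures ANOVA on absolute counts, and the
surface-coil tSNR near/deep band ratio (≈ 1.7 by construction).

The same stages are exposed on the command line:

```bash
retinoconn simulate --out sim --seed 3        # synthetic hemisphere inputs
retinoconn connect --tck sim/tracks.tck --labels sim/labels.nii.gz --out conn
retinoconn stats --counts conn/connectivity_counts.csv ... --out stats.json
retinoconn demo --out demo_out --seed 7       # full synthetic study
```

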