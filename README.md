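# napvc — partial volume correction for sodium MRI of the Achilles tendon

Quantitative sodium (²³Na) MRI estimates the apparent tissue sodium
content (aTSC, in mM) of the Achilles tendon, an early marker of tendon
degeneration. At the coarse resolutions sodium imaging requires (≈2 mm),
two partial volume effects corrupt the numbers: coarse voxels average
several tissues (tissue-fraction effect), and the long-tailed point
spread function (PSF) of radial ultrashort-echo-time acquisitions spreads
signal between tissues (spill-over effect). `napvc` is a toolkit for
researchers working on sodium quantification: it implements five
correction methods, the digital-phantom machinery to evaluate them
against a known ground truth, and the full aTSC quantification chain.

**Methods implemented**

| method | level | corrects |
|---|---|---|
| PSSR | region | tissue fraction: `C = S_m − S_sur·(1−v_PS)/v_PS` |
| 3D-mLTS | voxel | tissue fraction: least-trimmed-squares fit of kernel samples on fraction maps |
| GTM | region | spill-over: invert `W_ij = mean_i(RSF_j)` |
| STC | voxel | spill-over: iterative cross-spill subtraction / recovery division |
| eSTC | voxel | spill-over: single-sweep RSF-division estimates with erode-and-refill |

All spill-over machinery is built on region spread functions
`RSF_i = m_i * PSF_i`, with PSFs simulated from the k-space trajectory of
a density-adapted 3D radial sequence and the biexponential T2* decay of
each tissue. The package also provides a synthetic Achilles-tendon
phantom (tendon, skin, fat, muscle, calcaneus, bursa, vessels, reference
cylinders) with a forward corruption chain — relaxation weighting,
block-mean downsampling, surface-coil sensitivity, per-tissue PSF
convolution, Rician noise, zerofilling — and a Monte Carlo harness that
scores every method against the ground truth.

See `docs/methods.md` for models, assumptions and numerical choices.

## Worked example

```python
import numpy as np
from napvc import EvaluationConfig, run_monte_carlo

config = EvaluationConfig(n_iterations=5, snr_levels=(10.0,), seed=1)
report = run_monte_carlo(config)
print(report.noise_free[["d_ins", "d_mid", "d_mtj", "d_combined"]].round(2))
```

```
      d_ins  d_mid  d_mtj  d_combined
no     5.84   7.71   7.85        7.13
pssr   3.26   5.07   5.22        4.52
mlts   3.02   5.15   5.08        4.42
gtm    1.79   2.10   2.08        1.99
stc   -0.41   0.85   0.45        0.30
estc  -0.72   0.33   0.10       -0.10
```

These are the noise-free mean voxel-wise differences (mM) between each
method's aTSC map and the ground truth, per tendon section (INS =
calcaneal insertion, MID = mid-portion, MTJ = myotendinous junction) and
combined over the whole tendon; positive values are overestimates.
Without correction the tendon is overestimated by ≈7 mM — mostly because
the uncorrected reference phantoms underestimate their own signal, which
tilts the calibration. The tissue-fraction corrections remove part of
the error, the spill-over corrections most of it, and the single-sweep
eSTC matches the iterative STC at a fraction of its cost.

The same objects are scriptable from the shell:

```bash
napvc simulate-psf --t1 19.2 --t2l 14.2 --t2s 1.4 --out psf.nii
napvc make-phantom --seed 1 --out phantom/
napvc evaluate --iterations 5 --snr 10 --seed 1 --out report/
napvc run --seed 1 --out artifacts/          # full configured pipeline
```

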