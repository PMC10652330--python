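# mtmrs

Saturation-transfer ³¹P MRS analysis of cerebral ATP synthase flux, with a
layered Monte-Carlo model of transcranial light dosimetry for red/near-infrared
photobiomodulation (PBM).

## The problem

Magnetisation-transfer ³¹P magnetic resonance spectroscopy measures the
forward exchange rate k_f (s⁻¹) of the ATP synthase reaction in vivo: a train
of selective RF pulses saturates the γ-ATP resonance at −2.5 ppm, and chemical
exchange carries the saturation into intracellular inorganic phosphate Pi(i)
(~4.9 ppm) and phosphocreatine PCr (0 ppm). Under the Forsén–Hoffman two-site
formalism the observed signal fraction after saturation time τ is

    S(τ)/S₀ = k_f·T_app·e^(−τ/T_app) + T_app/T1,   1/T_app = 1/T1 + k_f,

so a curve of control-normalised Pi(i) peak areas over a grid of saturation
times (0, 3, 6, 12, 18, 30, 44 pulses of 169.29 ms ⇒ τ ≈ 0 … 7.4 s)
determines k_f once T1 is fixed (3.1 s for Pi(i), 5.1 s for PCr). Intracellular
pH follows from the Pi(i) chemical shift δ via
pH = 6.66 + log₁₀((δ − 3.08)/(5.57 − δ)).

The package implements the full analysis chain for this experiment, a
synthetic-data generator with known ground truth so every stage is testable
without scanner data, exact small-sample nonparametric cohort statistics, and
an MCML-style layered photon-transport simulation (scalp/skull/CSF/grey
matter, Henyey–Greenstein scattering, Fresnel boundaries) that quantifies how
much red light actually reaches and is absorbed in cortical grey matter, and
how strongly skin melanin attenuates it.

It is intended for MR spectroscopists analysing MT-³¹P data, and for anyone
planning PBM dosing who needs transparent, editable tissue-optics numbers.

## Worked example

Simulate a 7-subject pre/post-PBM cohort (subject-level ATP synthase rates
N(0.2, 0.05) s⁻¹ before and a paired +0.1 s⁻¹ treatment effect after, with
realistic spectral noise and phase errors), run the whole pipeline —
apodisation, Fourier transform, automatic phasing, quartic baseline removal,
two-Lorentzian fits of the 4–6 ppm Pi window, control normalisation and the
fixed-T1 kinetic fit — and test the cohort:

```python
import numpy as np
from mtmrs.synthetic_data import make_phantom_cohort
from mtmrs.pipeline import run_cohort

cohort = make_phantom_cohort(n_subjects=7, seed=1)
run = run_cohort(cohort)

pre  = [r.kf_pi.kf for r in run.subject_results if r.session == "pre"]
post = [r.kf_pi.kf for r in run.subject_results if r.session == "post"]
print(np.mean(pre), np.mean(post))      # 0.175  0.295  (truth: 0.179 / 0.284)
t = run.report.tests["Pi_i"]
print(t.z, t.p_two_tailed)              # -2.366  0.015625
print(run.group_fits[("Pi_i", "pre")].kf,
      run.group_fits[("Pi_i", "post")].kf)   # 0.171  0.281
print(run.report.tests["PCr"].p_two_tailed)  # 0.21875 (no PCr effect simulated)
```

The recovered individual-average rates (0.175 → 0.295 s⁻¹) track the
generating truth; the exact two-tailed Wilcoxon signed-rank test on the seven
paired differences gives Z = −2.366, p = 0.016 (all seven rates increased);
the creatine-kinase pathway shows no change, as generated. The group-mean
curve fit (mean decay across subjects, then fit) gives 0.171/0.281 s⁻¹ —
systematically slightly below the mean of individual fits, as expected for a
model nonlinear in k_f.

Light dosimetry, from the command line:

```bash
mtmrs mc melanin --wavelength 670 --fractions 0.04,0.43 --n-photons 100000 --seed 1
mtmrs mc sweep --lambda-min 450 --lambda-max 1100 --n-photons 100000 --seed 1
```

With the default head model, raising the epidermal melanin fraction from 0.04
(pale skin) to 0.43 (dark skin) cuts the 670 nm photons absorbed by
cytochrome c oxidase in grey matter by ≈ 64% — a two-thirds drop — and the
fraction of light entering the head that reaches grey matter stays below 8%
at every wavelength between 450 and 1100 nm (maximum ≈ 2.6%).

The CLI also exposes `simulate` (write a cohort bundle of per-condition FID
CSVs + JSON sidecars), `fit` (one session bundle → k_f, pH) and `run-all`
(cohort bundle → per-subject table, group fits, Wilcoxon/Kendall report).

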