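# cryptscore

Quantitative image-analysis and biostatistics pipeline for colorectal-crypt
biomarker trials: hemicrypt optical-density scoring of immunostained rectal
biopsies, crypt-zone statistics, and treatment-effect estimation for a
randomized 2×2 factorial trial of calcium and vitamin D supplementation.

## The problem

Colorectal-cancer chemoprevention trials use biomarkers of crypt-cell
proliferation (mib-1/Ki-67), differentiation (p21) and apoptosis (bax,
bcl-2), measured by immunohistochemistry in normal-appearing rectal mucosa
at baseline and after treatment.  The measurement unit is a *hemicrypt* —
one half of a longitudinally bisected crypt running from the muscularis
mucosae to the lumen.  A traced hemicrypt outline is divided into 50
equal-width axial segments (about one colonocyte each) and the
background-corrected optical density (OD) of the stain is integrated per
segment and overall.  Segment profiles are reduced to crypt functional
zones: the whole crypt, the upper 40% (differentiation zone, segments
31–50), the lower 60% (proliferation zone), and φ_h = upper40 / whole.

Treatment effects are estimated per biomarker × zone for three pooled
contrasts (vitamin D vs no vitamin D; calcium vs no calcium, 4-arm
participants only; calcium + vitamin D vs calcium alone) from a
repeated-measures linear mixed model on ln(OD) with a participant random
intercept:

    ln(y_iv) = β0 + β1·visit + β2·group + β3·(visit × group) + b_i + ε_iv

The **relative effect** is exp(β3) = (treated follow-up / treated baseline)
/ (reference follow-up / reference baseline), a ratio of ratios of group
geometric means; the **absolute effect** is the difference-in-differences
of the four geometric means, in OD units.

Because no slides or participant data are deposited, the package includes
synthetic generators with exact ground truth: rendered hemicrypt images
with planted axial OD profiles, and six-arm two-visit trial tables with
planted multiplicative treatment effects.

## Worked example

```python
import numpy as np
from cryptscore import *

# 1. render and score a synthetic hemicrypt
params = CryptSimParams(profile_kind="apical_gradient", total_od=120.0,
                        noise_sd=2.0, seed=42)
image, outline, truth = simulate_crypt_image(params)
profile = score_hemicrypt(image, outline, params.background_intensity)
z = zone_summary(profile)
print(f"whole={z.whole:.1f}  upper40={z.upper40:.1f}  phi_h={z.phi_h:.3f}")

# 2. estimate a planted 1.3x treatment effect from a simulated trial
tparams = TrialSimParams(
    baseline_log_mean={("p21", "upper40"): np.log(310.0)},
    true_relative_effect={"CaD": 1.3, "CaD2arm": 1.3},
    seed=7,
)
records = simulate_trial(tparams)
contrast = build_contrasts()["caD_vs_ca"]
print(TreatmentEffectModel(records, contrast, "p21", "upper40").fit())
```

prints

```
whole=126.5  upper40=77.0  phi_h=0.609
<TreatmentEffectResults p21/upper40 caD_vs_ca: relative 1.34 (1.20, 1.49), p=0.00, abs 106.0>
```

The scored whole-crypt OD (126.5) recovers the planted 120 up to pixel
noise (noiseless scoring is exact to 1e-6 per segment); the apical profile
concentrates signal in the upper 40%, hence φ_h ≈ 0.6.  The fitted relative
effect 1.34 (95% CI 1.20–1.49) brackets the planted 1.30: p21 expression in
the differentiation zone rose 34% more in the calcium + vitamin D group
than under calcium alone, an absolute gain of about 106 OD units.

A `cryptscore` command exposes the same pipeline from the shell
(`simulate-image`, `simulate-trial`, `score`, `aggregate`, `effects`,
`icc`); see `cryptscore --help`.

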