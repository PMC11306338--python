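# mtgrowth

Analysis of turbidimetric growth curves from microtubule polymerization
assays, together with the exposure-dosimetry arithmetic of a waveguide
apparatus — for experimentalists who need to decide whether two sets of
growth curves differ in *shape* and not merely in *rate*, and whether an
apparent field effect survives a thermal-history control.

## The problem and the model

A turbidity assay records optical density O.D.(t) at 365 nm as tubulin
polymerizes; curves are sigmoidal (nucleation, elongation, saturation).  In
the early phase

    O.D.(t) = A · (t / t_u)^b,

so ln(O.D.) vs ln(t) is a line with slope *b*, fitted here by ordinary least
squares over the part of the normalized curve between O.D. 0.1 and 0.4.
Each run is reduced to (final O.D., t10, b); cohorts are screened with MAD
outlier rejection (k = 3), summarized as mean ± σ/√(N−1), and compared with
two-sided Mann–Whitney U tests flagged at p < 10⁻³ (0.05 reported
alongside).  Because every rate accelerates with temperature, one group can
be *time-stretched* — its time axis rescaled so its average-curve t50
matches a reference — before comparing t10; stretching can never change *b*
or the final O.D., so it isolates curve shape from overall speed.

The key confounder this package makes testable is **thermal history**: a
sample that enters the observation window still warming (because local
heating — microwave absorption, an air stream, an IR spot — forces a cooler
enclosure) shows an inflated apparent *b* even when nothing but temperature
kinetics is at work.  The bundled synthetic generator produces Avrami/JMAK
curves driven by an Arrhenius progress integral over an explicit temperature
trace, so this mechanism can be simulated and the whole pipeline tested
without raw assay data.

The `dosimetry` module carries the companion arithmetic for the exposure
apparatus: dBm → mW, the reflected/transmitted/absorbed power budget from
S-parameters, the peak field √(2PZ)/d across the plate gap, and
SAR = σE²/ρ.

## Worked example

Simulate 25 runs pre-equilibrated at 34.9 °C and 25 runs reaching the same
end temperature through a two-step thermal history, then compare:

```python
import numpy as np
from mtgrowth import (KineticParams, constant_profile, two_step_profile,
                      simulate_cohort, screen_trace, extract_features,
                      summarize_cohort, mann_whitney_u)

params = KineticParams()   # defaults emulate the ~35 degC assay conditions
ambient  = simulate_cohort(25, params, constant_profile(34.9), seed=0)
two_step = simulate_cohort(25, params, two_step_profile(t_end=34.9), seed=1)

def analyze(runs, label):
    feats = []
    for r in runs:
        try:
            screen_trace(r.to_trace(label))
            feats.append(extract_features(r.to_trace(label)))
        except Exception:
            pass                      # bubbles land in the rejection log
    return feats

fa, fb = analyze(ambient, "ambient"), analyze(two_step, "two-step")
for label, f in (("ambient", fa), ("two-step", fb)):
    s = summarize_cohort(f, label=label)
    print(f"{s.label:9s} N={s.n:2d}  O.D.={s.od_final_mean:.2f}±{s.od_final_se:.2f}  "
          f"t10={s.t10_mean:5.1f}±{s.t10_se:.1f} s  b={s.b_mean:.2f}±{s.b_se:.2f}")
u, p = mann_whitney_u([f.b for f in fa], [f.b for f in fb])
print(f"Mann-Whitney on b: U={u:.0f}, p={p:.2g}")
```

prints

```
ambient   N=20  O.D.=1.35±0.04  t10= 22.3±0.9 s  b=1.92±0.01
two-step  N=23  O.D.=1.34±0.03  t10= 36.3±1.7 s  b=2.53±0.02
Mann-Whitney on b: U=0, p=3.1e-09
```

Both cohorts end at the same temperature and plateau at the same final O.D.,
but the two-step thermal history inflates the fitted exponent from 1.92 to
2.53 — a strongly significant shape change (p ≪ 10⁻³) produced by heating
kinetics alone, with no field effect in the model at all.  That is exactly
the signature that, on real data, could be mistaken for a non-thermal
microwave effect.

The same pipeline is scriptable from the shell:

```
mtgrowth simulate --n 25 --seed 0 --out-dir runs/ambient --label ambient
mtgrowth simulate --n 25 --seed 1 --t-start 28.3 --t-ambient 27.9 --t-local 7 \
         --out-dir runs/twostep --label twostep
mtgrowth compare --manifest-a runs/ambient/manifest.json \
         --manifest-b runs/twostep/manifest.json --out-dir results/
mtgrowth dose --s11 -11.88 --s21 -10.73     # 20 GHz, 166 mW configuration
```

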