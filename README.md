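# stunmird

Internal dosimetry and thyroid-stunning analysis for ⁹⁹ᵐTc-pertechnetate
SPECT studies in the mouse.

Diagnostic activities of ⁹⁹ᵐTcO₄⁻ are taken up by the thyroid through the
sodium/iodide symporter (NIS). The low-energy conversion and Auger electrons
of ⁹⁹ᵐTc deposit their energy locally, so a milligram-scale mouse thyroid
can receive tens of gray from a single injection — enough to transiently
*stun* the gland: its uptake capacity on a rechallenge scan a day later is
reduced, recovering within a few days, with NIS mRNA downregulation and no
cell death. `stunmird` implements the complete quantitative chain needed to
study this effect, for physicists and radiobiologists working with
small-animal NIS imaging:

1. **Self S-value** (`stunmird.transport`) — seeded Monte Carlo of electron
   energy deposition in a voxelised thyroid phantom
   (`stunmird.phantom`), driven by a packaged ⁹⁹ᵐTc emission-line table
   (`stunmird.emissions`), with an analytic mean-chord model for photons.
2. **Biokinetics** (`stunmird.tac`) — per-animal time–activity curves:
   linear uptake from zero to a 1 h peak, mono-exponential effective washout
   fitted on log activity, closed-form cumulated activity
   Ã = ½·A_peak·t_peak + (A_peak/λ_eff)(1 − e^(−λ_eff(t_end−t_peak))) over
   [0, 24 h].
3. **MIRD dose** (`stunmird.dose`) — D = Ã × S per animal, plus the
   calibration of 24 h absorbed dose against the single 60-minute peak
   activity measurement.
4. **Stunning statistics** (`stunmird.stunning`) — percent change in
   rechallenge uptake, dose-threshold detection by a maximally selected
   two-sample t statistic with permutation-calibrated significance,
   longitudinal recovery profiles, and comparative-CT (2^−ΔCT) qPCR
   expression.
5. **Synthetic cohorts** (`stunmird.synthetic`) — seeded generators that
   emulate the study design (group %ID distributions, washout spread,
   measurement noise, threshold dose–response, recovery course), so every
   stage is testable without animal data.

## Worked example

Simulate the imaging cohort (4/9/9/29 mice at 10/25/100/150 MBq), a stunning
rechallenge experiment, and run the full pipeline:

```bash
stunmird synth cohort --out tac.csv
stunmird synth stunning --doses 5:35:20 --out stun.csv
stunmird run tac.csv --stunning-csv stun.csv --out report/
```

which prints (seed 20140324, the package default):

```
stunmird pipeline report (seed 20140324)
S-value: 4.550e-10 Gy/(Bq s) [fixed]
  10 MBq group (n=4): dose 2.1 +/- 0.4 Gy
  25 MBq group (n=9): dose 4.4 +/- 1.0 Gy
  100 MBq group (n=9): dose 16.6 +/- 2.3 Gy
  150 MBq group (n=29): dose 26.8 +/- 5.8 Gy
peak->dose calibration: slope 7.92 Gy/MBq, R^2 0.937
stunning threshold: 21.6 Gy (p=0.001, below -4.92% vs above -17.98%)
```

Reading the numbers: each animal's fitted time–activity curve is integrated
to 24 h and multiplied by the thyroid self S-value, giving group mean
absorbed doses that rise proportionally with injected activity up to
~27 Gy at 150 MBq. Dose is strongly correlated with the 1 h peak activity
(R² 0.94), which is what justifies single-scan dosimetry. The threshold scan
splits the simulated rechallenge cohort at 21.6 Gy — mild ~−5% uptake change
below, ~−18% above, permutation-adjusted p = 0.001 — recovering the 22 Gy
threshold the generator encodes.

The longitudinal course (12 animals rescanned at days 1/2/4/8):

```bash
stunmird synth stunning --recovery --out rec.csv
stunmird recovery rec.csv
```

reports day means of 52%, 62%, 98% and 96% of the day-0 uptake with
`recovered: false` at days 1–2 (p < 0.05 vs 100%) and `recovered: true` at
days 4 and 8 — stunning, then full recovery by day 4.

The Monte Carlo S-value itself:

```bash
stunmird svalue --mass-mg 5.4 --voxel-um 200 --histories 1000000 --seed 20140324
```

returns `s_value_Gy_per_Bq_s ≈ 4.47e-10` with a relative standard error of
~0.02% and an electron share of ~96% of the absorbed energy.

Library use mirrors the CLI:

```python
from stunmird import (build_phantom, load_emission_spectrum, self_svalue,
                      CohortConfig, synth_cohort, doses_from_tac_table)

phantom = build_phantom(thyroid_mass=5.4, voxel_size=200.0, body_extent=20.0)
result = self_svalue(phantom, load_emission_spectrum(), n=10**6, seed=20140324)
records = doses_from_tac_table(synth_cohort(CohortConfig()), s_value=result.s_value)
```

See `docs/methods.md` for the transport model, fitting conventions, the
threshold-scan calibration and the generator's scope.

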