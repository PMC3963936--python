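# Methods

## Dosimetric model

The package computes absorbed dose with the MIRD schema, D = Ã·S, separating
biokinetics (the cumulated activity Ã in Bq·s) from radiation physics (the
self S-value in Gy·Bq⁻¹·s⁻¹).

### Emission data

`stunmird/data/tc99m_emissions.csv` lists the per-decay photon and electron
lines of ⁹⁹ᵐTc (140.5/142.6 keV gammas, K/L X-rays, conversion electrons of
the 2.17, 140.5 and 142.6 keV transitions, and Auger cascades) compiled from
the MIRD/ICRP-107 decay-data tabulations, with the physical half-life
(6.0067 h) in the header. Continuous Auger spectra are represented by their
mean discrete lines; the listed lines carry ≥ 99% of the emitted electron
energy (Δ_electron ≈ 15.5 keV per decay, Δ_photon ≈ 125.7 keV per decay),
which is adequate because absorbed fractions vary slowly within each Auger
group's energy span.

### Phantom

The thyroid is a voxelised sphere of soft tissue (1.05 g/cm³) centred in a
homogeneous soft-tissue cube; defaults are 5.4 mg, 200 μm cubic voxels and a
20 mm body. Voxels are selected nearest-to-centre with deterministic
tie-breaking, realising the requested mass within 2% (a coarser grid that
cannot do so raises a geometry error). Bone, lung and air structures are
omitted deliberately: they cannot influence a *self* S-value whose electrons
travel ≤ 0.25 mm and whose photon absorption is evaluated only inside the
organ.

### Electron transport

Electrons follow straight continuous-slowing-down tracks: a history samples
an emission point uniformly within a uniformly chosen thyroid voxel and an
isotropic direction, then deposits its energy uniformly along a track of
CSDA range taken from a packaged water-equivalent soft-tissue table
(log–log interpolated). The absorbed fraction is the mean in-organ path
fraction, evaluated by midpoint sub-sampling of the track against the voxel
labels (16–128 substeps, scaled to range/voxel). Because emission points are
uniform, boundary crossings fall uniformly within a substep, so the midpoint
estimator is unbiased; its extra variance is absorbed into the reported
Monte Carlo error. Straight tracks ignore multiple scattering (which
*shortens* the crow-flight range) and the rising stopping power near track
end (which shifts deposition toward the start of the track, i.e. inside the
organ); both simplifications bias the escape estimate mildly upward, which
is conservative for a self dose dominated (~96%) by electrons that deposit
locally anyway. Lines whose range is below 1% of the organ's equivalent
radius (all Auger lines and the 1.6–2.1 keV conversion electrons) are scored
as fully absorbed; the neglected surface escape is ≤ ~0.2%.

### Photons

Photon self absorption uses the thin-absorber closed form
φ = 1 − exp(−μ_en·ℓ̄) with ℓ̄ = 4V/S the mean chord length of the
volume-equivalent sphere and μ_en/ρ from a packaged water-equivalent table.
For a ~5 mg thyroid this gives φ ≈ 0.004 at 140.5 keV and ≈ 0.1 for the
18–21 keV X-rays — a ~4% contribution to S, small enough that the analytic
model's error is negligible against the electron term. Build-up from
photons converted elsewhere in the body is ignored (out of scope for a
self S-value at this precision).

### Uncertainty and seeds

S is Σ yᵢEᵢφ(Eᵢ)·(1.602×10⁻¹⁶ J/keV)/m. The relative standard error comes
from 20 equal history batches (SE = sd(batch means)/√20); analytic photon
and local-deposition terms contribute no variance. Every Monte Carlo entry
point takes one explicit 64-bit seed (documented default 20140324);
per-line generators are spawned from it with `numpy.random.SeedSequence`,
so identical inputs give bit-identical results. At 10⁶ histories per
transported line the run takes ~10 s on one CPU, the relative SE is
~0.02%, and S ≈ 4.47×10⁻¹⁰ Gy·Bq⁻¹·s⁻¹ for the default phantom — within 2%
of the 4.55×10⁻¹⁰ reference value the package ships as
`DEFAULT_S_VALUE` for pipeline use, comfortably inside the error expected
from the simplified transport.

## Time–activity model

Scans at 1, 3 and 7 h post-injection support only a minimal model: linear
uptake from zero activity at injection to a peak at the first scan time
(pertechnetate peaks within the first hour; a `free` mode instead places the
peak at the largest sample), then mono-exponential washout at the effective
rate λ_eff. Activities are used *without* decay correction, so λ_eff
combines physical decay and biological clearance and Ã follows directly; a
warning is emitted if a fitted λ_eff is slower than physical decay alone.
The washout is fitted by least squares on log activity over strictly
post-peak samples — exact for two points and appropriate for the
multiplicative noise of SPECT quantification — and the fitted amplitude at
the peak time anchors both branches. Cumulated activity uses the closed
form above with t_end = 24 h by default (activity at 24 h is < 1% of peak
for any plausible λ_eff, so later tail truncation is immaterial). Decay
correction is applied only when reporting %ID.

## Dose statistics

`calibrate_peak_to_dose` regresses 24 h dose on 1 h peak activity by OLS
with a free intercept (a through-origin mode exists; R² is centred in both
modes so they are comparable). `dose_for_injected` scales a reference dose
proportionally with injected activity, the reading used for decayed-source
estimates (150 MBq left to decay 72 h ≈ 12 half-lives → 0.04 MBq → 8 mGy on
a 30 Gy/150 MBq calibration).

## Threshold scan

Candidate thresholds are midpoints between consecutive distinct observed
doses with at least 3 records per side. Each candidate is scored by a
two-sided two-sample Student t-test on percent uptake change (Welch
optional). The scan selects the candidate with maximal |t| and calibrates
its significance by permutation of the max-|t| statistic (999 seeded
permutations, vectorised over prefix splits). The calibration matters:
without it, searching ~25 correlated splits at a nominal 0.05 level flags
~25–35% of null datasets; the permutation-adjusted scan holds the
false-positive rate at the nominal level (measured ≈ 5% over 200 null
replicates) while the power against the study-scale effect (−3.95% vs
−17.5%, SD 5, n = 15/group) remains ≈ 100%, and the selected split brackets
a simulated 22 Gy threshold in ≈ 80% of replicates — the intrinsic accuracy
limit of any changepoint estimator under those conditions. The unadjusted
per-candidate p is reported alongside (`p_naive`), and `adjust="none"`
reproduces the uncorrected smallest-significant-candidate rule with its
caveat recorded in the result's `method` field. No further multiplicity
correction is applied across the candidate grid beyond the max-|t|
calibration itself.

## Recovery profile

Uptake at each follow-up day is expressed as percent of the same animal's
day-0 value; per-day mean ± SD, a per-day one-sample t-test against 100%,
and a one-way ANOVA across days are reported. A day is classified
*recovered* when its mean lies within one SD of 100% **or** the t-test is
non-significant. The pure one-SD rule alone is unreliable at n = 3 (the
event |mean − 100| > SD has probability ≈ 22% for a truly recovered day,
independent of the noise scale); adding the significance criterion restores
a ~5% misclassification rate while leaving genuinely impaired days (≥ 40%
deficits against ~8% SD) flagged essentially always. With one animal per
day SD, p and the flag are undefined and reported as absent.

## qPCR

`relative_expression` is the comparative-CT measure 2^(−(Ct_target −
Ct_reference)); group fold changes are ratios of 2^(−mean ΔCt) (geometric
means), with Student t-tests on ΔCt against the control group.

## Synthetic generators

All generators are pure functions of config + seed (byte-identical tables on
re-run). The cohort generator draws decay-corrected %ID ~ N(group mean, SD)
truncated positive by redraw, converts to a measured (non-corrected) peak,
draws λ_eff log-normally, and evaluates the piecewise model at the scan
times with mean-preserving multiplicative log-normal noise (CV 5%,
a typical small-animal SPECT quantification repeatability). Defaults encode
the study design: groups (10 MBq, n=4, 2.84±0.63), (25, 9, 2.6±0.35),
(100, 9, 2.67±0.33), (150, 29, 2.63±0.47); scans at 1/3/7 h; peak at 1 h.

**λ_eff calibration.** The washout rate is not printed anywhere; the
generator's default median 0.23 h⁻¹ (geometric SD 1.15) is the value that
makes the four simulated group mean absorbed doses land on the reported
2.6/4.8/19.6/28.4 Gy given the reported %ID means and a 4.55×10⁻¹⁰ S-value.
It implies ~20% of peak activity remaining at 8 h and a dose-per-peak slope
of ~8 Gy/MBq — slightly above the ~6.3–7.1 Gy/MBq implied by the reported
18.9–49.6 Gy dose range for 3–7 MBq peaks, a tension internal to the
source numbers that cannot be resolved on published information; the group
means were given priority. This is a calibration choice, not a measured
value, and is exposed as an ordinary config field.

The stunning generator draws percent changes N(−3.95, 5) below and
N(−17.5, 5) at/above a 22 Gy threshold; the recovery generator uses day
means 55/60/100/100% of baseline at days 1/2/4/8 with an 8% SD (day-2 kept
near the day-1 trough since impairment persists through day 2; the exact
day-2 level is not published). The qPCR generator centres group ΔCt to give
2.5-/12-fold downregulation at 20/30 Gy with σ(ΔCt) = 0.5.

**What the generators do not emulate** — and hence what passing tests do
not establish about real data: image formation (resolution, partial volume,
scatter, ROI delineation bias), correlations between %ID and washout within
an animal, inter-scan biological drift other than the modelled stunning,
non-normal outliers, and any mechanistic NIS-downregulation kinetics. The
generators reproduce the *statistical shape* of the study's tables, not the
imaging physics behind them.

## Numerical conventions

- Units: hours and MBq at all interfaces; Bq·s only inside Ã; keV in
  emission tables; μm for voxels; Gy for dose.
- Log–log interpolation for range and μ_en tables; energies outside a table
  raise rather than extrapolate.
- Degenerate inputs are errors with named offenders (schema violations
  report line numbers; config validation lists every bad field; missing
  day-0 pairings name the animal).
- JSON reports sort keys and format floats to 12 significant digits, so
  identical inputs and seed give byte-identical files.
- Problem sizes used by the test suite: 10⁶ Monte Carlo histories for the
  headline S-value check, 2×10⁴ for comparative properties (mass
  monotonicity, electron fraction), 200 replicates for threshold power and
  type-I simulations, n = 200 animals for generator parameter recovery.

## Known limitations

- The transport model is range-based and uncoupled; it is fit for self
  S-values of electron-dominated emitters in small organs, not for
  cross-organ doses, photon-dominated nuclides, or organs comparable to the
  photon mean free path.
- The TAC model cannot represent delayed peaks, biexponential clearance or
  blood input; it is exact only for the sampled-design it targets.
- The threshold scan assumes a single changepoint and equal variances by
  default.
- Human extrapolation is out of scope: the dose-per-activity relation here
  is specific to mouse thyroid biokinetics and a ~5 mg gland.
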