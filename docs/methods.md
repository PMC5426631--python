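# Methods

This note records the models implemented by `tidalflux`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
generators do and do not capture. Problem sizes quoted for tests are the
sizes the test suite actually runs.

## Hourly counts and target strength

Fish tracks are ingested from delimited exports with per-track mean time,
duration, number of single-target echoes, mean TS (dB re 1 m²) and optional
heading. Tracks with fewer than 5 single targets are excluded — the
standard track-quality threshold for this class of split-beam/single-beam
processing — and counted in a validation report. Counts use half-open
hourly bins `[t, t+1h)`; a track exactly on an hour boundary belongs to the
bin starting there. All internal timestamps are UTC; a site UTC offset
(default −4 h, for a Maine tidal channel) enters only in diel summaries.

TS quartiles use linear interpolation between order statistics (the common
default; no convention is forced by the data).

**TS–length.** Side-aspect TS of a fish scales log-linearly with length and
acoustic wavelength (Love-form relation):

    TS = 22.8 · log10(L_cm) − 2.8 · log10(λ_cm) + b,   λ = c / f

with sound speed c = 1490 m/s. The slope and wavelength coefficients follow
the Love side-aspect family; the intercept b = −63.2 dB is calibrated so
that a 6 cm fish at 200 kHz returns −45.1 dB, the median TS of the
monitored assemblage. With this single calibration the relation also maps
−50 dB → 4 cm, −46.5 dB → 5 cm and −43.4 dB → 7 cm after rounding, i.e.
every published conversion for this gear. The exact constants of the
original relation are not recoverable from the published pairs alone, so
`TsLengthParams` exposes all four coefficients.

## Gap filling

The wavelet transform needs a complete series, so deployment gaps are
filled before analysis. Three methods:

* **median** — every missing hour takes the global median of observed
  values;
* **linear** — interpolation between flanking observed values (edge gaps
  extend the nearest value);
* **harmonic** (preferred) — per gap, ordinary least squares of

      y(t) = C + Σᵢ Aᵢ sin(2πt/Pᵢ) + Bᵢ cos(2πt/Pᵢ) + ε

  on the observed hours within `max(gap width, 48 h)` to either side of the
  gap. Candidate periods Pᵢ are the top-amplitude local maxima of the
  discrete Fourier amplitude spectrum of the median-filled series (default
  6 peaks, frequencies restricted to one cycle per twice the record length
  up to the 2 h Nyquist period). Periods longer than twice the fitting
  subset's duration are excluded per gap; "subset duration" is read as the
  total observed hours used (both sides combined) — a per-side reading is
  available via `max_period_rule="per_side"`. If no period survives, the
  model degenerates to the midline alone. Zero-mean Gaussian noise with the
  fit's residual SD is added to predictions (this measurably reduces the
  spectral footprint of the fill relative to noiseless predictions, because
  a noiseless fill locally removes the series' intrinsic noise power).
  Filled counts are clamped at zero before the later log transform.

The model carries an explicit midline C even though the sinusoid-sum form
can be written without one: counts have a nonzero local mean, and the
midline is also what defines slack crossings in the tidal application.

Fits are plain `numpy.linalg.lstsq` on the dense design; windows are at
most a few thousand rows by 13 columns, where dense QR is exact and fast.
Residual SD uses a degrees-of-freedom correction (n − p).

**Fill-method comparison.** `evaluate_fill_methods` applies a gap layout to
a complete truth series, fills with each method, wavelet-transforms truth
and filled series, and reports the mean power added per period band,
averaged over times outside the cone of influence. The comparison runs on
the count scale by default — the benchmark asks how much spurious structure
a fill injects into the series being filled — with `log_scale=True`
available to mirror the log(1+x) analysis pipeline. The benchmark truth
(`simulate_benchmark_series`) is an additive sinusoid series (midline 120;
amplitudes 40, 30, 10, 30, 70 at the 0.5, 1, 14.7, 182 and 365 d periods;
Gaussian noise SD 8; clipped at zero): it lies inside the harmonic model's
own family, which is the right yardstick for a comparison of fills — the
best method should be able to reconstruct the truth — and its deep seasonal
swing (hourly values from ~0 to ~280) reflects the dynamic range of real
tidal-channel fish counts. Against this truth, median filling inflates the
4–20 d and 40–100 d bands via step artifacts at gap boundaries, while the
harmonic fill with matched noise stays near zero inflation; the test suite
checks that ordering over 10 independently simulated replicates on the
packaged deployment calendar.

## Wavelet analysis

The hourly series is transformed as log(1+x) (natural log; a different base
rescales power by a constant), mean-removed, zero-padded to the next power
of two above the record length, and convolved with scaled Morlet wavelets
(ω₀ = 6):

    ψ₀(η) = π^(−1/4) · exp(i ω₀ η) · exp(−η²/2)

Scales map to Fourier periods by the Torrence–Compo factor
4π/(ω₀ + √(2+ω₀²)) ≈ 1.033. The period grid is geometric, 16 voices per
octave by default, from 2 h (hourly Nyquist) to half the record length,
capped at one year. The transform samples the scaled wavelet in the time
domain on the padded grid and applies it by FFT fast convolution, so the
result is exactly (to machine precision) a circular convolution that a
brute-force oracle can reproduce; differences from the analytic
frequency-domain formulation are below the Gaussian tail ~e^(−ω₀²/2).
Power is the squared modulus. A constant series yields identically zero
power (mean removal), and doubling the input amplitude quadruples power.

**Cone of influence.** The Morlet e-folding time is √2·s, so the maximum
trustworthy period at distance d from the nearer record end is
`1.033 · d/√2`; the curve is zero at both ends and symmetric.

**Significance.** Each power cell is compared against `n_sim = 100` seeded
Gaussian white-noise simulations with the analyzed series' SD; the p-value
is the fraction of simulations whose power at that cell meets or exceeds
the observed power, and cells with p < α = 0.05 are flagged. The test is
pointwise — no area-wise or multiple-testing correction — matching how
white-noise significance contours are normally drawn on wavelet spectra.
With an empirical p-value from 100 simulations the attainable null rate is
5/101 ≈ 0.0495, indistinguishable from α at the tolerances used. The null
is white (not AR(1)): the reference analysis tested against "a random
signal", and count series at this hourly resolution are dominated by
near-white observation noise between periodic components.

## Tidal stage from fish headings

At the monitored site fish move with the current except briefly at slack
water, with flood/ebb heading plateaus near 285°/120°. Headings are
circular, so they are first unwrapped onto `[seam, seam+360)` with the seam
at 20° by default — far from both plateaus; the fit is invariant to the
seam so long as no plateau straddles it. A harmonic model (same form as
the gap models) with constituent periods

    M2 12.4206  S2 12.0000  N2 12.6583  K2 11.9672  K1 23.9345
    O1 25.8193  P1 24.0659  Q1 26.8684  M4 6.2103   L2 12.1916
    NU2 12.6260 2N2 12.9054 MF 327.8599 MM 661.3112 SSA 4382.9052  (hours)

is least-squares fitted to the unwrapped headings directly (the standard
astronomical periods; no nodal corrections or phase arguments — direction,
not elevation, is modeled). Fitting headings in degrees rather than via
sine/cosine components keeps the model linear and mirrors how a current
proxy is used downstream. A rank-deficient design (e.g., a record that
cannot separate two constituents) raises an error naming the offending
constituents.

Peaks of the fitted sinusoid are peak flood, troughs peak ebb; midline
crossings are slack tides, located by a 5-minute scan with Brent root
refinement to under one second. Rising crossings (ebb→flood) are labeled
low slack by default — at this site the turnover to flood occurs at low
water — with a flag to flip the convention. Stage labels assign times
within 30 min (default) of a crossing to that slack; otherwise flood above
the midline, ebb below; phase is the elapsed fraction between bounding
crossings.

Note that a sinusoid family fitted to a square-wave direction signal
recovers the fundamental, whose amplitude exceeds the plateau half-span by
4/π; the prediction then sits within ±30° of a plateau for about two thirds
of each cycle. The constituent set contains no odd harmonics of M2, so no
squarer fit is possible — slack timing, which depends only on the
crossings, is unaffected.

## Diel and tidal summaries

Sunrise and sunset use the NOAA solar-calculator algorithm
(Julian-century polynomial ephemeris for the sun's apparent longitude,
obliquity, declination and the equation of time; zenith 90.833° for
refraction plus solar radius). Latitudes poleward of 66° are rejected.
Site default: outer Cobscook Bay, 44.9°N 67.0°W, UTC−4.

The hour-by-day matrix is 24 × D in site-local time, with filled and
missing cells flagged separately from observed zeros. Hours are labeled
crepuscular when their midpoint lies within 1.5 h (default) of sunrise or
sunset, else day/night. The stage × diel cross-tab reports mean observed
counts and occupancy per stratum; imputed hours are excluded by default so
fill values cannot feed back into pattern summaries; empty strata are
absent rather than zero.

## Synthetic data

* **Counts** are independent Poisson with log-linear mean: baseline plus
  sinusoidal components (tidal M2, diel, spring–neap 14.7 d, 27.6 d,
  semi-annual, annual), optional product interactions, and optional annual
  amplitude envelopes `1−depth+depth·((1+cos)/2)^sharpness` that can switch
  tidal/diel dominance seasonally. Poisson guarantees non-negative integer
  counts; a negative-binomial knob adds overdispersion. A guard rejects
  log-means above 20.
* **The deployment calendar** is a packaged constant: 21 data segments
  (1–57 d, totalling 582 whole days) alternating with 20 gaps (2 h–29.5 d,
  totalling 161 d) across the 743-day span July 15 2013 – July 28 2015.
  Exact gap positions of the real deployment were never published; the
  packaged layout satisfies every published property, including both range
  extremes.
* **Directions** follow the sign of a tidal driver (default pure M2):
  flood/ebb plateau plus wrapped Gaussian noise, uniform on [0,360°) within
  a configurable half-width of the driver's zero crossings; the true
  crossing times are returned as ground truth.
* **Tracks** draw per-hour Poisson counts with uniform within-hour
  timestamps and Gaussian TS with median −45.1 dB and quartiles −46.5 /
  −43.4 dB (quartiles sit 0.6745 SD from the median).

What the generators do *not* emulate: species composition and its seasonal
turnover, schooling (schools are excluded from the real counts), detection-
probability changes with current speed, autocorrelated (non-Poisson)
arrival processes, and weather-driven noise bursts. Passing tests therefore
demonstrate that the pipeline recovers planted structure under its own
statistical assumptions, not that those assumptions exhaust real data.

## Numerical choices and degenerate inputs

* Harmonic fits: dense least squares; residual SD with df correction;
  empty retained-period sets degrade to midline-only fits; gaps at series
  edges are fitted from the available side.
* Wavelet: padding to the next power of two strictly above n; filters
  precomputed once per (length, grid) in a reusable bank (significance
  reuses the bank across simulations).
* Slack refinement: `brentq` with xtol = 0.5 s on 5-min brackets; duplicate
  roots at bracket boundaries are deduplicated.
* Probabilities: empirical p-values are k/n_sim; the flagged set at a
  vacuous threshold is every cell not beaten by all simulations.
* Reproducibility: every stochastic routine takes a seed;
  `harmonic_fill` spawns one child generator per gap from a root
  `SeedSequence`, so gap fills are independent and the whole fill is
  bit-reproducible.

Problem sizes in the test suite: null calibration uses 4,096-hour records,
100 simulations and 20 seeds; the fill comparison uses the full 17,832-hour
deployment span at 8 voices/octave with 10 replicates; oracle equivalence
checks run at 256–512 samples.

## Known limitations

* The TS–length intercept is calibrated, not the original instrument
  constant; lengths are indicative, as TS varies strongly with fish
  orientation and anatomy.
* Wavelet significance is pointwise; contiguous flagged areas are easier to
  over-read than a corrected test would allow.
* The tidal model predicts direction only (no current speed or elevation)
  and assumes the fish-direction proxy holds, which fails where fish do not
  stream with the current.
* The low/high slack assignment is a site convention (rising = low), not
  derivable from headings alone.
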