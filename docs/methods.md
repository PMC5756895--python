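# Methods

## The process being modelled

A brood of poikilotherm insects develops through an ordered sequence of
life stages. Within a stage, each individual accrues *physiological age* —
a dimensionless development level, distinct from calendar age — at a
temperature-dependent rate, and matures into the next stage when its
accrued age crosses a threshold `γ_s` (set to 1 for every mountain pine
beetle stage, so age within a stage is "fraction of the stage completed").
Daily temperature records force the model three ways: development responds
to the daily mean, cold mortality to the daily minimum, and adult flight
to the daily maximum.

Phenotypic variability is modelled by making the per-step aging increment
of each individual an independent log-normal draw whose *median* equals
the deterministic rate-summation increment `r_s[T(t_i)] Δt`:
`increment ~ LN(μ = ln(r_s[T] Δt), σ_s²)`. The median identity
(`exp(μ) = r Δt`) is exact by construction, so `σ_s = 0` recovers the
classical deterministic rate-summation model, and the increments are drawn
fresh each step (no persistent individual rate deviate), which is what
makes the population age density evolve by convolution.

Three equivalent simulators share this process model:

- **IPM** — the age density within each stage lives on a uniform grid and
  is advanced each day by one FFT convolution with the day's discretized
  increment density, thinned by the day's mortality probability, and split
  at `γ_s`; crossers are recruited into the next stage at age zero as a
  point mass. Deterministic, bit-reproducible.
- **Cohort model** — the identical algorithm on a coarse (16-bin) grid.
- **IBM** — the stochastic process itself, one individual at a time.
  The IPM's stage totals are the IBM's exact expectation; the test suite
  and acceptance script verify this to within 3 binomial standard errors
  across 500 replicates.

## Numerical conventions

These choices matter for anyone comparing this engine against another
implementation.

**Grid and kernel.** Grid point `j` carries age value `j·w`
(`w = a_max / n_bins`) and represents the age cell `[(j−½)w, (j+½)w)`.
The kernel mass in bin `j` is the log-normal CDF difference across that
cell's edges, renormalized to sum exactly to one. Centred cells make the
increment rounding unbiased; assigning increments to the cell *below*
(left-edge binning) would bias every step's aging downward by ~`w/2`,
which accumulates linearly in step count and visibly distorts completion
times. With `σ = 0` (or median rate at/below the clip floor) the kernel is
an exact point mass (the degenerate cold kernel is the identity and is
applied without any FFT, so a freezing day changes nothing bit-for-bit).

**Threshold split.** The cell containing `γ` is split in proportion to the
part of the cell at/above the threshold — one half when `γ` falls exactly
on a grid point, which the default grids arrange. Assigning the boundary
cell wholly to either side shifts the effective threshold by up to `w/2`
and biases the crossed fraction by `~(w/2)·x(γ)`; the fractional split is
unbiased under the (local) approximation that mass is uniform within a
cell. Retained plus crossed equals the input total exactly.

**Conservation.** Convolutions are zero-padded to full length (no circular
wraparound); mass carried past `a_max` accumulates in an explicit overflow
bucket that is alive, above any admissible threshold, and counted as
crossed at the next split. Deaths accumulate in a ledger, so
staged + emerged + flying + settled + dead is constant (to FFT round-off,
relative ~1e-14) at every step. Negative FFT ringing within
`1e-12 × max(1, total mass)` of zero is clamped; anything more negative is
a hard error.

**Order of operations within a day.** Age (convolve) → kill (multiply by
`1 − m` from the day's tmin) → split at `γ` → recruit crossers at age zero.
Recruits are neither aged nor killed again in the same step; the IBM
snapshots each individual's start-of-day stage to enforce exactly the same
semantics (an individual crossing A→B today develops under A's rate and
dies under A's rule today, and under B's tomorrow). Emerged adults awaiting
flight remain exposed to the final stage's cold rule; flying and settled
pools are not (flight happens outside the cold season, and settled beetles
have left the natal tree). Flight is applied after the day's
development/mortality update: the flying pool settles by
`1 − exp(−λ Δt)`, then — if the day's tmax strictly exceeds the flight
threshold — the emerged pool (including today's emergers) takes wing.

**Threshold boundary conventions.** Cold mortality triggers strictly below
−18 °C (a tmin of exactly −18 °C kills nothing); flight triggers strictly
above 18.3 °C. Maturation uses at/above-`γ` crossing (the IBM allows a
1e-9 relative slack so that `n` increments of exactly `γ/n` complete on
step `n`, matching the deterministic limit).

**Recruitment bookkeeping.** The engine's native form removes crossed mass
at each split ("truncation"). The equivalent difference form — cumulative
above-threshold mass today minus yesterday, with no removal — is
implemented as a separate diagnostic (`recruitment_series`); the two are
algebraically identical for mortality-free runs (verified to 1e-10 over a
30-day three-stage run) because mass already above `γ` can never re-enter
the sub-threshold region under a nonnegative-increment kernel. With
mortality the difference form double-counts killed crossers, so the
diagnostic rejects stages carrying a mortality rule.

**Grid sizing.** Default `a_max = 4 γ_s` with 128 bins. Resolving a
near-deterministic kernel requires `w ≲ σ · r Δt`; `build_kernel` logs a
warning when ≥99% of kernel mass lands in one bin while `σ > 0` (the
deterministic-limit checks therefore run at 1024 bins). Conversely, at
16 bins a `4γ` domain leaves only four cells below threshold and typical
mountain pine beetle daily increments (0.03–0.1) vanish entirely, so the
cohort/IPM resolution sweep uses a common `a_max = 1.5 γ` — still far
above `γ` plus several kernel standard deviations for these kernels.

## Parameters

| Parameter | Default | Meaning |
|---|---|---|
| `σ_s` | 0.15–0.25 per stage | log-normal scale of rate variability (dimensionless) |
| `γ_s` | 1 | development threshold per stage |
| `clip_floor` | 1e-8 day⁻¹ | rates at/below this are exact zero development (ln 0 is undefined; development halts in cold) |
| cold threshold | −18 °C | step-function mortality on egg, pupa, teneral adult, adult; larvae are cold-hardened and carry no rule |
| flight threshold | 18.3 °C | daily tmax above which emerged adults fly |
| settling rate | ln 2 / 3 day⁻¹ | exponential flight half-life of 3 days (illustrative; fit to flight data in applications) |
| `n_bins`, `a_max` | 128, 4γ | age-grid resolution per stage |

The per-stage rate curves bundled in `default_stages()` are Logan-type
hump curves (exponential rise, sharp collapse toward an upper lethal
threshold near 30 °C, optimum near 26 °C) with peak median rates of
0.06–0.16 day⁻¹ chosen once so that a brood laid in late July completes a
univoltine cycle — overwintering as fourth-instar larvae and flying the
next August — under the synthetic reference year. They are deliberately
labelled illustrative: fitted rearing-data parameters should be supplied
through the YAML life-cycle config for real applications.

## Synthetic forcing

The generator produces `tmean(d) = mean_annual + amplitude · cos(2π(doy −
peak_day)/365.25) + AR(1) noise` with tmin/tmax a symmetric half diurnal
range around the mean. The reference configuration (mean 4 °C, amplitude
16 °C, diurnal range 10 °C, AR(1) noise sd 3 °C, autocorrelation 0.6,
443 days from 15 July) emulates a cool continental mountain climate:
winters dip below the −18 °C mortality threshold and summer maxima clear
the 18.3 °C flight threshold.

What it does **not** emulate: asymmetric diurnal ranges, weather-regime
persistence beyond lag-1 autocorrelation, under-bark thermal buffering
(the affine bark transform defaults to the identity; the real air-to-bark
relationship is nonlinear), elevation/aspect effects, or multi-year
climate trends. Passing tests therefore demonstrate the *internal*
consistency of the three simulators and the correctness of the numerics
under realistic forcing statistics — not predictive skill against field
data, which requires station forcing and fitted rate curves.

## Validation statistics

Predicted flight curves and observed trap catches are compared as weighted
ECDFs aligned on the union of their supports; the KS statistic is the
maximum absolute difference, and the p-value is asymptotic (Kolmogorov
distribution at effective size `n_obs·n_pred/(n_obs+n_pred)`). Trap counts
are frequency weights for the *statistic*; the reported sample size
follows the records-in-the-time-series convention by default, with
counts-as-samples available behind a flag (the two conventions change the
p-value, never the statistic). Exact small-sample p-values are not
implemented; for the modest record counts typical of one trap season the
asymptotic p is adequate for a 0.05 verdict threshold, and the statistic
itself is convention-free (pinned exhaustively against a brute-force ECDF
oracle).

## Known limitations

- No density-dependent mortality, no reproduction closing the life cycle,
  no mating/oviposition submodel (a brood is introduced as a configurable
  start-time schedule), and no spatial structure or dispersal beyond the
  exponential settling term.
- Larval cold mortality is deliberately absent (cold-hardening interacts
  with development in ways that are still unresolved); mid-winter larval
  mortality can therefore not end a simulated outbreak here.
- A single life cycle is simulated (no multi-year voltinism loop).
- The IBM draws increments fresh each step; a persistent per-individual
  rate deviate (heritable "fast" and "slow" developers) would break the
  convolution representation and is not implemented.
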