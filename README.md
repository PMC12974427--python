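# hesdyn

Analysis of single-cell HES1 protein oscillations across cell cycle arrest
and reentry, with a calibrated synthetic trace generator.

## The problem

HES1 is a Notch-pathway transcriptional repressor whose protein level
oscillates in ER+ breast cancer cells. In cycling cells it carries a
dominant cell cycle-locked ~24 h ("circadian-level") oscillation — high
after mitosis, a characteristic dip 10–14 h before the next mitosis at the
G1/S transition, high again into mitosis — with a weak nested 4–8 h
ultradian component. During reversible CDK4/6-inhibitor (palbociclib)
arrest the ~24 h oscillation is lost, mean levels rise ~1.4-fold, and the
ultradian component is relatively enhanced; on drug withdrawal cells reenter
the cycle through a deep synchronous HES1 dip that precedes S-phase entry.
Sustaining HES1 (an anti-phase exogenous copy flattening the total signal)
blocks that dip and prevents reentry.

`hesdyn` packages the quantitative pipeline behind those observations for
anyone analyzing long-term single-cell reporter tracks: normalization and
band-isolating detrending, Lomb–Scargle and autocorrelation periodicity,
mitosis-to-mitosis pseudo-time alignment, dip/peak event statistics, phase
relations between reporters, and reentry/division statistics. Because the
original imaging tracks are not bundled, a first-class synthetic cohort
generator reproduces the statistical structure of each experimental regime
(proliferative, arrested, released, misexpression, constitutive control),
calibrated so the full pipeline recovers the headline population statistics
reported for this system — 23–25 h median periodicity, a dip 10–14 h before
mitosis, 85% reentry within 30 h, a 2.2-fold release dip, 1.4-fold arrest
levels, 89% dip–S-phase coincidence, and 75% vs 14% division in the 24 h
misexpression assay.

## Core quantities

For a uniformly sampled track *y(t)* (hours, arbitrary units):

- **Band isolation** subtracts a centered moving average of width *W*:
  a period-*T* sinusoid is retained with amplitude 1 − sinc(*W*/*T*).
  *W* = 40 h isolates circadian-level oscillations, *W* = 12 h isolates
  ultradian ones.
- **Lomb–Scargle periodogram (standard normalization):** at each frequency
  the power is the fraction of signal variance explained by a least-squares
  sine+cosine fit, so P(f) ∈ [0, 1]; the dominant period is the grid
  maximum, and band power is the mean of P over grid periods inside the
  20–30 h or 4–8 h band.
- **Pseudo-synchronization:** each mitosis-to-mitosis segment is rescaled
  to percent-of-cycle before averaging, exposing cycle-locked oscillations
  that cancel in real-time averages of asynchronous cells.
- **Dip statistics:** the per-cell minimum of the z-scored
  circadian-isolated daughter-generation segment, in hours before the final
  mitosis; the post-release dip fold-change is intensity at release divided
  by the minimum before the first mitosis.
- **Phase coincidence:** two events are coincident when they fall within
  1 h; the headline statistic is the fraction of cells whose HES1 dip
  precedes or coincides with S-phase onset.

## Worked example

Simulate the default proliferative cohort (3 replicates × 90 cells, 96 h at
0.25 h sampling) and measure its periodicity and dip timing:

```bash
hesdyn simulate --regime proliferative --n-cells 90 --replicates 3 \
    --duration 96 --seed 1 --out tracks.csv
hesdyn periodicity --band circadian --in tracks.csv --out spectra.csv
hesdyn periodicity --band ultradian --in tracks.csv --out spectra_u.csv
hesdyn diptiming --in tracks.csv --out dips.csv
```

prints

```
wrote 270 traces to tracks.csv
median circadian period: 24.04 h over 270 cells
median ultradian period: 6.58 h over 270 cells
median dip time -12.26 h over 206 cells
```

i.e. the cohort's cell cycle-locked oscillation has a ~24 h median period
(the generating median cycle length is 23.3 h), the nested ultradian
component sits in the 6–7 h range, and across the 206 cells with two
annotated generations the HES1 minimum falls a median of 12.3 h before the
final mitosis — inside the 10–14 h G1/S window.

The same operations are available as library calls:

```python
import hesdyn as hd

cohort = hd.simulate_cohort(hd.calibrate_defaults()["released"],
                            n_cells=100, n_replicates=3,
                            duration=96.0, dt=0.25, seed=1)
hd.reentry_stats(cohort, window=30.0)["fraction"]      # ~0.85
```

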