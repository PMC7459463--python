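# Methods

## The fingerprinting procedure

The input is a stationary sensor-noise voltage record x(t) sampled at f_s.
Its one-sided power density spectrum S(f) is estimated by Welch's averaged
periodogram (Hann window, 50 % overlap, per-segment mean removal,
`scipy.signal.welch` with density scaling), the DC bin is dropped, and the
estimate is smoothed onto a logarithmic grid (geometric-mean frequency and
arithmetic-mean density per log bin). All subsequent analysis happens on the
(log₁₀ f, log₁₀ S) plane.

Given an analysis band [f_L, f_H] tiled into n sub-bands with log-equal
edges, every slope is a **chord**: the straight line through the two band
endpoint values, with endpoint densities obtained by linear interpolation in
log-log coordinates when they fall between grid points. Interior structure
is deliberately ignored — the chord, not a least-squares fit, is the
method's defining convention (a least-squares variant,
`least_squares_slope`, exists for comparison only). Chord slopes on
log-equal plans telescope: the mean of the n local slopes equals the global
slope identically, which implies every binary fingerprint contains at least
one +1 bit.

Binary coding compares each local slope with the global slope; the tie goes
to +1 ("below → −1, otherwise → +1"), so a pure power law codes as all +1.
Ternary coding compares each local slope with the reference spectrum's local
slope over the identical sub-band; the reference is first resampled onto the
agent's in-band grid (union of grid points and sub-band edges) in log-log
space so both slope profiles share exactly the same endpoints. Equality is
declared within a tie tolerance τ: an exact floating-point equality test
would make the 0 symbol unreachable on estimated spectra, so τ is an
explicit, reported parameter rather than an implicit machine epsilon.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| Welch segment length | 4096 (2048 in the packaged experiments) | samples | ≥ 100 averaged segments at the packaged record length, for stable log-log slopes |
| overlap | 0.5 | — | standard Hann-window Welch practice |
| window | Hann | — | low leakage for steep (γ ≈ 2) spectra |
| log binning | 12 | bins/decade | smooth enough for stable local slopes, fine enough for 5–10 sub-bands over 2–3 decades |
| analysis band | [2·f_min, 0.8·f_Nyquist] unless given | Hz | discards the noisiest lowest bin and the anti-aliasing roll-off; always operator-overridable |
| sub-bands n | 5 | — | matches the five-symbol codes used throughout the examples |
| tie tolerance τ | 0.05 | slope units | ≈ 2.5–4× the chord-slope scatter at the packaged acquisition settings, so designed slope ties are read as 0 reliably while ±0.5 margins never alias into 0 |
| distance | Hamming count | — | minimal assumption; a graded variant (sign flip = 2, zero step = 1) is provided but non-default |

Band endpoints are closed everywhere, logs are base-10 throughout (slopes
are base-invariant when both axes share a base), and spectra with
non-positive densities are rejected outright — flooring them would silently
corrupt slopes.

## The noise simulator

`simulate_noise` draws a zero-mean Gaussian record whose *expected*
one-sided PSD is a piecewise power law: white Gaussian Fourier coefficients
are scaled by √(S(f)·f_s·N/2), Hermitian symmetry is enforced (DC zero,
Nyquist bin real), and the result is inverse-transformed. This gives the
exact target spectrum in expectation for any piecewise law, with no
filter-design error. Frequencies outside the model's stated support follow
the nearest segment's law, so any (0, f_Nyquist] grid is legal. A
"measurement pair" — the in-silico analogue of measuring the same Petri
plate twice — is two draws with seeds s and s+1; all randomness flows from
one user-visible seed.

What the simulator emulates: the piecewise-1/f^γ spectral shapes and the
measurement-to-measurement estimator scatter of repeated acquisitions. What
it does not emulate: sensor drift, temperature sensitivity,
adsorption–desorption kinetics, non-Gaussian or nonstationary fluctuations,
and Lorentzian (generation–recombination) components. Passing tests
therefore demonstrate that the *analysis chain* is correct and reproducible
under its stated statistical model, not that any particular physical sensor
achieves these agreement rates.

`designed_model_pair` constructs the packaged experiment: a 1/f reference
("laboratory air") and an agent whose power-law segment boundaries coincide
exactly with the sub-band edges of the 3–300 Hz five-sub-band plan, so the
agent's analytic local slopes sit at prescribed offsets
(+0.5, −0.5, 0, +0.5, +0.5) from the reference's. The non-zero margins of
0.5 slope units are an order of magnitude above the estimator scatter
measured at the packaged acquisition settings (σ ≤ 0.045 per sub-band), and
the slope-matched sub-band lies mid-band where scatter is smallest
(σ ≈ 0.02), keeping it within τ = 0.05 on essentially every draw.

## Problem sizes

The packaged experiments use records of 2¹⁹ samples at 1000 Hz (≈ 8.7 min
of signal per measurement, 511 averaged Welch segments of 2048), 20
measurement pairs for the reproducibility statistic, 10 seeds per exponent
for slope recovery over γ ∈ {0.5, 1, 1.5, 2}, and ≥ 100 random spectra /
≥ 1000 random ternary strings for the property suites. These sizes were
chosen so every stochastic check operates with comfortable statistical
margin; the whole acceptance script completes in seconds on one CPU.

## Numerical and design choices

- **Resampling** is linear interpolation of log₁₀ S vs log₁₀ f, exact on
  power laws; extrapolation beyond a spectrum's support is always an error.
- **Degenerate inputs** fail loudly with typed exceptions: series shorter
  than two Welch segments (`SizingError`), bands keeping fewer than two
  points (`BandError`), reference spectra not covering the analysis band
  (`AlignmentError`), incompatible fingerprints (`CompatibilityError`).
- **Classification ties** are surfaced as an ambiguity result listing all
  tied labels; the sklearn wrapper's `predict` raises unless the caller
  explicitly opts into lexicographic tie-breaking.
- **Determinism**: writers use fixed field order and 13-significant-digit
  numeric formatting, so identical configuration and seed give byte-identical
  artifacts; reader/writer pairs round-trip to 12 significant digits.
- The sklearn estimators intersect a requested analysis band with the
  log-binned grid's actual support, since a log-binned grid cannot carry
  points exactly at requested band edges.

## Known limitations

- Fingerprints built from differently configured analyses (band, sub-band
  count, binning) are deliberately incomparable; there is no automatic
  re-alignment of foreign fingerprints.
- The tie tolerance trades zero-bit sensitivity against sign-bit stability;
  no data-driven calibration of τ is attempted.
- Only alphabets of size 2 and 3 are implemented, and only Gaussian
  piecewise-power-law noise is simulated.
- The nearest-fingerprint classifier has no rejection threshold: a query far
  from every library entry still returns the (possibly meaningless) nearest
  label together with its distance, and it is the caller's job to gate on
  that distance.
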