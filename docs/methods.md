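# Methods

## Model

A peptic peptide of sequence length L observed as a singly protonated MALDI
ion has N = L − 1 − (internal prolines) exchangeable backbone amide
hydrogens: one per peptide bond, none for proline (no amide hydrogen) and
none for the N-terminal residue (an amine, not an amide). The HDX reaction
sample is modelled as a mixture over the incorporation count k = 0..N, with
unknown fractions f_k ≥ 0, Σ f_k = 1.

### Theoretical envelopes

The envelope of the species with exactly k amide deuteriums is built in
three steps:

1. **Natural pattern.** The elemental composition (CHNOS) of the neutral
   peptide is the sum of residue formulas plus H2O. Its isotope pattern is
   computed by iterative convolution of the elemental isotope distributions
   (CIAAW/IUPAC masses and abundances, hard-coded in `chem.ISOTOPES`).
   Isotopologues are aggregated on the fly into nominal-mass bins keyed by
   total neutron count; each bin's reported m/z is the abundance-weighted
   mean mass of its members. This binning is exact for the mixture algebra
   and mirrors what a reflectron-TOF instrument resolves: the ~1 Da comb, not
   the fine structure within each peak. Because bins are integer-keyed the
   convolution is linear, not exponential, in formula size; no intermediate
   pruning is needed and the engine agrees with exhaustive isotopologue
   enumeration to 1e−10 in abundance for small formulas (see
   `tests/test_chem.py`).
2. **Side-chain removal.** Fast-exchanging side-chain and terminal hydrogens
   (per-residue labile counts R:4 K:2 H:1 D:1 E:1 S:1 T:1 N:2 Q:2 Y:1 W:1
   C:1, plus 2 for the N-terminal amine and 1 for the C-terminal carboxyl)
   re-equilibrate with the quench solvent and carry no structural signal.
   They are stripped from the formula and re-added as a binomial(n_side, p)
   occupancy distribution at the solvent deuterium fraction p (default 0.9,
   i.e. a 1:9 H:D buffer); each occupied site adds the D−H mass difference
   1.006277 Da. The ionizing proton (1.007276 Da) is added once as a
   non-exchanging mass offset.
3. **Backbone shift.** Component k is the stripped envelope rigidly shifted
   by k × 1.006277 Da before the side-chain convolution, so k counts only
   backbone amide deuteriums. All N+1 components are placed on the common
   union grid of nominal bins (zero-padded), each renormalized to unit sum.

### Quantification and fit

Observed spectra are plain two-column ASCII (whitespace or comma delimited,
`#` comments). Each theoretical peak is quantified by the trapezoidal
integral of intensity over a window of ± half_width (default 0.3 Da) with
linear interpolation at the window edges; with ~1 Da peak spacing the default
windows cannot overlap, and a warning is emitted if a user widens them until
they do. No baseline is subtracted by default. Unresolved (linear-mode)
peptides are summarized by the intensity-weighted average mass over a window
instead.

The area vector y is scaled to unit sum (removing the intensity scale) and
fit by active-set NNLS (`scipy.optimize.nnls`): min ‖A f − y‖², f ≥ 0, with
column k of A the k-deuterium envelope on the grid. The solution is
renormalized to Σ f_k = 1. Exact zeros in reported profiles arise naturally
from the non-negativity active set; no sparsity penalty is applied. A
rank-deficient basis (possible only for pathologically wide envelopes) is
still solved but flagged as non-unique on the profile. Summaries:
average exchanged atoms ⟨k⟩ = Σ k f_k; deuteration ratio = 100 ⟨k⟩ / N (%),
undefined (rejected) for N = 0.

### Kinetics

Uptake time courses are fit by weighted nonlinear least squares to

    D(t) = D_inf − A exp(−k_obs t),

with bounds 0 ≤ D_inf ≤ 100, A ≥ 0, k_obs ≥ 0, weights 1/sd² when per-point
standard deviations are supplied. D_0 = D_inf − A is the zero-time uptake —
sites exchanging faster than the first sampled time. Initialization is
data-driven (D_inf ← max D, A ← range, k_obs ← 1/median t) plus 10 jittered
restarts from a seeded generator; the lowest-SSR fit wins. When the best fit
drives A to zero — or the flat model D(t) = const fits no worse — the series
is reported as A = 0 with k_obs undefined (NaN) and D_inf the weighted mean,
since k is then unidentifiable. Parameter uncertainties are 1σ values from
the covariance of the converged fit; var(D_0) = var(D_inf) + var(A) −
2 cov(D_inf, A). At least 4 time points are required for the 3 free
parameters.

Region-specific uptake for a sub-region covered by nested peptic fragments
(child contained in parent) is the amide-weighted difference

    D_region = (D_parent n_parent − D_child n_child) / (n_parent − n_child)

with standard deviations propagated in quadrature. Noise can push region
values slightly outside [0, 100]; points outside [−5, 105] are kept but
warned about, and should be clamped only for display.

## Synthetic data

The simulator exists so that every stage is testable against known ground
truth without instrument data. `render_spectrum` draws each basis peak as a
Gaussian of FWHM = m/z / resolution (default resolution 10000, typical of a
reflectron TOF at ~1 kDa) whose integrated area equals f_k × abundance,
samples at 0.01 Da, and superimposes seeded additive Gaussian noise scaled to
the maximum intensity. The noise is left untruncated so integrated peak
areas stay unbiased; measured window areas are floored at zero instead.
`render_time_series` evaluates the exponential model at the standard
sampling schedule 1, 3, 5, 7, 10, 20, 40 min and adds seeded noise.

What the simulator does *not* emulate — matrix cluster peaks, detector
saturation, calibration drift, isotope-dependent peak widths, chemical
baseline — bounds what passing tests show: they validate the computation
(envelope algebra, integration, NNLS, kinetics), not robustness to every
instrumental artifact. Real spectra with poor calibration (> ~0.3 Da error)
would need recalibration upstream, which is out of scope.

## Numerical choices and defaults

| Parameter | Default | Meaning |
|---|---|---|
| `solvent_D_fraction` | 0.9 | D fraction of exchange/quench solvent (1:9 H:D) |
| `half_width` | 0.3 Da | peak integration half-window |
| `prune_threshold` | 1e−6 | envelope tail-trimming abundance cutoff |
| `resolution` | 10000 | simulator m/Δm at FWHM |
| `mz_step` | 0.01 Da | simulator sampling interval |
| noise seed | explicit everywhere | all randomness is seeded and recorded |

Tail trimming removes only leading/trailing sub-threshold bins so the ~1 Da
peak spacing is preserved; envelopes are renormalized after trimming. Since
every component shares the trimmed base envelope, centroid differences
between components remain exactly k × 1.006277 Da regardless of trimming.

Degenerate inputs are rejected with specific errors: unknown residue letters
(named with position), all-zero observations, empty spectra windows (area 0
with a warning rather than an error), zero-amide deuteration ratios,
sub-4-point kinetics series, and zero-amide children in nested subtraction.

## Design choices made where the design was open

- **Normalization before fitting** is by total area (unit-sum), not peak
  height; it makes the fit invariant to intensity rescaling and the profile
  independent of absolute counts.
- **Binomial side-chain occupancy** is the standard physical model for
  solvent-equilibrated labile sites and is what "computational removal" of
  side-chain exchange amounts to; the per-residue labile table follows
  common HDX practice (cysteine counted as a free thiol; no modified
  residues supported).
- **Components are shifted by the exact D−H mass difference**, not an
  averaged isotope spacing; for singly charged ions at reflectron accuracy
  the distinction is well inside the ±0.3 Da window.
- **Profile vs stick data**: the same windowed-area contract handles both;
  a stick spectrum is treated as a piecewise-linear signal.
- **Batch time points** are parsed from a `t<minutes>min` token in spectrum
  file names when present (no convention is imposed otherwise; the field is
  NaN when absent).

## Test problem sizes

The suite validates recovery with: 100 random composition profiles at 2%
noise (average uptake recovered within 0.1 atoms), 200 noisy kinetics series
at 1% noise (median D_inf error < 1 point, D_0 < 2 points), exhaustive
isotopologue enumeration for formulas up to 8 atoms, and property-based
sweeps (hypothesis, derandomized) over random sequences for the amide-count
rule and hydrogen partition. These sizes keep the full suite around a
minute on one CPU while giving stable medians.

## Known limitations

- Singly charged ions only; no ESI charge-state handling.
- No post-translational modifications or non-standard residues.
- No bimodality significance testing or automatic conformer assignment —
  multimodal profiles are reported quantitatively and interpreted by the
  user.
- Back-exchange during workup is not corrected for; it appears as a
  reduced apparent deuteration ratio, as it does in the measurement.
- Single-exponential kinetics only; stretched/multi-exponential or
  per-residue models are out of scope.
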