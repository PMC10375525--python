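# Methods

## The system and the model

Two protein nanodisks, each a double-layered circular assembly of 34
coat-protein monomers carrying one chromophore per monomer, are joined
covalently at their peripheries. One disk is labeled with a donor dye,
the other with an acceptor. Because the closest donor–acceptor pair
sits above 7 nm — far beyond contact-quenching range — any inter-disk
energy transfer is Förster-type, and the donor's fluorescence lifetime
is the observable: transfer opens an extra decay channel, shortening
the donor lifetime from τ_D (donor-only disk) to τ_DA (coupled disks).

The three inferred quantities follow from rate additivity of the
donor's excited-state decay:

    1/τ_DA = 1/τ_D + 1/τ_T
    τ_T = (1/τ_DA − 1/τ_D)⁻¹,  k_T = 1/τ_T,  E = 1 − τ_DA/τ_D.

The two expressions for E are algebraically linked: E = τ_DA/τ_T. When
τ_DA ≥ τ_D the model has no transfer to report; the package returns an
infinite timescale sentinel (zero rate, zero efficiency) rather than a
negative τ_T, since the expressions are undefined there.

### Collapsing biexponential fits to one lifetime

Donor decays on the protein scaffold are biexponential (a long
solvent-exposed component near 4.5 ns and a short dye–dye interaction
component). The transfer expressions take one lifetime per sample. The
package's default is the amplitude-weighted mean Σaᵢτᵢ/Σaᵢ, with the
donor-only fully-labeled disk as the τ_D reference. This choice is an
inference, fixed by brute force rather than convention:
`pipeline.enumerate_averaging_schemes` crosses four schemes
(amplitude-weighted, intensity-weighted, short-only, long-only) with
three candidate donor references (the sparsely labeled disk, the fully
labeled disk, and the uncoupled donor/acceptor mixture) and exactly
one combination — amplitude-weighted with the fully labeled donor-only
disk — reproduces the reported 0.066 ns⁻¹ / 15 ns / 21% triplet
simultaneously. The intensity-weighted mean and the single-component
schemes remain selectable.

## Idealized coupled-disk geometry

The pathway analysis replaces distance measurements on the atomic
structure with a parametric idealization:

- each disk is two rings of 17 sites; ring radius comes from chord
  inversion of the nearest-neighbor spacing s: r = s / (2 sin(π/n)),
  giving r = 5.306 nm at s = 1.95 nm;
- the two rings of a disk are coaxial, 2.5 nm apart axially (half a
  nominal 5 nm disk height; the true axial offset of the labeling
  sites is not derivable from sequence, and the pathway distribution
  is only mildly sensitive to it), with zero azimuthal offset;
- the disks sit side-by-side with parallel coaxial normals, one site
  of each ring aligned on the inter-center axis, so the in-plane
  center separation that calibrates the closest inter-disk pair to
  d_min is exactly d_min + r_donor + r_acceptor (18.11 nm at
  d_min = 7.5 nm).

All distances are 3-D Euclidean in nm. The calibrated model spans
7.5 nm (closest pair, realized exactly by construction and verified by
brute force over all pairs) to 28.72 nm (furthest pair, reported as
~29 nm). Pathway weights are the distance-only Förster shares
p_i = R_i⁻⁶/Σ_j R_j⁻⁶; no dipole-orientation factor (κ²) is modeled,
so the weights say which pairs *could* matter geometrically, not which
do photophysically. Both the all-pairs normalization (1156 pathways)
and a k-nearest renormalization (e.g. the 25 nearest pairs) are
supported; under either, the maximum single-pathway share stays well
below 12% (2.6% all-pairs, 6.6% top-25).

Not modeled: linker flexibility and non-parallel disk orientations,
sites off the ring circumference, and networks of more than two disks.

## TCSPC simulation

A decay model is a set of (amplitude, lifetime) components plus a
background fraction. The expected histogram is the decay convolved
with a Gaussian IRF plus a flat background; counting noise is a
multinomial draw over the normalized profile, conditioning on the
total recorded photon count as real acquisitions to a target count do
(independent per-bin Poisson noise is an option).

Defaults, chosen once as realistic acquisition conditions where the
experimental description is silent:

| parameter | default | why |
|---|---|---|
| IRF shape / FWHM | Gaussian, 150 ps | stated instrument width; Gaussian is the minimal model for a width-only specification |
| IRF position t₀ | 2 ns | leaves a pre-pulse baseline for background estimation |
| channel width | 16 ps | typical TCSPC channelization |
| window | 4096 bins ≈ 65.5 ns | > 10× the longest lifetime; re-excitation wrap-around negligible and not modeled |
| total counts | 10⁶ | bright-sample acquisition |
| background fraction | 5% | dark counts/scatter floor present in every real measurement; keeps tail bins populated as real data are |

For the parametric Gaussian IRF the convolution is evaluated in
closed form per component (the exponentially modified Gaussian,
written in log space with an asymptotic erfc branch so the far
pre-pulse tail neither overflows nor loses precision), which is exact
at every bin center. A discrete-convolution path exists for tabulated
IRF profiles; it agrees with the closed form to its O(h²)
discretization error away from the rising edge, and its summed counts
are exactly conserved because the IRF profile is unit-sum.

Dead time, afterpulsing, pile-up, anisotropy and multi-detector
routing are out of scope.

## Reconvolution fitting

Free parameters: one or two amplitudes and lifetimes, a flat
background, and the IRF temporal position (bounded within ±0.5 ns of
its nominal value). The fit window runs from 1 ns before the IRF
position to the last bin with at least one count. The default
objective is the Pearson chi-square, Σ(y−m)²/m: under Poisson noise
its per-bin expectation is exactly 1 at any count level, so reduced
χ² = χ²/(n_bins − n_par) is a calibrated goodness-of-fit statistic
even in sparse tail bins, and the minimizer is effectively a
chi-square-weighted maximum-likelihood surrogate. The data-weighted
Neyman variant (1/max(y,1)) common in instrument software is
selectable but biases lifetimes low when the window contains
low-count bins — on simulated million-count decays the bias reaches
several estimated standard errors — which is why it is not the
default. A signed-deviance Poisson MLE objective and unweighted least
squares are also available.

Minimization uses trust-region least squares (via lmfit), with
standard errors from the asymptotic covariance at the optimum. These
SEs are comparable to, but not expected to match exactly, values from
support-plane analysis. Initialization is automatic: background from
the pre-pulse baseline, the long lifetime from the log-slope of the
decade-down tail, the short lifetime from the early-decay log-slope.
Because biexponential objectives can be multimodal, the fit runs
`multi_start` (default 5) seeded restarts with log-normal jitter on
the initial guesses and keeps the best objective; on clean
high-count data a single start from the automatic guesses converges
to the same optimum. If a biexponential fit's two lifetimes collapse
within a ratio of 1.2, the data are refitted monoexponentially and
the result flagged. Model selection (`compare_models`) prefers the
biexponential only when it improves reduced χ² by more than a
threshold (default 0.02) *and* resolves the lifetimes (ratio > 1.5);
ties go to the simpler model.

## What the synthetic validation does and does not show

The simulate → fit → infer loop (`run_synthetic_validation`, and the
20-replicate recovery check in the test suite) demonstrates that the
estimator recovers its own generating model: lifetimes and amplitude
fractions within stated uncertainties at 10⁶ counts, reduced χ² within
[0.9, 1.1], and the downstream (k_T, E) consistent with the analytic
values of the generating lifetimes. It does not validate the physical
assumptions — a Gaussian IRF, a strictly biexponential decay, a flat
background, or the absence of dead-time artifacts — so agreement on
real instrument data depends on those holding approximately.

## Numerical conventions

- Times in ns, rates in ns⁻¹, distances in nm; histogram bin centers
  at (k+½)·width, axis starting at 0.
- Pathway tables are sorted by ascending distance; weights sum to 1
  to 1e-12 and are strictly decreasing wherever distance strictly
  increases (ties share equal weight).
- Reported precision mirrors conventional reporting — rates to three
  decimals, timescales to the nearest ns, efficiencies to whole
  percent (halves rounded up) — alongside full-precision values.
- Geometry calibration is verified to 1e-6 nm by brute force after
  construction; an unsatisfiable calibration raises instead of
  returning an approximate geometry.
- Every pipeline report embeds the configuration hash and seed;
  identical inputs give identical reports.
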