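# diskfret

Lifetime-based Förster resonance energy transfer (FRET) analysis for
covalently coupled ring-array chromophore assemblies.

Protein nanodisks (34-monomer, double-layered circular assemblies of a
tobacco mosaic virus coat-protein variant) can each carry a circular
array of 17 dyes per layer — a synthetic mimic of the ring-shaped
pigment arrays of bacterial light-harvesting complexes. When a
donor-labeled disk is covalently joined at its periphery to an
acceptor-labeled disk, excitation energy migrates between the disks by
FRET. `diskfret` is for spectroscopists and protein engineers who want
to quantify that transfer from time-correlated single photon counting
(TCSPC) measurements and to reason about the many-pathway geometry of
ring-to-ring transfer.

## What it computes

**Lifetime fitting.** A TCSPC decay is modeled as a mono- or
biexponential decay convolved with a Gaussian instrument response
function (IRF, 150 ps FWHM by default) plus a flat background, fitted
by iterative reconvolution (Pearson-weighted least squares; Neyman,
Poisson-MLE and unweighted objectives selectable) with asymptotic
standard errors and reduced χ².

**Transfer inference.** With τ_D the donor lifetime in a donor-only
disk and τ_DA the donor lifetime when coupled to an acceptor disk,

    τ_T = ( 1/τ_DA − 1/τ_D )⁻¹ ,   k_T = 1/τ_T ,   E = 1 − τ_DA/τ_D ,

where τ_T is the transfer timescale, k_T the transfer rate and E the
transfer efficiency. Multiexponential fits are collapsed to a single
lifetime by the amplitude-weighted mean Σaᵢτᵢ/Σaᵢ (intensity-weighted
and single-component schemes selectable).

**Pathway geometry.** An idealized 3-D model of the coupled disks —
two rings of 17 sites at 1.95 nm spacing per disk, rings 2.5 nm apart,
disks side-by-side with the closest inter-disk pair calibrated to
7.5 nm — yields all 34×34 donor–acceptor distances R_i and the
distance-only pathway weights p_i = R_i⁻⁶ / Σ_j R_j⁻⁶, i.e. the share
of transfer each pair would carry from the 1/R⁶ law alone.

**Synthetic data.** A TCSPC simulator (multiexponential decay ⊗
Gaussian IRF, flat background, multinomial or Poisson counting noise)
provides ground-truth histograms so the whole fit-and-infer pipeline
is testable without instrument data.

## Worked example

Donor lifetimes from the packaged lifetime-component table
(amplitude-weighted: τ_DA = 3.126 ns for the coupled disks,
τ_D = 3.933 ns for the donor-only disk):

```
$ diskfret infer --tau-da 3.126 --tau-d 3.933
tau_T: 15 ns (15.2349 ns)
k_T  : 0.066 ns^-1 (0.0656388 ns^-1)
E    : 21 % (0.205187)
```

About one excitation in five crosses from the donor disk to the
acceptor disk, on a ~15 ns timescale — slow compared with the donor's
~4 ns radiative decay because the closest donor–acceptor pair is
already 7.5 nm apart. The geometry shows why no single pair dominates:

```
$ diskfret geometry
center separation : 18.112 nm
closest pair      : 7.500 nm
furthest pair     : 28.719 nm
pathways          : 1156
max contribution  : 2.57 %
```

The strongest of the 1156 donor–acceptor pathways carries under 3% of
the transfer, so the observed efficiency is the sum of many weak,
redundant routes — the same design principle as inter-complex transfer
in photosynthetic membranes. Simulation and refitting close the loop:

```
$ diskfret simulate --tau 0.86 --tau 4.39 --amp 0.3582 --amp 0.6418 \
      --background 0.05 --counts 1000000 --seed 1 --out decay.tsv
$ diskfret fit decay.tsv
tau_0: 0.8862 +/- 0.0180 ns  amp: 1682.1 +/- 19.5
tau_1: 4.3971 +/- 0.0093 ns  amp: 3117.9 +/- 13.2
short component amplitude: 35.04 %
reduced chi^2: 0.9694
amplitude-weighted lifetime: 3.1667 ns
```

`diskfret reproduce` runs the full table-to-report computation and
`diskfret validate --seed 1` runs the simulate → fit → infer recovery
check; `diskfret show-config` prints every default.

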