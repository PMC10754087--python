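# Methods

`molspan` reimplements, as a tested pipeline, the integrative analysis by
which molecule-spanning ~150 ns dynamics are inferred in a large
multi-domain protein dimer (the Hsp90 chaperone is the motivating system):
single-molecule fluorescence (burst selection, nanosecond FCS,
time-resolved anisotropy), trajectory mode analysis (inertia-axis
rotational ACF, cartesian PCA, accessible dye volumes, elastic-network
modes) and quasi-elastic neutron scattering (NSE effective diffusion,
mode amplitude functions, backscattering confinement fits). Real
single-molecule photon records, microsecond MD trajectories and neutron
beamtime data are not shippable at desk scale, so every stage is paired
with a synthetic generator whose ground truths are the published fitted
values; correctness is demonstrated by parameter recovery.

## Photon-stream model

Detection events are generated molecule by molecule (molecules are
independent, so their photon streams superpose exactly):

* **Diffusion.** Each molecule performs 3D Brownian motion through a 3D
  Gaussian focus with lateral waist w and axial elongation kappa; the
  diffusion coefficient is set from the diffusion time tau_D = w^2/(4D).
  Molecules live in a box of +-2.5 waists for windows of 10 tau_D;
  brightness profiles are piecewise constant at tau_D/25 resolution,
  which is far below every correlation feature analyzed (<= 1 us).
* **Photophysics.** The emission rate is multiplied by (i) a symmetric
  two-state brightness telegraph with contrast c_b and correlation time
  tau_b (the conformational bunching process; a lognormal
  Ornstein-Uhlenbeck modulation is selectable since the microscopic
  process is not established), (ii) a triplet on/off telegraph with
  contrast c_T and relaxation time tau_T, and (iii) antibunching renewal
  1 - exp(-dt/tau_ab) since the molecule's previous emission, a
  deliberate simplification of excitation-emission cycling that
  reproduces the lifetime-limited dip of the nanosecond correlation
  functions.
* **FRET and detection.** Each excitation transfers with the state's
  efficiency E; donor decays are quenched accordingly and microtimes are
  drawn from the resulting exponential cascades. Crosstalk routes donor
  photons into the acceptor channel with probability alpha/(1+alpha),
  detection efficiencies realize gamma, and pulsed interleaved excitation
  (50 ns period) adds direct acceptor excitation for stoichiometry.
* **Polarization.** A dipole per dye evolves by hierarchical rotation:
  isotropic global tumbling (rank-2 time rho_global) carrying a local
  cone (OU tilt, relaxation rho_local, plateau A_local) carrying the dye
  cone (rho_dye, A_dye). Photoselection weights excitation by cos^2 and
  polarized collection splits emission into parallel/perpendicular
  channels. Two instrument-realism parameters interpolate between ideal
  and saturated/depolarized optics: `photoselection_weight` and
  `polarization_fidelity`. The anisotropy configurations use ideal values
  (1.0); the nsFCS configurations use 0.1/0.15, chosen so the rotational
  intensity modulation is weak relative to the conformational bunching
  term, matching the observation that the polarization (branch
  difference) signal is far smaller than the 149 ns component. The
  small-tilt mapping sigma^2 = (1 - sqrt(A))/3 converts cone plateaus to
  OU tilt amplitudes and is accurate for plateaus >~ 0.3.

Count rates (peak molecular brightness 5e6/s before photoselection, mean
occupancy 0.3) are higher than typical experimental rates; they condense
hours of acquisition into 30 s streams so that six-replica recovery runs
finish in minutes. Statistical structure (burst statistics, contrast,
photon-pair noise) is unaffected by this rescaling. The open-state
configuration uses a higher excitation power (7.1e6/s): its
donor-dominated signal at E = 0.13 otherwise carries about half the
informative pair counts of the closed state per unit time.

## Burst analysis

Bursts are maximal photon runs with all inter-photon gaps <= Delta-T
(default 100 us), kept for 35 <= N <= 10 000 photons; the dual-channel
variant intersects segments found independently in the donor- and
acceptor-excited subsets. E, S and r follow the standard corrected
forms; G is applied to F_DA consistently in numerator and denominator
(the printed formula is typographically ambiguous; this choice keeps
E in [0, 1] for ideal data). Degenerate denominators return NaN
sentinels so stream-scale processing never raises.

## Correlation analysis

The correlator histograms photon pairs into arbitrary lag bins directly
from arrival times (two-pointer sweep, O(pairs)), with the symmetric
normalization C(tau) T^2 / (N_a N_b dtau (T - tau)). Substate
correlations aggregate pair counts over selected bursts and normalize by
the summed per-burst uncorrelated expectation; every pair then enters
with unit weight and the Poisson error model is exact. (A
duration-weighted average of per-burst correlations was measured to
inflate per-bin noise 2x through unequal per-pair weights and was
rejected.) Per-bin errors use locally smoothed expected counts rather
than observed counts — observed-count weighting correlates the weight
with the fluctuation and biases least squares low wherever bins hold
only a few pairs (the acceptor-acceptor curve of the open state).

The linear nsFCS model
`G = a (1 - c_ab e^{-|tau-tau0|/tau_ab}) (1 + c_b e^{-|tau-tau0|/tau_b})`
is fitted globally over D x D, A x A and A x D on a 1 ns grid to 1 us
with tau_b (and tau_0) shared, multi-started over tau_b decades. Two
slow nuisance factors multiply the model with coefficients determined
beforehand from a tail window (0.5-25 us) of the same burst-selected
correlations: a triplet factor (1 + c_T e^{-tau/tau_T}) with tau_T the
known dye constant and c_T estimated from the tail (burst overlap
dilutes molecular contrasts, so the equilibrium c_T would overcorrect),
and a linear baseline (1 + b tau) per curve for the slowly decaying
within-burst diffusion profile. Without these, the bunching time
acquires +5..+10 ns biases from slow structure leaking into the window.

## Time-resolved anisotropy

Polarized microtime histograms from substate-selected bursts give
r(t) per bin with first-order Poisson errors; the cone-in-cone model
`r = r0 ((1-A_dye) e^{-t/rho_dye} + A_dye)((1-A_local) e^{-t/rho_local} + A_local) e^{-t/rho_global}`
is fitted globally over populations with rho_dye and rho_global shared
and r0 fixed at 0.4. The default fit starts at 0.5 ns (no IRF model is
needed beyond that), and rho_local is bounded to [0.1, 20] ns to prevent
exchange with the dye term. Because the 52 ns tumbling must be read from
a ~3.8 ns lifetime window, recovery is strongly photon-limited: the
anisotropy generator defaults to 2e8 photons per population
(tens of measurement hours, consistent with the 68 x 1 h acquisition the
analysis emulates); at 1e7 photons the recovered tumbling time
attenuates by ~10-15%.

## Trajectory mode analysis

Superposition uses batched weighted Kabsch alignment. The leading
inertia axis is sign-corrected by the 0.5-component-jump rule, and its
component-averaged, mean-subtracted ACF is fitted with
`A exp(-tau/tau_1) + B cos(2 pi omega tau + theta)`; the near-zero
frequency start lets the cosine absorb the finite-series offset of the
ACF estimator. For replica ensembles, means and variances are pooled
across replicas (suppressing the mean-subtraction bias by 1/n) and fits
are weighted by the replica scatter. The default Brownian-rotor ensemble
is 5 x 1e5 frames at 0.1 ns: ~4% sampling error on the 81 ns decay time,
sized so the recovery check is meaningful (5 x 1e4 frames leave ~13%
seed-to-seed scatter).

Cartesian PCA diagonalizes the mass-weighted covariance of backbone +
C-beta coordinates (flexible-loop residues 208-280 excluded by default;
the elastic-network analysis removes 208-267, kept separate on purpose).
Accessible volumes use a simplified single-sphere dye on a grid: cells
within the linker length, free of protein contact (dye radius + contact
radius) and flood-fill reachable from the attachment count toward the
volume (defaults L = 20 A, width 4.5 A, R = 3.5 A, spacing 0.9 A). The
anisotropic network model builds the standard 3N x 3N Hessian with
uniform springs inside a 15 A cutoff; a connected network has exactly
six near-zero modes.

## Neutron scattering

NSE: I(q, tau) is fitted per q with C exp(-D_eff q^2 tau) using only
tau < 30 ns and I > 0.3. The rigid-body reference is the coherent first
cumulant D_eff(q) = [D_t q^2 <|F|^2> + sum_i D_r,i <|L_i|^2>] /
(q^2 <|F|^2>) with form factor F and angular lever L = sum b e^{iq.r}
(q x r), orientation-averaged over a 256-point Fibonacci sphere
(doubling the order changes results < 0.5%); the diffusion center is the
scattering-length-weighted centroid. Oligomer rescaling divides D_t by
n^(1/3) and D_r by n. Mode amplitude functions
A_k(q) = <|sum_a b_a e^{iq.r_a} (q_hat . v_ka)|^2> are combined over the
first ten modes weighted by sqrt(eigenvalue) (weighting the displacement
vectors instead is selectable); comparisons against D_eff(q) are
line-shape only.

NBS: spectra are modeled as beta_q [A0 L(Gamma_glob) + (1-A0)
L(Gamma_glob + Gamma_int)] + background with Gamma_glob = hbar D_app q^2
and the diffusion-in-a-sphere EISF A0 = [3 j1(qa)/(qa)]^2, convolved
with a Gaussian resolution analytically (Voigt profiles, exact even when
linewidths fall below the omega grid step). All q are fitted globally
for D_app, a and Gamma_int. The synthetic spectra (15 q in 0.2-1.8 1/A,
+-30 ueV at 0.25 ueV, 0.4 ueV resolution sigma, 1% noise) carry the
reference ground truths D_app = 3.27 A^2/ns, a = 1.95 A.

## What the generators do and do not emulate

The generators reproduce the statistical structure each analysis stage
assumes: confocal burst statistics, telegraph bunching and triplet
blinking, antibunching renewal, hierarchical rotational depolarization,
OU internal modes on rigid-body diffusion, and exponential/Lorentzian
neutron observables with resolution. They do not emulate photobleaching,
spectral dynamics, detector afterpulsing/afterglow, IRF shapes,
force-field-level structural detail, coherent/incoherent cross-section
mixtures, or instrument-specific reduction artifacts. Passing recovery
tests therefore demonstrates the correctness and calibration of the
analysis chain under the stated stochastic models — not robustness to
every instrumental nonideality of real data.

## Problem sizes

Defaults are sized for single-CPU runs: 30 s photon streams (~7e6
photons each, six replicas per recovery), 5 x 1e5 rotor frames, 2e4-1e5
bead-dimer frames, 15-q backscattering sets, 24-bead NSE models. These
condense the information content of much longer experiments while
keeping every recovery run in the minutes range.

## Known limitations

* The cone-wobble mapping is a small-tilt approximation; extreme cone
  amplitudes (A < 0.3) deviate from the exact restricted-diffusion
  plateau relation.
* The renewal antibunching model reproduces the dip time scale but not
  exact excited-state saturation kinetics at very high excitation rates.
* Branch (pq vs qp) asymmetry arises in this model only through
  instrumental channel delays; stationary reversible dynamics alone make
  the two branches statistically identical.
* The nsFCS bunching-time estimator is unbiased to ~1-3% under the
  default conditions, but per-stream scatter (~6-16 ns closed, ~14 ns
  open, with occasional heavier-tailed realizations) is irreducible at
  30 s per stream; six replicas are averaged and the residual scatter of
  the mean is a few ns.
* Accessible-volume values depend on the grid spacing at the few-percent
  level; spacings above the dye radius are rejected with a warning.
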