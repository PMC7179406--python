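# Methods

## Model

The water layer is a harmonic one-dimensional diatomic chain.  Each unit
cell of length l = 0.319 nm (the nearest-neighbour O···O distance in
liquid water) contains a lumped two-hydrogen element of mass
M₁ = 2.016 u and an oxygen element of mass M₂ = 15.999 u, coupled by an
intramolecular spring K₁; the oxygen couples to the next cell's H₂ element
by the hydrogen-bond spring K₂.  The chain therefore carries exactly two
phonon branches: an acoustic band [0, ω_r] in which neighbouring molecules
move in phase, and a narrow optical band [ω_q, ω_p] in which H₂ and O move
in anti-phase.  In the gap (ω_r, ω_q) and above ω_p only evanescent
solutions with complex Bloch phase exist.

All parameters come from two experimental observables: the IR absorbance
maxima of the intermolecular vibration (≈190 cm⁻¹, assigned to ω_r) and of
the OH symmetric stretch (≈3410 cm⁻¹, assigned to ω_q).  The force
constants follow from the closed-form inversion of the zone-boundary
quadratic (implemented without numeric root finding, so the round trip
band edges → springs → band edges is exact to round-off), and ω_p follows
as √[(K₁+K₂)(1/M₁+1/M₂)].  For water this gives K₁ ≈ 1223 N/m,
K₂ ≈ 9.6 N/m, ω_p ≈ 643.8 Trad/s — a 130:1 spring contrast that makes the
optical band only ~1 Trad/s wide.

Assumptions worth keeping in mind:

- One dimension, one polarization.  Bending, libration and the
  hydrogen-bond network's transverse structure are not modes of this
  chain; the extracted conductance is accordingly a lower estimate.
- Harmonic and elastic.  No phonon–phonon scattering; transport is fully
  ballistic, so conductance is independent of layer thickness for the
  clean chain.
- Reservoirs are semi-infinite periodic copies of the same diatomic cell,
  i.e. "frozen water" leads; the device layer may be disordered
  cell-by-cell.

## Parameter extraction from spectra

Peak picking uses `scipy.signal.find_peaks` on an optionally
moving-average-smoothed absorbance, with a prominence threshold expressed
as a fraction of the maximum absorbance (default 0.02) and 3-point
parabolic refinement of each grid maximum.  Mode assignment uses fixed
spectral windows (intermolecular 50–400 cm⁻¹, OH stretch 2800–3800 cm⁻¹,
each taking the most intense contained peak) so that libration and bending
features can never displace the two structural modes.  Window edges and
the threshold are configuration, not physics: the broad libration band of
real water overlaps no default window edge, but both windows are
overridable.  The anti-symmetric stretch, unresolved in liquid-phase
absorption, is reconstructed as k_a = k_a′ − k_b′ + k_b from the
isolated-molecule wavenumbers (3756, 3657 cm⁻¹), carrying the gas-phase
splitting onto the liquid symmetric-stretch position.

Wavenumber → angular frequency conversion uses ω = 2πkc.  The default
constant set uses the rounded light speed c = 3.00×10⁸ m/s, which
reproduces the reference mode table to its printed precision (e.g.
3509 cm⁻¹ → 661.4 Trad/s); the exact CODATA value is available behind
`PhysicalConstants.codata()` and shifts all frequencies by 0.07%.
Boltzmann and Planck constants are the exact SI-defining values
throughout.

## NEGF transport

The device operator is the mass-weighted dynamical matrix in the
site basis (2N scalar sites for N molecules): on-site values
(sum of attached springs)/mass, hoppings −K/√(m_a m_b), energy variable
ε = ω².  Bloch reduction of a homogeneous chain's blocks reproduces the
dispersion relation identically, which is the constraint that fixes the
construction; tests enforce it against the 2×2 Bloch-matrix eigenvalues.

Reservoir surface Green's functions are computed by Sancho–Rubio
decimation on the 2×2 cell blocks (each iteration doubles the effective
chain length; convergence threshold 10⁻¹² relative, typically <60
iterations even at small broadening).  Lead self-energies act on the two
boundary sites only, so the Caroli trace collapses to
γ_L γ_R |G_D[1, 2N]|².  The device Green's function is computed by dense
inversion up to 64 sites and by an O(N) scalar recursive sweep beyond;
both routes are exposed and cross-tested, and for N = 1 both agree with
the scalar closed-form expression.

Degenerate (monatomic) cells are allowed, in which case the chain reduces
to the textbook monatomic lead whose surface Green's function has a closed
form — used as an independent oracle for the decimation.

### Broadening

The retarded branch is selected by a positive imaginary part η added to
ε = ω², default η = 10⁻⁸·ω_p².  In-band transmission deviates from unity
linearly in η (≈2×10⁻⁵ at the default), and halving η at or below
10⁻⁷·ω_p² moves it by under 10⁻⁴.

Inside the heat-flow quadrature the broadening is scheduled as
η(ω) = η·min(1, ω/ω_p).  A constant η becomes comparable to ε itself on
the low-frequency acoustic tail (η/ε = 10⁻⁸(ω_p/ω)²), which would fake
attenuation precisely where the low-temperature conductance integral
lives; the ω-proportional schedule keeps η/ε ≤ 10⁻⁸·ω_p/ω ≪ 1 down the
whole tail, and the computed low-temperature conductance then matches the
universal one-channel quantum π²k_B²θ/3h to better than 10⁻⁶ relative at
1 K.

## Heat-flow quadrature

The Landauer integrand (ħω/2π)tr(T)(ω)[N₀ − N_{N+1}] is integrated with
adaptive Gauss–Kronrod quadrature over (0, 1.05·ω_p], split into panels at
the band edges and at 5× and 30× the thermal frequency k_Bθ/ħ so the
low-temperature tail is always resolved.  The ω → 0 limit of the integrand
is finite, (k_B/2π)Δθ·tr(T)(0⁺), and handled analytically.  Per-panel
absolute targets are anchored to the classical ballistic bound
k_B(ω_r − ω_q + ω_p)Δθ/2π, which is a strict upper bound on |J|, so the
quadrature stays effectively relative even when the quantum J is orders of
magnitude below the bound; relative tolerance 10⁻⁸, with a convergence
check at 0.1% of |J| (or 10⁻¹⁵ W absolute) that raises a named error
rather than returning a doubtful number.  Bose–Einstein occupations switch
to the Laurent series 1/x − ½ + x/12 below x = 10⁻⁶.

Conductance curves are reported against the mean reservoir temperature
with the difference split symmetrically (θ ± Δθ/2), which makes curves for
different Δθ collapse as Δθ → 0.

## Synthetic data

`synthetic_spectrum` plants Gaussian (or Lorentzian) bands at configurable
centres with additive uniform noise; the default recipe places bands at
190, 700, 1660 and 3410 cm⁻¹ with the OH stretch dominant, a 2 cm⁻¹ grid
over 20–4000 cm⁻¹ and noise at 0.5% of the stretch amplitude — a clean
caricature of a liquid-water IR spectrum.  It does not emulate baselines,
detector drift, the strongly asymmetric libration band, or Fermi
resonances, so passing peak-recovery tests demonstrates the pipeline's
correctness on well-formed spectra, not robustness to real instrument
artefacts.  `disordered_device` perturbs device cells (never the
reservoirs) with mean-one lognormal factors, guaranteeing positive masses
and springs at any disorder strength; it models compositional/mass
disorder of a liquid layer, not its dynamic structural rearrangement.

## Design choices that were genuinely open

- Masses: the model lumps both hydrogens into one element; M₁ = 2.016 u,
  M₂ = 15.999 u (configurable).  Nothing in the band-edge inversion pins
  the masses — they set the overall frequency scale of the springs but
  cancel in the band edges by construction.
- Interface springs: the reservoir–device bond defaults to the
  device-side K₂ (options: reservoir-side, mean).  For the homogeneous
  junction all choices coincide; for disordered layers the choice moves
  individual resonances but not band-level statistics.
- Mirror convention: `DeviceModel.reversed()` constructs the true
  physical mirror (element order inside each cell swapped, inter-cell
  springs re-indexed, interface springs exchanged), and reciprocity
  tr(T) = tr(T_mirror) holds to 10⁻¹⁰ at interior frequencies.  Exactly at
  a band edge the decimation is marginally convergent and the (tiny)
  trace is round-off dominated.
- Evanescent branch: gap solutions carry Re(kl) = π, above-band solutions
  Re(kl) = 0; the forward solution is fixed by |e^{ikl}| < 1 (decay) or
  positive group velocity (propagation).

## Problem sizes

Default grids are sized for interactive use: 400-point transmission
spectra with 40-point refinement windows (2% width) around each band
edge, 200-subdivision quadrature panels, ≤8-molecule disorder studies.
All are parameters; nothing in the engine caps N beyond memory, and the
recursive Green's function route is O(N) per frequency.

## Known limitations

- The conductance of the clean chain is thickness-independent (ballistic);
  diffusive or anharmonic length dependence is out of scope.
- No conversion to conductivity (W/K/m): that requires an effective
  cross-section per chain, which is a modelling statement about packing,
  not an output of the chain model itself.
- The two-band chain underestimates the conductance of real water by
  omitting bending/libration channels.
- Reservoir model is the same diatomic chain; metallic or Debye-like
  leads would change the contact self-energies.
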