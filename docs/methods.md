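# Methods

## Model

Each toy system is a two-state EVB Hamiltonian.  The diabats ε₁ and ε₂
are sums of independent harmonic wells over the reactive degrees of
freedom (well centers, force constants, and a constant offset — the
gas-phase shift α sits on state 2) plus harmonic bath modes whose
equilibrium position depends on the end state; a bath mode displaced by
Δ between states adds ½kΔ² of reorganization energy.  The adiabatic
ground state is the lowest eigenvalue of [[ε₁, H₁₂], [H₁₂, ε₂]] with a
*constant* coupling H₁₂ — the canonical EVB baseline; no gap- or
distance-dependent coupling is modelled.  The reaction coordinate is the
energy gap ε₁ − ε₂ (reactant-minus-product, so the reactant basin sits
at negative gap).  Units are fixed package-wide: kcal/mol, Å, K;
R = 1.9872×10⁻³ kcal/(mol·K); entropy is reported in e.u. = cal/(mol·K);
k_B/h = 2.0837×10¹⁰ s⁻¹K⁻¹.

Every bath mode carries one component tag: `rr` (within the reacting
fragments), `rs` (reacting-fragment–surroundings coupling) or `ss`
(internal to the surroundings).  Per-frame component energies use the
ground-state mixing weights c₁², c₂² (the coupling cross-term and the
state offsets are booked under `rr`), so the tagged pieces sum to the
ground-state energy exactly — the invariant every decomposition relies
on.

For a symmetric bath-free pair with reorganization energy λ the
diabatic crossing barrier is λ/4; with coupling it is λ/4 − H₁₂ above
the *diabatic* well energy, and the full adiabatic barrier adds
H₁₂²/λ because the coupling also depresses the ground-state minimum.

## Sampling

Windows are sampled with the BAOAB splitting of Langevin dynamics at
unit mass.  Forces on a mapping potential (1−λ)ε₁ + λε₂ are affine in
the coordinates, so propagation is exact vector arithmetic.  The
default time step is 0.15/ω_max (ω_max = √k_max); the scheme is
unstable beyond 2/ω_max and such time steps are rejected up front,
with divergence additionally detected post hoc.  Default friction is
1 per unit time — mildly underdamped for the stiffness range of the
toy systems, which decorrelates faster than the overdamped limit.
Equilibration defaults to 20% of the production length.  Per-window
seeds are the first state word of `SeedSequence([master_seed,
window_index])`, so replicate runs differ only through the master seed.

## Free-energy estimators

Adjacent-window increments use the dual-direction Zwanzig estimator
(mean of forward and backward exponential averages, both through
log-sum-exp), which cancels the leading one-sided bias at desk-scale
sampling.  The gap-resolved profile uses the classic EVB umbrella
estimator: per window and bin, Δg(X) = ΔG_m − RT ln⟨exp(−(E_g −
E_m)/RT)⟩ over the frames in the bin, combined across windows by
count-weighted averaging (no WHAM/MBAR iteration).  The profile is
shifted so the reactant minimum is zero; the transition state is the
highest interior maximum between the two outermost minima, and the
reactant minimum the lowest bin on its negative-gap side.

Bins with few frames are *masked, not valued*.  The default threshold
is 1% of the median window length (at least 10 frames): with correlated
Langevin samples, bins populated by one or two excursions of a single
window are biased low by up to ~1 RT — the count weight selects
realizations with excess visits — and no useful value can be reported
there.  The bias was diagnosed by comparison with exact references:
i.i.d. samples from the exact window Gaussians show no such deviation,
and shrinking the time step worsens rather than cures it (fewer
effective samples per frame count).  An explicitly supplied
`min_count` is honored as given.

Validation references (`reference.py`) never touch the sampler: for
equal-force-constant systems the gap is linear in the coordinates and
exactly Gaussian in any mapping ensemble, so the binned ground-state
probability reduces to a one-dimensional quadrature, and ⟨E_g⟩ in a
mapping ensemble follows from Gaussian quadratic-form moments plus a
1-D integral.  Dense grid scans provide the 1-D potential-energy
barriers.

## Arrhenius analysis

Replicate barriers are averaged per temperature (SEM = sd/√n; a single
replicate reports SEM as undefined, never 0).  ΔH‡ and ΔS‡ come from
unweighted OLS of ΔG‡/T on 1/T over the per-temperature means; the
default grid is 8 evenly spaced temperatures, 275–310 K.  Parameter
errors are a nonparametric bootstrap over replicates within each
temperature (default 2000 resamples, seeded), with resampled-mean
deviations rescaled by √(n/(n−1)) to the unbiased variance scale.
Empirical calibration on synthetic tables (σ = 0.5 kcal/mol, 100
replicates × 8 temperatures): bootstrap SE 0.447 vs 0.453 kcal/mol
analytic for ΔH‡, and joint ±2 SE coverage of 94.7% ± 0.9 over 600
repetitions — consistent with the nominal 95.4%.  Fold changes of TST
rates are reported raw and rounded to the nearest integer (the
convention used for headline k_cat comparisons); κ defaults to 1.

## Decomposition

ΔH‡ ≈ ΔU‡ (pressure–volume term dropped).  The rr and rs terms are
direct TS-minus-RS ensemble averages of the tagged energies from
dedicated endpoint ensembles, not from the FEP windows; on symmetric
toys the TS ensemble is sampled on the λ = ½ mapping potential (which
centers sampling on the crossing region) and the RS ensemble at λ = 0.
SEMs use block averaging with 10 blocks.  ΔU‡_ss is estimated
indirectly as ΔH‡ − (ΔU‡_rr + ΔU‡_rs); on toy systems the ss term is
also directly computable, and `direct_ss_check` compares the two.  The
standard error of that comparison uses the block SEM of the *total*
tagged energy (plus the ΔH‡ uncertainty): per-tag SEMs cannot be added
in quadrature because the adiabatic mixing weights correlate the
components within a frame.

## Softness statistics

Frames are superposed by reflection-guarded Kabsch least squares on the
backbone atoms (N, Cα, C, O) against an iteratively refined mean
structure (two passes: first frame, then the rebuilt mean); collinear
selections are rejected as degenerate.  Per-atom RMSF is √⟨|r − ⟨r⟩|²⟩;
residue values average over backbone atoms (Cα-only is available — the
appropriate atom set for a given comparison is not universal, so it is
switchable).  Residues are assigned to 5 Å shells by the distance of
their mean-structure Cα to the active-site center (centroid of a
user-selected atom set), computed once from the mean structure: the
shells are a static partition.  Prevalence per shell is the percentage
of residues with RMSF above the threshold (default 1.1 Å); empty shells
are flagged, not zero-valued.  Note that rigid-body fitting absorbs
6/(3·N_indep) of the displacement variance, where N_indep counts
independently moving units — visible (~5% in RMSF) when only ~20
residues move independently, negligible for larger systems.

## Synthetic data

The generators are pure functions of their arguments and seed.
Replicate barrier tables scatter Gaussian noise (default σ = 0.5
kcal/mol, matching realistic replicate SEM magnitudes) around
ΔH‡ − TΔS‡/1000 on the default 8-temperature grid.  Tagged energy
frames are i.i.d. Gaussians with distinct RS/TS means.  Trajectories
place residues (4 backbone atoms each) at prescribed radii in random
directions and displace each residue rigidly and isotropically per
frame with a radius-dependent σ; expected residue RMSF is σ√3.  The
radial σ profiles `bovine_like` and `salmon_like` are invented
sigmoids sharing a stiff core (σ = 0.18 Å), with the salmon-like
preset softening earlier and further — they emulate only the
stiff-core/soft-surface *pattern* and its between-enzyme contrast,
not any real enzyme's fluctuation spectrum.  What passing tests on
these data show is that the estimators are correct and calibrated
under the stated statistical assumptions; they say nothing about
force-field accuracy, sampling convergence of all-atom MD, or real
trypsin numbers.

## Pipeline and problem sizes

The `pipeline` driver runs, for each temperature and replicate, an
11–51-window ladder → umbrella profile → barrier, then aggregates,
fits the Arrhenius line, and decomposes ΔH‡ from endpoint ensembles at
the reference temperature; every artifact carries a hash of the full
run config, readers refuse mismatched artifacts, and reruns of the
same config are bit-identical.  Default toy sizes (3 temperatures × 5
replicates × 11 windows × 1500 production steps) were chosen so a full
smoke run plus validation suite completes in minutes on one CPU while
keeping every statistical check comfortably inside its tolerance;
window counts and lengths scale up linearly when sharper profiles are
needed (the 51 × 20000 configuration used for the quadrature
comparison bounds the profile deviation at ≲0.13 kcal/mol).

## Known limitations

- Constant H₁₂ and harmonic diabats: no anharmonicity, no
  coupling-coordinate dependence, no multi-state (>2) EVB.
- The toy TS ensemble convention (λ = ½ mapping) is exact only for
  symmetric systems; strongly exergonic systems would need a gap
  restraint instead.
- The equal-force-constant quadrature references do not cover systems
  whose force constants differ between states (the FEP increment
  reference does).
- Statistical acceptance checks pinned at 2σ thresholds pass ~86–95%
  of seed choices by construction; the calibration measurements above
  are the stronger evidence of correctness.
- No explicit solvent, periodic boundaries or replica exchange; the
  sampler is for equilibrium statistics of toy systems only.
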