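# evbcold

Tools for diagnosing enzyme **cold-adaptation** from reaction free-energy
simulations: empirical valence bond (EVB) free-energy profiles sampled by
FEP/umbrella sampling on toy systems, computational Arrhenius plots that
split the activation free energy into ΔH‡ and ΔS‡, decomposition of the
activation enthalpy into reacting-fragment and surroundings contributions,
and RMSF-based radial "surface softness" statistics.

## The scientific problem

Cold-adapted (psychrophilic) enzymes universally show a *lower activation
enthalpy* and a *more negative activation entropy* than their warm-adapted
orthologs, while the activation free energies near room temperature stay
similar.  Transition-state theory links the catalytic rate to the barrier,

    k_rxn = κ (k_B T / h) exp(−ΔG‡ / RT),      ΔG‡ = ΔH‡ − TΔS‡,

so a lower ΔH‡ makes the rate less sensitive to falling temperature.
Computationally, ΔH‡ and ΔS‡ are obtained by calculating many independent
free-energy profiles over a temperature grid and regressing ΔG‡/T on 1/T
(slope = ΔH‡, intercept = −ΔS‡).  The activation enthalpy (≈ the activation
internal energy; the pressure–volume term is negligible) further decomposes
into

    ΔU‡ = ΔU‡_rr + ΔU‡_rs + ΔU‡_ss,

contributions from within the reacting fragments (rr), their interactions
with the surroundings (rs), and interactions internal to the surroundings
(ss).  The ss term involves far too many interactions to converge directly
in an all-atom system, but it follows *indirectly* as
ΔU‡_ss = ΔH‡ − (ΔU‡_rr + ΔU‡_rs), since both terms on the right converge
well.  A low ΔU‡_ss operationalizes a "soft" environment of the active
site; structurally, softness shows up as a high prevalence of residues
with RMSF above a threshold in outer radial shells around the active site.

This package implements the full protocol at desk scale: two-state EVB
systems with harmonic diabats and tagged bath modes stand in for the
all-atom enzyme, a BAOAB Langevin sampler generates window ensembles, and
every estimator is validated against analytic or quadrature references.

## Worked example

Fit activation parameters from synthetic replicate barriers generated
around ΔH‡ = 20.4 kcal/mol, ΔS‡ = 4.667 e.u. (100 replicates at each of 8
temperatures, 275–310 K, replicate noise σ = 0.5 kcal/mol):

```python
import evbcold as ec

table = ec.synth_barriers(dH=20.4, dS=4.667, n_reps=100, sigma=0.5, seed=7)
fit = ec.fit(table, n_bootstrap=2000, seed=0)
print(f"dH = {fit.dH:.2f} +/- {fit.dH_se:.2f} kcal/mol, "
      f"dS = {fit.dS:.2f} +/- {fit.dS_se:.2f} e.u.")
# dH = 20.01 +/- 0.42 kcal/mol, dS = 3.51 +/- 1.43 e.u.
print(f"dG(300 K) = {fit.predict_dG(300.0):.2f} kcal/mol")
# dG(300 K) = 18.96 kcal/mol
```

The recovered enthalpy and entropy sit within one bootstrap standard error
of the generating values, and the fitted line reproduces the 300 K barrier.
The deterministic identities behave the same way as the published
activation-parameter tables they mirror:

```python
ec.gibbs(20.4, 1.4)                      # 19.0  (dG = dH - TdS)
ec.indirect_ss(20.4, 14.6)               # 5.8   (dU_ss = dH - dU_rr+rs)
ec.fold_change(18.2, 19.0, 300.0)        # 3.83 -> rounds to 4-fold
```

The same stages are scriptable from the shell (`evbcold synth`,
`simulate`, `profile`, `arrhenius`, `decompose`, `softness`,
`pipeline`); every stage reads and writes plain CSV/TSV so they compose
through files.  `evbcold pipeline --config cfg.yaml --outdir out/` runs
ladder sampling → umbrella profiles → barriers → Arrhenius fit →
decomposition end to end and writes a Table-style activation-parameter
report.

## Layout

- `src/evbcold/core.py` — two-state EVB energetics, energy-gap coordinate
- `src/evbcold/sampler.py` — BAOAB Langevin sampling of mapping potentials
- `src/evbcold/fep.py` — dual-direction Zwanzig FEP + umbrella binning
- `src/evbcold/arrhenius.py` — ΔH‡/ΔS‡ regression, TST rates, fold changes
- `src/evbcold/decomposition.py` — rr/rs/ss decomposition, indirect ss term
- `src/evbcold/softness.py` — superposition, RMSF, radial shell prevalence
- `src/evbcold/synthetic.py` — seeded generators for all inputs
- `src/evbcold/reference.py` — analytic/quadrature validation references
- `src/evbcold/io.py`, `cli.py`, `pipeline.py` — formats, CLI, driver

See `docs/methods.md` for the model, estimators, defaults and limitations.
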