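# Methods

## Model structure and assumptions

The default model describes inflammation in a single well-mixed tissue
volume. All concentrations are kept internally in fM and time in minutes;
interfaces accept aM–nM with exact 10³ conversion factors. TNF is reported
in pM and peptide doses in nM.

Cellular components: healthy fibroblasts (dynamic), bacteria (dynamic,
only used in the infection scenarios), and constant pools of B cells (1 fM)
and mast cells (0.1 fM). Mast-cell state is carried by a conserved receptor
pool of 10 fM split over free, FLC-loaded and CRA-crosslinked receptors;
mast cells and B cells do not proliferate. Molecular components: CRA, FLC,
TNF, MMP7, MMP8, a bacteriolytic protease and the anti-FLC peptide. All
molecular species, fibroblasts and bacteria wash out first-order.

The inflammation circuit has one dominant positive feedback: crosslinked
receptors produce TNF; TNF both kills fibroblasts and stimulates them to
secrete CRA; less fibroblast mass means less MMP8, and MMP8 is the main
*sink* for CRA (antigen neutralisation), so losing fibroblasts lets the
antigen pool, receptor crosslinking and TNF rise further. MMP7 acts
pro-inflammatory by assisting CRA clip-off from the fibroblast surface.
Because fibroblast growth is logistic (autocatalytic, capped at
F_max = 1000 fM by contact inhibition), the fibroblast-free subspace is
invariant: the "chronic" family of steady states has exactly zero
fibroblasts, which is what makes the acute→chronic transition irrevertible
under antigen withdrawal — no influx, no recovery.

TNF-mediated fibroblast killing is modelled as a Hill function of TNF with
coefficient 4 and half-point 40 pM. The cooperativity is a deliberate
choice: killing must be negligible at acute TNF levels (a few pM), fast at
chronic levels (tens of pM), and weak enough at ~10 pM that a combined
TNF-reset + fibroblast-implantation intervention can win the race against
the TNF rebound while either intervention alone loses it. A first-order
killing term cannot separate these regimes.

Dying fibroblasts are not an explicit species; the killing reaction carries
an optional pro-inflammatory CRA-release stoichiometry
(`death_release_CRA`, default 0) so that the "dying cells secrete
pro-inflammatory factors" variant can be switched on in configuration
without changing the network.

## Parameters

All kinetic constants live in `innatedyn.network_model.DEFAULT_PARAMETERS`
(units in the inline comments) and can be overridden per call or via the
CLI/YAML configuration. The constants were calibrated once, against the
model's own qualitative contract — coexistence of an acute
(fibroblasts ≥ 99% of F_max at loads ≤ 1 fM/min, low TNF) and a chronic
(zero fibroblasts, tens of pM TNF) family over a wide antigen-influx window;
an acute-branch collapse threshold inside the scanned decade (it falls at
≈ 5.7 fM/min); a down-scan that never rejoins the acute branch; relapse
under peptide alone versus cure under peptide plus fibroblast support;
cure of the chronic state only under joint TNF-reset + fibroblast
implantation; and recurrent bacterial bursts whose frequency does not
decrease with moderate protease influx while a strong influx resolves the
infection. Within those constraints, individual values were kept at
biologically sensible orders of magnitude (FLC around 1 pM, receptor K_D
100 fM, TNF turnover ~100 min, fibroblast doubling ~70 min, bacterial
doubling ~7 min, molecular washouts minutes-to-hours).

Two scales deserve comment. CRA basal washout is slow (6·10⁻⁴/min): the
persistent antigen pool is the memory that restores chronic TNF after the
peptide has cleared, setting the ~1 day relapse time together with the
peptide washout (8·10⁻³/min). And the MMP8-mediated CRA clearance at a
confluent lawn exceeds basal washout ~700-fold, which is what separates the
two branches' antigen levels (and hence TNF) by more than a decade.

## What the default model emulates, and what it does not

The model reproduces the studied *phenomenology*: bistability with branch
crossing of the TNF curves at very low load (the branches are separated by
fibroblast level, not TNF), threshold collapse, irrevertibility,
wobble-point structure (basin boundary below the saddle when probing from
the acute side; no feasible boundary at moderate load from the chronic
side), bimodal control distribution, relapse/cure therapy outcomes, and
protease-dependent infection flares. It does *not* reproduce any published
model's exact printed numbers (thresholds, plateau levels, specific
eigenvalues): those are properties of a specific rate-law/parameter file,
and the package recomputes them only when such an SBML file is supplied to
`load_sbml`. Passing the qualitative suite therefore validates mechanism
and analysis machinery, not quantitative agreement with any laboratory
system. Two known qualitative deviations: the acute branch here tolerates a
100 pM TNF spike only below ~0.1 fM/min antigen load less robustly than the
published figures suggest, and the chronic-mode control coefficient of TNF
with respect to antigen influx approaches 1 (not 2) at very low load,
because antigen enters the activation cascade linearly in this model.

## Numerical choices

- Integration: LSODA via `scipy.integrate.solve_ivp`, rtol 10⁻⁸,
  atol 10⁻¹² fM; both exposed everywhere. Intervention events restart the
  integrator; same-time events apply in input order. Endpoint invariance
  under tolerance halving is part of the test suite.
- Steady states: staged integration to quiescence (10⁴ → 10⁶ min) followed
  by a damped Newton polish. Newton steps are taken in the stoichiometric
  subspace: conserved moieties (the receptor cycle) make the full Jacobian
  singular, and unconstrained steps would drift along the conserved
  direction. Steady tolerance: max |dxᵢ/dt| < 10⁻⁹·max(xᵢ, 1 fM).
- Stability: central finite-difference Jacobian with per-species step
  10⁻⁶·max(|xᵢ|, 1 fM). The full spectrum is reported (one eigenvalue per
  dynamic species); the stability call uses the spectrum restricted to the
  stoichiometric subspace, which removes the structural zeros of conserved
  moieties. A state is *stable* only if max Re λ < −10⁻⁶/min AND a
  confirmation integration (default 10⁵ min; 2·10⁴ min inside scans) drifts
  by < 0.1% per species; positive eigenvalue OR drift ⇒ *unstable*; else
  *marginal*. Positive eigenvalues whose eigenvector is dominated by a
  species below its reporting floor (10⁻³⁰ fM; the numerically extinct
  fibroblasts of the low-load chronic states) are annotated, and
  `frozen_species_recheck` re-classifies with that species clamped.
- Control coefficients: central log-differences on per-reaction activity
  multipliers, default relative step 10⁻², carry-state Newton re-solve.
  Every profile coefficient carries a Richardson check at half the step and
  the step is refined (down to 5·10⁻⁴) until two step sizes agree to 10⁻³;
  a Newton failure or a >10× state jump under perturbation is reported as a
  branch jump (the expected near-threshold singularity) and retried at a
  smaller step, or recorded as a divergence marker in scans. Coefficients of
  processes involving species below floor are flagged non-computable and
  excluded from the summation totals.
- Scans: carry-state protocol throughout (each solve seeded from the
  previous point); branch labels come from the state classifier
  (fibroblasts ≥ 50% F_max ⇒ acute; < 1 fM ⇒ chronic; else TNF > 10 pM ⇒
  chronic; else indeterminate), never from scan direction. Threshold
  bisection tolerance 0.01 fM/min; wobble bisection reports the final
  bracket (relative width 0.5%) because the boundary location depends
  mildly on the relaxation protocol. Unstable-state searches seed each grid
  value by relaxing the remaining subsystem with the scanned species
  clamped, then release it to the full Newton — plain seeding from a stable
  state's composition rarely converges to the saddle.
- Therapy classification: *cured* means the final steady state is on the
  acute branch (fibroblast-primary call; the TNF levels of the two branches
  cross at low load, so a fixed TNF cutoff cannot separate them at every
  antigen load). A checkpoint is *stable* when the steady state found from
  it is stable and the checkpoint TNF is within 50% of it — i.e. the system
  has actually arrived, not merely paused mid-transient. A bacterial burst
  is a local maximum above 10⁻⁴ fM exceeding 10× the preceding minimum.
- The infection scenarios run with zero CRA influx (bacterial antigen
  shedding is then the sole driver of mast-cell activation); the
  bistability/control analyses run with bacteria removed from the
  computation (frozen at zero) and a constant CRA influx instead, via
  `build_inflammation_model` — otherwise the invariant zero-bacteria
  direction adds its spurious positive eigenvalue to every stability call.

## Problem sizes

The default analyses use 12 dynamic species and 30 tagged processes. Branch
scans in the test and acceptance suites use 3–14 points per direction over
v_CRA ∈ [10⁻³, 30] fM/min; control profiles solve ≈ 4 perturbed steady
states per process; wobble bisections use ~15–25 relaxations of 3·10³–5·10⁴
min; infection sweeps integrate 1.2·10⁴ min per influx value. These sizes
keep the full verification run in minutes on one core while leaving every
qualitative conclusion insensitive to further refinement (the suite checks
tolerance- and step-halving invariance explicitly).

## SBML import

The reader supports the subset needed for single-compartment kinetic
models: species with initial concentrations, boundary/constant species,
global and local (reaction-namespaced) parameters, and kinetic laws in
content MathML (arithmetic, powers, roots, exp/ln/log). Events, algebraic /
assignment / rate rules, function definitions and multiple compartments
raise explicit unsupported-construct errors. Values are taken at the file's
face value on the package's fM/min scale; files on another scale must be
converted first. Process tags default to reaction ids and can be remapped
with an explicit table for control-analysis labelling.

## Known limitations

No adaptive immunity, no stochasticity, no spatial structure, no delay
terms, no limit-cycle continuation (eigenvalue sign reporting only), no
pharmacokinetics beyond first-order peptide washout, and no claim of
exhaustiveness in steady-state searches (up to three states per condition
are sought, as in the underlying two-mode phenomenology). The therapy and
infection conclusions are statements about this model family, not about
patients.
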