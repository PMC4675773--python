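# Methods

## The mechanical model

The lung is `n` alveolar compartments in parallel behind a single proximal
airway node.  Compartment `i` has

* a threshold opening pressure `TOP_i` (cmH₂O): a collapsed unit admits no
  flow until the airway pressure reaches `TOP_i`;
* a stiffness coefficient `S_i` (cmH₂O/ml²) giving the quadratic recoil
  `P_i = S_i·V_i² + P_ext,i`, where `V_i` is volume above the compartment's
  resting volume — the functional form follows from the printed units of
  `S_i` and yields the concave-down volume–pressure curve of a stiff,
  recruitable unit;
* an extrinsic pressure `P_ext,i` (cmH₂O) compressing the unit from
  surrounding tissue and oedema;
* a bronchiolar resistance `R_aw,i` (cmH₂O·s/ml), uniform by default.

Parameters live in the physiological box TOP ∈ (5, 60), S ∈ (0.005, 0.5),
P_ext ∈ (−20, 28.8), nominal (30, 0.05, 28.8).

Breaths are volume-controlled: a constant inspiratory flow
`F_insp = V_T·RR/(60·DC)` for the inspiratory fraction `DC` of each cycle,
then passive expiration against PEEP (default 5 cmH₂O, always stated
explicitly where results depend on it).  Each 5 ms slice solves the shared
airway pressure so the open compartments jointly take the commanded flow,
recruits collapsed units whose TOP is reached, moves gas through each
`R_aw,i`, and collapses any unit whose volume above resting reaches zero.
A unit with `P_ext > PEEP` therefore empties and derecruits during
expiration and re-opens only if the next inspiration drives the airway
pressure past its TOP — tidal recruitment, air trapping at short
expiratory times, and persistent collapse all emerge from this rule set.

Numerical choices: explicit slices of `dt` = 5 ms (halving `dt` changes
end-inspiratory volume by < 0.1 %, verified over random parameter draws);
fractional final slices make the delivered volume exact; ties in
recruitment are resolved by compartment index; airway pressure above the
120 cmH₂O safety cap is reported, never silently clipped; non-finite
states abort with the offending compartment named.

### Reduced lungs

The parameter tables describe 100 alveolar units.  An `n`-compartment lung
(`n` < 100) represents those units lumped into `n` parallel groups:
pressures are intensive and unchanged, the lumped stiffness is
`S·(n/100)²`, resistances scale as `n`, and the 2,000 ml total resting
volume is shared uniformly.  Aggregate mechanics (compliance, FRC, airway
pressures) are exactly preserved, so the reduced lungs used in the test
suite exercise the same physiology at a fraction of the cost.  Stiffness
is kept on the table scale for export and round-trips.

## Gas exchange

Inspired gas is humidified, `PIO₂ = FiO₂·(760 − 47)` mmHg.  The first
`V_Danat/V_T` fraction of every compartment's tidal inflow re-breathes the
mixed expirate held in the shared anatomical dead space (160 ml, the
conventional 70 kg value); the rest is fresh.  End-capillary blood
equilibrates fully with alveolar tensions.  Unventilated or collapsed
units pass mixed-venous blood unchanged; arterial blood is the
perfusion-weighted mixture, and the reported shunt fraction is the venous
admixture `(Cc'O₂ − CaO₂)/(Cc'O₂ − CvO₂)` — with full equilibration this
coincides with the perfusion fraction of unventilated units, so shunt is
fully emergent from the compartment parameters.  Perfusion fractions are
static, `q_i ∝ 1/R_vasc,i` (no hypoxic vasoconstriction), with a mildly
heterogeneous seeded lognormal spread (σ = 0.3) scaled so the parallel
total equals the configured PVR.  The heterogeneity is physiological and
also lets a reduced lung realise shunt fractions between the coarse
multiples of `1/n`.

Species flux uses the standard conversion `V̇ = V̇A·P/0.863` between
alveolar ventilation (l/min BTPS), tension (mmHg) and STPD flux (ml/min).
Mixed venous composition is closed by the Fick balance with
under-relaxation 0.5 to a fixed point (tolerance 0.05 mmHg on the venous
tensions, ≤ 200 iterations); per-compartment alveolar tensions are the
unique roots of the monotone gas-side/blood-side balance, found by
bisection.  A configuration whose metabolic demand exhausts the venous O₂
content raises an explicit infeasibility error.

Two independent routes compute the same steady state — the algebraic
bisection solver used everywhere, and an explicit time-sliced integration
of the alveolar stores (dilution through a well-mixed dead-space buffer,
flux-limited capillary exchange, slowly relaxing venous pool).  Their
agreement on small lungs is a standing cross-check in the test suite.

### Dissociation curves (frozen)

* O₂: `C = 1.34·(Hb/10)·S(P) + 0.003·P` ml/dl with the Hill saturation
  `S(P) = (P/26.6)^2.7 / (1 + (P/26.6)^2.7)` — P50 26.6 mmHg, Hill
  coefficient 2.7.
* CO₂ (whole blood, Douglas-style single-term fit):
  `C = 48·(P/40)^0.57` ml/dl — anchored at 48 ml/dl / 40 mmHg with an
  in-vivo slope of ≈ 0.68 ml/dl/mmHg there; exactly invertible.

No pH, temperature or 2,3-DPG shifts.  Tests pin these curves themselves,
not external physiology tables.

### Dead space

Bohr–Enghoff: `V_Dphys = V_T·(PaCO₂ − PĒCO₂)/PaCO₂`, with PĒCO₂ the
volume-weighted mixed-expired CO₂ tension (dead-space gas exhaled first is
fresh and CO₂-free; alveolar gas follows, ventilation-weighted).  On a
homogeneous shunt-free lung this recovers the anatomical value.  The
arterial-based (Enghoff) form is used because the strategies control
PaCO₂.

## Configuring metabolism from a dataset

The matched outputs are PaO₂, PvO₂, PvCO₂ and shunt; barometric pressure
760 mmHg; ideal body weight 70 kg (baseline V_T = 560 ml, strategy-3
bounds 175–560 ml).  Whole-body V̇O₂ and V̇CO₂ are not free dials:

* **V̇O₂** follows from the Fick principle applied to the dataset's own
  arterial and venous tensions, `V̇O₂ = 10·CO·(C(PaO₂) − C(PvO₂))`.  The
  Fick closure makes PvO₂ a deterministic function of PaO₂ given V̇O₂, so
  any other choice would place the venous target out of reach of every
  compartment parameter.
* **V̇CO₂** is 0.8·V̇O₂ (standard respiratory quotient), capped at 97 % of
  the largest value for which the venous CO₂ target remains attainable:
  the lowest arterial CO₂ content any parameter set can produce at the
  configured ventilation is
  `C(0.863·V̇CO₂/V̇A) + f/(1−f)·V̇CO₂/(10·CO)` (ideally ventilated aerated
  pool plus the target shunt fraction `f` of venous admixture), and the
  target implies `C(PvCO₂) − V̇CO₂/(10·CO)`; the cap sits at their
  crossing, with 3 % slack for ventilation–perfusion spread inside the
  aerated pool.

Defaults of 250/200 ml/min remain for workflows without measured targets
(e.g. the synthetic generator).

## Matching

A seeded generational GA searches the 3n-dimensional box: tournament
selection (size 3), blend crossover (rate 0.9, per-gene extrapolation
±0.25), per-gene Gaussian mutation (probability 0.15, σ = 5 % of each
range annealed by 0.995 per generation), elitism 2, population 60,
termination at E_T below threshold.  Candidates are clipped at the bounds.
The initial population spans injured fractions 0–0.6 (high-TOP,
high-P_ext units versus aerated units with log-spread stiffness), seeding
the clinically relevant region.  Each evaluation simulates the candidate
to steady state at the dataset's RR/DC with V_T = 8 ml/kg — breaths until
the end-expiratory volume settles, then the algebraic gas solve — so one
evaluation costs milliseconds rather than twenty simulated minutes.

With 3n parameters against four outputs the problem is deliberately
non-identifiable; the contract is output recovery (E_T), never parameter
recovery.  Dynamic compliance and PVR are configuration cross-checks
(warn at > 15 % deviation), not cost terms.  Matching a generated
patient's own observations recovers its outputs to E_T ≤ 0.01.

One caveat the package computes rather than hides: the mildest packaged
dataset (FiO₂ 0.8) pins PaO₂, PvO₂ and shunt into a triple that no
parameter set can satisfy simultaneously under the frozen O₂ curve — the
shunt equation demands a ventilated end-capillary content slightly above
what `PIO₂ − PACO₂` can provide at FiO₂ 0.8 — so its fit settles at
E_T ≈ 0.05 with the shunt ~20 % under-estimated, whereas the other two
datasets fit to E_T ≤ 0.002.  (The same dataset's published model fit also
shows the largest single-output deviation, on PvCO₂.)  The acceptance
script reports the fitted values as computed.

## Strategies

All strategies step RR through (16, 24, 32, 40, 48) b/min, nominally 20
minutes per step, executed without resetting the lung state; step
summaries use each step's own end-expiratory volume as FRC for strain,
and peak alveolar pressure is the mean end-inspiratory recoil pressure of
the quartile (⌈n/4⌉) of compartments with the highest pressures.

* **Strategy 1**: `V_T = M_Valv/RR + V_Danat` with `M_Valv` = 5,400
  ml/min, `V_Danat` = 160 ml, DC = 0.33.
* **Strategy 2**: the same volumes; DC from `V_T·RR/(60·F_insp)` with
  `F_insp` = 337 ml/s (a configured constant; it is not derivable from
  the baseline settings).  A DC ≥ 1 is reported as infeasible.
  At RR = 16 the two published settings (F_insp 404.04 ml/s, DC 0.40) are
  not consistent with the flow equation at V_T = 497.5 (which gives
  402.02 ml/s and 0.39); the implementation follows the equations and
  documents the discrepancy here.
* **Strategy 3**: per step, the V_T ∈ [2.5, 8] ml/kg returning the
  steady-state PaCO₂ to its baseline value.  Because PaCO₂ is strictly
  decreasing in V_T at fixed RR (a tested invariant), the five-variable
  search decomposes into five sequential 1-D problems solved by bisection
  from the frozen start-of-step state (bracket tolerance 0.5 ml); an
  exhaustive 1 ml grid search is retained as an oracle and agrees within
  1 ml.  Targets unreachable inside the bounds return the clipped bound
  with the residual flagged; candidate volumes so small that the
  circulation cannot close are treated as unbounded PaCO₂.  DC is held at
  0.33 (the source material does not state strategy 3's duty cycle).
* **Adaptive strategy 1**: before each rate increment the physiological
  dead space of the current steady state replaces `V_Danat`.  The
  maintained constant is `M_Valv = RR·(V_T − V_Dphys)` measured at
  baseline: carrying the nominal 5,400 ml/min (which already exceeds the
  baseline's true alveolar ventilation) together with the corrected dead
  space would systematically over-ventilate and perform *worse* than
  strategy 1.  With an externally supplied measurement and an explicit
  `m_valv` the variant reduces exactly to strategy 1 when
  `V_Dphys ≡ V_Danat`.

The "20-minute" steps use the accelerated settling scheme above;
`mechanics.simulate_breaths_dense` provides full slice-level transients
when trajectories are needed.

## Synthetic patients

The generator draws ground-truth lungs from two sub-populations: an
injured fraction (TOP ~ U(30, 55), P_ext ~ U(18, 28.8), S ~ U(0.05, 0.3))
that stays collapsed under baseline ventilation, and aerated units
(TOP ~ U(6, 18), P_ext ~ U(−8, 4), log-uniform S) providing
ventilation–perfusion spread.  Severity recipes — injured fraction
0.18/0.25/0.42 at FiO₂ 0.30/0.60/0.90 — were calibrated once against the
simulator so the simulated P/F ratio lands in the Berlin mild/moderate/
severe band, and are frozen; generation is reproducible from the seed and
every draw respects the parameter box.  Circulation defaults: CO 6 l/min,
Hb 120 g/l, V̇O₂/V̇CO₂ 250/200 ml/min.

What the generator does *not* emulate: breath-to-breath physiological
noise, measurement error on the observed gases, pendelluft or airway-tree
heterogeneity, haemodynamic pulsatility, pH chemistry.  Tests passing on
these patients therefore demonstrate the internal consistency of the
pipeline (matching recovers outputs; strategies behave as the model
predicts), not agreement with any individual real patient.

## Known limitations

* The whole-lung picture is parallel compartments behind one airway node —
  no inter-compartment gas redistribution, no inertance, no spontaneous
  effort.
* Dissociation curves are fixed standard forms; acid–base state is out of
  scope, so PaCO₂-driven pH effects on the curves are absent.
* Shunt and admixture follow entirely from collapsed/unventilated
  perfusion; there is no extrapulmonary (anatomic) shunt channel.
* Default problem sizes in the tests use 10-compartment reduced lungs;
  the 100-compartment configuration runs behind the same API (an
  evaluation costs ~25 ms instead of ~3 ms).
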