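# Methods

Model equations, shipped constants, generator conventions and numerical
choices of `melferm`. Everything stated here is implemented and tested in
the package; no empirical claims are made beyond what the shipped code
computes.

## Two-phase process model

The fermentation is modelled as two decoupled phases chained by a hand-over.

### Growth phase

State: broth volume V (L), dry biomass c_x, glucose c_Gluc and sodium
nitrate c_NaNO3 (all g/L). Specific growth rate (dual-substrate Monod,
minimum operator for two non-complementary substrates):

```
mu = mu_max * min( c_Gluc/(K_Gluc + c_Gluc), c_NaNO3/(K_NaNO3 + c_NaNO3) )
```

Balances with volumetric medium feed F (L/h), dilution rate D = F/V:

```
dV/dt       = F
dc_x/dt     = (mu - D) * c_x
dc_Gluc/dt  = D*(c_Gluc,feed  - c_Gluc)  - (mu/Y_X/Gluc)  * c_x
dc_NaNO3/dt = D*(c_NaNO3,feed - c_NaNO3) - (mu/Y_X/NaNO3) * c_x
```

The optional exponential feed law is open-loop:

```
F(t) = (V0*c_x0*mu_set) / (Y_X/S,feed * (c_Gluc,feed - c_Gluc,broth))
       * exp(mu_set * (t - t_start)),       t in [t_start, t_end]
```

with c_Gluc,broth held at a constant assumed value (default 0 g/L). When a
scenario's total delivered feed is known (e.g. from a balance reading), the
profile can be rescaled by a constant factor so its window integral matches
that total (`delivered_volume_L`); the exponential shape is preserved.

### Production phase

At the configured end of growth the biomass concentration is frozen as the
catalytic biomass c_x,growth. State: V, lipid-free biomass c_x,free (which
starts at c_x,growth), inclusion biomass c_x,incl, oil c_Oil, free fatty
acids c_FA, product c_MEL. Specific rates:

```
q_hyd  = q_max,hyd * c_Oil / (c_Oil + K_m,hyd * (1 + c_FA/K_i,hyd))
q_MEL  = q_max,MEL * c_FA / (c_FA + K_m,MEL)
q_incl = q_max,incl * c_FA / (c_FA + K_m,incl)
```

Balances (continuous oil feed F with oil concentration c_Oil,feed):

```
dc_Oil/dt    = D*(c_Oil,feed - c_Oil) - q_hyd * c_x,growth
dc_FA/dt     = -D*c_FA + Y_FA/Oil * q_hyd * c_x,growth
               - Y_FA/MEL * q_MEL * c_x,growth
               - Y_FA/incl * q_incl * c_x,free
dc_MEL/dt    = -D*c_MEL + q_MEL * c_x,growth
dc_x,incl/dt = -D*c_x,incl + q_incl * c_x,free
dc_x,free/dt = -D*c_x,free - Y_X,free/incl * q_incl * c_x,free
```

Lipid inclusion converts lipid-free biomass into inclusion biomass, so the
lipid-free pool carries a negative reaction term; the measurable dry
biomass is c_x,free + c_x,incl.

**Inclusion-drain coupling.** By default the fatty-acid drain into
inclusions is scaled by the *lipid-free* biomass, making it exactly
Y_FA/incl times the inclusion-biomass formation flux of the c_x,incl
balance: the inclusion bookkeeping closes, and the drain shuts down as the
lipid-free pool is exhausted. The alternative convention — scaling the
drain by the catalytic biomass like the other fluxes, so it persists at
full strength for the whole production phase — is available as
`inclusion_by_free_biomass=False` but drains fatty-acid mass without a
matching sink and depresses late-process MEL formation markedly. A second
switch (`scale_by_total_biomass=True`) scales all reaction fluxes by the
current total biomass instead of the frozen catalytic biomass, for
sensitivity analyses.

**Oil boluses** are instantaneous, perfectly mixed additions: every
concentration is diluted by V_old/V_new and the oil pool gains
(added mass)/V_new. Leftover glucose and nitrate are passively diluted in
the production phase (no reactions touch them).

## Shipped kinetic constants

Growth (`GrowthParameters`):

| constant | value | units |
|---|---|---|
| mu_max | 0.11 | 1/h |
| K_Gluc | 1.0 | g/L |
| K_NaNO3 | 0.01 | g/L |
| Y_X/Gluc | 0.17 | g/g |
| Y_X/NaNO3 | 1.7 | g/g |

Maximum specific consumption rates are derived, not stored:
q_max,Gluc = mu_max/Y_X/Gluc ≈ 0.647 g/g/h and q_max,NaNO3 ≈ 0.065 g/g/h.

Production (`ProductionParameters`):

| constant | value | units |
|---|---|---|
| q_max,hyd | 0.1 | g oil/g/h |
| K_m,hyd | 5.0 | g/L |
| K_i,hyd | 20.0 | g/L |
| Y_FA/Oil | 0.957 | g/g |
| q_max,MEL | 0.02 | g MEL/g/h |
| K_m,MEL | 5.0 | g/L |
| Y_FA/MEL | 1.667 | g/g |
| q_max,incl | 0.07 | g FA/g/h |
| K_m,incl | 1.0 | g/L |
| Y_X,free/incl | 0.203 | g/g |
| Y_FA/incl | 1.128 | g/g |

Y_FA/Oil equals the triolein hydrolysis stoichiometry
3·M(oleic acid)/M(triolein) = 0.957 computed in `melferm.stoichiometry`.

Feed defaults (`ExponentialFeedSpec`): 300 g/L glucose, 30 g/L NaNO3,
Y_X/S,feed = 0.25 g/g, feed density 1.15 g/mL.

## Process analytics

- Windowed rates and yields by linear regression (two-point difference
  quotients as a method option). Specific rates q_S divide the volumetric
  rate by the *logarithmic-mean* biomass of the window, which makes
  q_S·Y_X/S = µ hold exactly on noiseless exponential windows.
- Off-gas balance from dry-gas mole fractions: the molar gas flow is
  Q_air·p/(R·T) (numerically mmol/h with Q_air in L/h), the outlet flow
  follows from the inert-gas (N₂) balance, and

  ```
  OUR = n/V * (y_O2,in  - (inert_in/inert_out) * y_O2,out )   [mmol/L/h]
  CER = n/V * ((inert_in/inert_out) * y_CO2,out - y_CO2,in)
  RQ  = CER/OUR
  ```

  `outlet_fractions_from_rates` is the exact algebraic inverse and is used
  to synthesize off-gas observations.
- Extract purity X_MEL = c_MEL/(c_Oil + c_FA + c_MEL).
- Conversions: 0.35 g/L dry biomass per OD625 unit; OD625 per gain-5
  backscatter unit = 1/0.14. Feed-solution bookkeeping converts fed mass
  to substrate mass at a stated density; the default 1 g/mL reproduces the
  convention under which 460 g of 300 g/L feed delivers 138 g glucose.

## Stoichiometry

Atomic masses C 12.011, H 1.008, N 14.007, O 15.999, Na 22.990. Average
dry-biomass compositions (g/100 g, remainder treated as oxygen): growth
phase C 48.5/H 7.1/N 6.2, production phase C 62.2/H 9.2/N 1.3 (nitrogen
diluted by lipid accumulation). The nitrogen balance gives the biomass
ceiling of the mineral medium (3 g/L NaNO3 → 0.494 g/L N → ≈8 g/L
lipid-free biomass at 6.2% N); the carbon balance budgets glucose carbon
into biomass.

## Synthetic-data generator

`generate_observations` samples a simulated trajectory like a real
fermentation:

- offline species (OD, dry biomass, glucose, nitrate, oil, FA, MEL) every
  8 h by default, snapped to the simulation grid; multiplicative lognormal
  noise (default relative SD 5%) plus an optional half-normal detection
  floor per species, so observations never go negative;
- off-gas records every 0.2 h: outlet mole fractions constructed by exactly
  inverting the inert-gas balance from model-implied OUR/CER, with absolute
  Gaussian noise (default SD 2·10⁻⁴).

Generator conventions (not model claims): aeration 0.7 volumes of air per
liquid volume per minute at 101325 Pa / 303.15 K; growth-phase oxygen
uptake q_O2 = µ/Y_X/O2 with Y_X/O2 chosen so q_O2 = 4.3 mmol/g/h at µ_max,
RQ 1.4; production-phase uptake a constant 1.5 mmol/g/h on the catalytic
biomass, RQ 0.52. With all noise set to zero the table lies exactly on the
trajectory; tables are deterministic for a fixed seed.

The scenario library reconstructs six processes: B1/B2 (batch growth in
4 L, oil boluses from 48 h) and FB1–FB4 (batch then exponential feed from
3 L, oil boluses and/or continuous oil feeds). Quantities the process
descriptions leave open (some feed-spec biomass assumptions, fed-batch
start volumes) are reconstructed and flagged in the builder; the fed-batch
feed totals are pinned to the recorded delivered masses via
`delivered_volume_L`.

## Parameter estimation

- `fit_yields_direct`: µ_max from a log-linear regression on an exponential
  window; yields from substrate/biomass changes; maximum consumption rates
  from a regression of windowed consumption rates on biomass.
- `fit_model` (wrapped by `MELProcessModel.fit`): weighted least squares of
  the forward simulation against observed species, each scaled by its
  observed maximum. Nelder–Mead in log-parameter space with deterministic
  seeded multi-starts; approximate standard errors from a finite-difference
  Gauss–Newton Jacobian at the optimum. Identifiability can be inspected
  with one-parameter objective profiles.

## Numerical choices

- Explicit Euler with default steps 0.05 h (growth) and 0.2 h (production);
  the step sizes are part of the model definition, and the test suite
  verifies first-order convergence and agreement with an adaptive
  reference solution within 0.5% at a tenth of the default steps.
- A non-negativity clamp absorbs the scheme's slight undershoot at
  substrate exhaustion; undershoots beyond 10⁻⁶ are logged.
- Oil boluses are applied at the nearest grid time at or before the event
  time (scenario event times lie on the grid).
- The feed profile is integrated by the same first-order scheme, so the
  delivered volume carries an O(µ_set·dt) quadrature bias (≈0.2% for the
  shipped scenarios).

## Limitations

- The production model is driven by the frozen catalytic biomass; it does
  not describe lipase dynamics, oxygen limitation or temperature effects.
- The minimum-operator growth model switches limiting substrates sharply;
  no maintenance or death terms are included.
- The feed law is open-loop: broth glucose in its denominator is an
  assumed constant, not the simulated value.
- Off-gas synthesis uses fixed respiratory quotients per phase rather than
  an elemental electron balance.
- Measured scenario descriptions leave some initial conditions open; the
  shipped reconstructions state their assumptions but remain
  reconstructions.
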