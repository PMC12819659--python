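# Methods

## Model

MG1113 is an IgG4 monoclonal antibody against tissue factor pathway
inhibitor (TFPI).  TFPI exists in two pools with very different kinetics: a
soluble α-isoform circulating in plasma (sTFPI) and a membrane-associated
pool on endothelium and platelets (mTFPI).  Binding to both pools makes the
antibody's clearance dose-dependent, so the pharmacokinetics are described
with a full two-target target-mediated drug disposition (TMDD) model rather
than a linear compartment model.

The model has eight states; concentrations are in nM, amounts in nmol,
time in days:

| state    | meaning                                         | unit |
|----------|-------------------------------------------------|------|
| A_depot  | drug amount at the s.c. injection site          | nmol |
| A_transit| drug amount in the absorption transit state     | nmol |
| C2       | free drug in the central compartment            | nM   |
| C3       | free drug in the peripheral compartment         | nM   |
| Cs       | free soluble TFPI (central)                     | nM   |
| Cm       | free membrane TFPI (central)                    | nM   |
| C2_CS    | drug–sTFPI complex                              | nM   |
| C2_CM    | drug–mTFPI complex                              | nM   |

Structural features:

- **Absorption.** A subcutaneous dose enters a depot that empties through a
  single transit state into the central compartment (rate `k01`, then
  `k12`), with a parallel direct path (`k02`) and a pre-systemic loss path
  (`k_loss`).  An i.v. bolus is placed directly into `C2`.
- **Disposition.** Two-compartment distribution (`V2`, `V3`, distributional
  clearance `CL_D`) plus linear elimination of free drug (`k_el_MG1113`).
- **Target turnover.** Each target pool has zero-order synthesis and
  first-order degradation (`k_deg_s`, `k_deg_m`); synthesis rates are
  derived from the baselines at steady state (`k_syn = k_deg × baseline`),
  so the drug-free system is exactly stationary.
- **Binding.** Second-order association `k_on` shared by both targets with
  `k_off = k_on × KD`; binding occurs in the central compartment only.
  Complexes are eliminated with their own first-order rates (`k_el_CS`,
  `k_el_CM`), which is what produces the post-suppression rebound of free
  sTFPI: while complex outlives free drug, target synthesized during
  suppression accumulates in complex and is returned by dissociation.

Parameter values are the rank-1 cynomolgus-monkey estimates shipped as
`tfpi_tmdd.parameters.monkey_rank1()`.

## Interspecies scaling

Monkey parameters are scaled by body weight with fixed allometric
exponents: 0.75 for distributional clearance, 1.0 for volumes, and −0.25
for all nine first-order rate constants.  `KD` and `k_on` are
species-conserved (antigen affinity does not scale with size).  The
soluble-TFPI baseline is taken from literature values per species (rabbit
1.114 nM, human 2.3 nM) and the membrane baseline is set by the monkey
membrane/soluble ratio (12.04/0.9456 ≈ 12.73).

## Fitting

Fifteen parameters are estimated (all except `BW` and `KD`, which are
fixed) from group-mean concentration–time data of drug and soluble target
across six monkey dose groups simultaneously.  The objective is the sum of
squared base-10 log residuals, with non-positive predictions floored at
1e-12 nM.

- **Multi-start.** Starting points are sampled log10-uniformly within the
  published search ranges.  Each start is refined by a damped Gauss–Newton
  method on log10-parameters: finite-difference Jacobian (step 1e-4),
  rank-revealing least-squares step (`rcond` 1e-10), step-norm cap of 4
  decades, step-halving line search, and termination on stalled improvement.
- **Stacked integration.** All dose groups share one parameter set, so each
  objective evaluation integrates a single block-diagonal 48-state system
  (one stiff solve instead of six).
- **Acceptance of terminal sets.** Terminal SSRs are sorted; the accepted
  cluster is cut at the elbow of the min-max-normalized log10-SSR curve
  (maximum second difference; values floored three decades below the best
  SSR so solver jitter among near-perfect fits is not an elbow), followed
  by one-sided Grubbs outlier pruning at α = 0.05.
- **Identifiability.** For each parameter, an approximate profile likelihood
  is built by binning the log10 values over all terminal sets and taking
  the minimum SSR per bin.  A parameter is flagged non-identifiable if the
  profile is flat (range < 3.84, a χ²(1, 0.95) heuristic) over at least two
  decades, or if it has two or more separated minima below the acceptance
  threshold.  On synthetic monkey data, `k02` (direct absorption bypass)
  and `k_loss` (pre-systemic loss) are non-identifiable with near-zero
  estimates, consistent with the original analysis; i.v.-only information
  cannot inform them and the s.c. data support a single dominant absorption
  path.

## Synthetic data

The animal concentration data behind the published model are not publicly
deposited, so all pipeline stages run on synthetic tables simulated from a
known truth parameter set under the published study designs (monkey
i.v./s.c. 17.2/34.4/68.8 nmol/kg at 3.5 kg; rabbit i.v. 2.75/17.2/34.4 and
s.c. 17.2/34.4/68.8/137.6 nmol/kg at 2.5 kg with the printed sampling
schedules).  The monkey sampling schedule was never printed; the surrogate
used here is the rabbit schedule augmented with intensive early sampling
(5, 15, 30, 60 min) and extended to 42 days so the soluble-target rebound
window is observed.  Realism choices:

- multiplicative log-normal residual error, median-preserving
  (`exp(σz)` with `σ² = ln(1 + CV²)`), default CV 15% (configurable; the
  true ELISA error magnitude is unknown, recovery was exercised at CV 0,
  0.15 and 0.3);
- lower-limit-of-quantification censoring: values below the LLOQ are
  flagged and carry no concentration, mimicking below-calibration ELISA
  readouts treated as missing;
- n = 3 animals per group by default; fitting consumes the per-group
  arithmetic mean with fully censored points remaining censored.

## Numerical choices

- Stiff integration by LSODA (`scipy.integrate.odeint`) with an analytic
  Jacobian; binding at `k_on = 28.5 /nM/day` against `k_deg_s = 75.5 /day`
  makes the system stiff after large doses.
- Tolerances: rtol 1e-8 / atol 1e-10 for reporting simulations, relaxed to
  rtol 1e-5 / atol 1e-8 inside the fitting objective (the log-residual
  objective does not resolve below that, and it is ~2× faster); the
  objective also caps the internal step count so hopeless parameter regions
  fail fast instead of stalling the optimizer.
- Integration is restarted at every dose event (bolus discontinuities are
  never stepped over).
- Suppression duration is computed from linearly interpolated threshold
  crossings, summed over all intervals below threshold.
- numba-compiled right-hand sides when numba is importable, with a pure
  NumPy fallback.

## Limitations

- Binding is restricted to the central compartment; peripheral target is
  not modelled.
- A single `k_on`/`KD` is shared by both TFPI pools.
- The monkey sampling schedule and residual-error magnitude are surrogates
  (see above), so recovered-parameter uncertainty from the synthetic study
  should not be read as the uncertainty of the published animal fits.
- The depot → transit → central absorption chain is structurally symmetric
  in `k01` and `k12` (classic absorption "flip-flop"): swapping the two
  rates gives an identical fit, and on noisy data the accepted cluster can
  mix the two labelings.  Their sum/profile, not the individual labels,
  is what the data determine.
- Allometric exponents are fixed, not estimated; human predictions inherit
  the usual caveats of monkey-to-human extrapolation for target turnover.
- No inter-animal variability in truth parameters and no assay-calibration
  simulation; noise is i.i.d. per observation.
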