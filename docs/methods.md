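# Methods

## Model

`jointmsm` models the disease-activity and damage processes of the 28 hand
joints of an arthritis patient jointly, at the individual-joint level, from
panel data: each joint is assessed only at clinic visits, as a binary
activity indicator (swollen/painful or not) and a binary, irreversible
damage indicator.

Two state spaces are supported.

**Six-state model (transition intensities).** Movers follow a four-state
chain over (activity x damage) — inactive/undamaged (1), active/undamaged
(2), inactive/damaged (3), active/damaged (4) — with transitions 1<->2,
1->3, 2->4, 3<->4; damage is absorbing as a level (no damaged state can
reach an undamaged one), and the activity process continues after damage.
Stayers — a latent subpopulation at no risk of damage — follow a two-state
activity chain (states 5, 6). The intensities are log-linear:

    lambda_12 = lambda0_AbarA * exp(beta_AbarA' z + u)
    lambda_21 = lambda0_AAbar * exp(beta_AAbar' z + alpha u)
    lambda_13 = lambda0_DbarD * exp(beta_DbarD' z + v)
    lambda_34 = lambda_12 * exp(betaDamaged_AbarA)
    lambda_43 = lambda_21 * exp(betaDamaged_AAbar)
    lambda_24 = lambda_13 * exp(betaActive_DbarD)
    lambda_56 = lambda_12 * exp(betaStayer_AbarA)
    lambda_65 = lambda_21 * exp(betaStayer_AAbar)

so three scalar log-rate effects carry the clinically central questions
(does damage change the activity process; does current activity accelerate
damage; do stayers fluctuate differently), while (u, v) is a zero-mean
bivariate normal random-effect pair (variances sigma_u^2, sigma_v^2,
correlation rho) shared by all 28 joints, with loading alpha letting u act
differently on the two activity intensities.

**Five-state model (sojourn times and jump probabilities).** The activity
states after damage are collapsed into a single absorbing damaged state (3),
and the model is reparameterised through the quantities clinicians ask
about: the mean sojourn times mu_1, mu_2 of the undamaged states (log link)
and the jump probabilities p13, p23 of moving directly to damage at the
next transition (logit link), each with its own regression, loadings
alpha_1/alpha_2 and stayer effects on the sojourn times. The smooth
bijection back to intensities is

    lambda_12 = (1-p13)/mu_1,  lambda_13 = p13/mu_1,
    lambda_21 = (1-p23)/mu_2,  lambda_23 = p23/mu_2,
    lambda_45 = 1/mu_4,        lambda_54 = 1/mu_5,

using the facts that, for a time-homogeneous chain, sojourn times are
exponential with mean 1/(total exit rate) and jump probabilities are
normalised intensities.

**Covariates** are frozen at the visit opening each interval (piecewise
constant): the dynamic ones are the adjusted mean activity
AMA(t) = (1/t) * integral of the linearly interpolated activity observations
(origin at the first visit), the attained number of damaged joints (0-28),
and contralateral-joint damage; the fixed ones are joint type (five levels,
thumb interphalangeal as reference, entering only the inactive->active and
damage intensities of the six-state model and absent from the five-state
model), sex, age at arthritis onset (years) and arthritis duration (years,
entry value plus time in clinic). Because AMA needs history, the first
interval of every patient is excluded from the likelihood by default; an
option reinstates it with baseline activity as the AMA proxy.

## Likelihood

Conditional on covariates, latent class and the random effects, each joint's
chain is Markov and time-homogeneous within an interval, so one joint
contributes a transition-probability factor P(dt) = expm(Q dt) per interval.
One (u, v) draw per interval is shared by the patient's 28 joints
(observation-level structure, independent across intervals); the
patient-level comparator uses a single (u, v) for all of a patient's
intervals. The double integral is evaluated by nested Gauss-Hermite
quadrature after factorising phi(u, v) = phi(v | u) phi(u), with weights
normalised to sum to one on the standard-normal scale; defaults are 15
nodes per dimension (observation-level) and 30 (patient-level). All
accumulation is in the log domain with log-sum-exp across nodes; 28-joint
products underflow otherwise.

The mover-stayer mixture acts per patient with a common stayer proportion
pi: patients with damage at the last visit (c* = 1) are known movers and
contribute (1-pi) L_mover; damage-free patients contribute
(1-pi) L_mover + pi L_stayer. The stayer integral over v is marginalised
analytically (the stayer chain does not involve v).

### Matrix exponentials

The public `transition_matrix` uses scipy's scaling-and-squaring Pade expm.
The likelihood hot path exploits the block-triangular structure
Q = [[A, B], [0, C]] of the mover chains: the 2x2 blocks have real,
nonpositive eigenvalues (computed stably as tau +/- d and exponentiated
directly, so no cosh overflow at extreme quadrature nodes), and the
transient-to-damaged block X(t) solves the Sylvester equation
A X - X C = e^{At} B - B e^{Ct}, a batched 4x4 linear solve. Rows whose
blocks (numerically) share an eigenvalue are detected by a spectral-gap
check and recomputed with scipy expm. Entries below -1e-12 raise; smaller
negatives are clamped and rows renormalised. The same closed forms are
compiled with numba (plain-python fallback included) and are cross-checked
against scipy expm and an adaptive Runge-Kutta integration of the Kolmogorov
forward equations in the test suite. Joints sharing an identical covariate
vector and interval length share one exponential per node. Linear
predictors are clipped at +/-60 before exponentiation so that extreme
optimizer excursions degrade gracefully instead of overflowing.

### Quadrature accuracy and a known limitation

Gauss-Hermite centred at the prior mean is exact only while the
per-interval integrand is well resolved by the node grid. With 28 joints
sharing one frailty the integrand can be much narrower than the prior and
displaced from zero; at sigma^2 around 2 the 15-node rule carries an O(0.1)
per-interval error that no practical node count removes (an 80-node rule
still oscillates by ~0.02 on a 30-patient cohort). Under moderate
heterogeneity (sigma^2 around 0.1-0.5) the rule converges cleanly
(15 -> 30 nodes moves a 20-patient log-likelihood by ~1e-7). The
node-insensitivity check in the acceptance suite is therefore run in the
moderate-heterogeneity regime; fits under strong heterogeneity maximise a
slightly smoothed likelihood, which the parameter-recovery study shows is
accurate enough for estimates to land within sampling error of truth.
Adaptive (posterior-centred) quadrature would remove the limitation but is
deliberately not used: the package keeps the prior-centred rule that defines
the model's fitting procedure, including its 1-node == conditional-at-zero
identity.

## Estimation

Maximum likelihood on an unconstrained working scale: log for variances,
atanh for rho, logit for pi, identity for everything else. BFGS with
numerical gradients maximises the working-scale log-likelihood; starting
values take baselines from crude transition counts over person-time
(ignoring clustering), coefficients at zero, variances at 0.5, rho at zero
and pi at 0.2 x the damage-free fraction.

Convergence is assessed at the returned point with a central-difference
gradient (step 1e-4, accuracy ~3e-5 at these problem sizes) against a
max-norm tolerance of 5e-3; the line search's own termination signal is
unreliable near the optimum because forward-difference gradients hit the
roundoff floor of a log-likelihood of magnitude 1e3-1e4. One BFGS restart
(fresh curvature) is attempted when the assessment fails.

The mover-stayer mixture has a characteristic spurious optimum: the stayer
log-rate effects can run onto a likelihood plateau (a stayer chain switching
so fast that one more unit changes nothing), leaving the stayer class
uninformative, whereupon pi collapses to zero and the whole stayer block
becomes flat. When a fit started at pi >= 0.02 ends with pi < 0.01, the
optimiser is rerun once from the collapsed solution with the stayer effects
reset to zero and pi re-opened, and the higher-likelihood solution is kept;
on recovery-study data this restores the interior optimum (which also has
the higher likelihood by ~30 log units).

Standard errors invert the negated central-difference Hessian at the
optimum. The default step 5e-3 balances truncation against roundoff
(second differences amplify the ~1e-5 absolute roundoff floor by 1/step^2;
a step of 1e-4 is noise-dominated and can produce spurious sign changes in
near-flat directions). A cheaper mixed stencil (central diagonal, forward
cross terms, ~4x fewer evaluations, first-order cross-term accuracy) is
available for expensive likelihoods. A non-negative-definite Hessian
raises, naming the parameter loading most on the flattest direction. 95% Wald intervals are
formed on the working scale and back-transformed, giving the expected
asymmetric intervals for variances and pi. The profile log-likelihood for
pi refits all other parameters on a grid, warm-starting each point from its
neighbour.

## Synthetic cohorts

The simulator draws exactly the process the likelihood assumes: latent
class ~ Bernoulli(1-pi); per-interval (or per-patient) bivariate normal
(u, v); conditional chains simulated event-by-event (exponential holding
times at the total exit rate, multinomial jumps) with covariates updated
only at visit times from the observed states — the analyst's information
set, not the latent path. Cohort-level defaults mirror the clinic
population the models were designed for: 55% male; age at onset
N(36.7, 13.3^2) years; arthritis duration at entry gamma with mean ~5.2 and
SD ~7.2 years; all joints undamaged at entry; ~10% of joints active at
entry (matching a cohort whose joints are inactive most of the time,
mean AMA ~0.09); visit gaps lognormal with
median 6 months and sdlog 1.0 (mean ~10 months, SD ~1.1 years); visits per
patient uniform on a configurable range (default 4-12). The first
(likelihood-excluded) interval is simulated with baseline activity as the
AMA proxy so the generative process is defined everywhere. In the
five-state variant a damaged joint's activity is recorded as 0 (activity
after damage is outside that model).

What the simulator does not emulate: informative visit scheduling, dropout,
treatment interventions, measurement error in joint assessment, and
serially correlated frailties. Passing recovery tests therefore demonstrate
the estimator is consistent with its own assumptions at realistic effect
sizes, not robustness to these violations.

## Study sizes used in the test suite

Chosen as the package's own desk-scale defaults: the parameter-recovery
study uses 200 patients x 28 joints x 7-9 visits and a reduced design (AMA
and sex on the activity intensities; AMA, attained damaged count and
contralateral damage on the damage intensity; 19 free parameters), with
clinically realistic true values (pi = 0.15, sigma_u^2 = 2, alpha = -0.4,
activity baselines e^-1.6 and e^0.6 per year). The fit runs a 7-node
first pass and polishes estimates and standard errors (forward-scheme
Hessian) at 11 nodes: at 7 nodes the maximiser of the approximated
likelihood is itself displaced by several standard errors in the variance
components (the quadrature limitation above), while at 11 nodes only a
remnant ~1-sigma-scale displacement remains; the profile-likelihood
identifiability check for the stayer proportion runs within the 7-node
fitted model around its own maximum.
The damage baseline is set to e^-6.5 per year and sigma_v^2 to 2 so that a
54-patient-year cohort yields enough damage events for the damage block of
the model to be identified (with a clinic-scale damage baseline of order
e^-9 per year, a cohort this size sees essentially no baseline-driven damage
and the Hessian is singular). The random-effect-structure comparison runs 10
replicates of 24 patients x 4-5 visits with an intercept-only design.
Monte-Carlo cross-checks use 10^6 draws (quadrature validity) and 10^5
draws (simulator consistency).

## Numerical conventions

Time is measured in years throughout; visit times are years since the
patient's first visit. Ages and durations stay in years, uncentred, so
coefficients read per year. Zero-length intervals are rejected at
validation. Mean sojourn times require a positive total exit rate;
conversions raise otherwise, naming the state. Datasets must contain all
28 layout joints at every visit and more than two visits per patient.
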