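# Methods

`nng` simulates the Nested Neuron Game: a hierarchical sensorimotor
coordination task in which a *sensor group* of four binary decision-making
units can see a fixed goal but can only act by displacing the target shown to
an *actor group*, whose four units move the cursor on both screens but cannot
see the true goal. This note documents the world model, the three agent
models, the metric suite, the evolutionary search, and the numerical and
design choices behind them — including where the package deliberately departs
from the most literal reading of its sources and why.

## 1. World model (`nng.game`)

Discrete time. Positions live in an abstract plane (origin at the
actor-screen centre, y up); there is no pixel raster. With group actions
`A^s, A^a in {0,1}^4` and assigned directions `mu^s_i, mu^a_i`, one step is

    sensor cursor   S^s <- S^s + alpha * sum_i A^a_i phi(mu^a_i)
    actor cursor    S^a <- S^a + beta  * sum_i A^a_i phi(mu^a_i)
    actor target    T^a <- T^a + gamma * sum_i A^s_i phi(mu^s_i)
    sensor target   T^s <- T^s                      (fixed within a trial)

where `phi` maps an angle to its unit vector. The stimulus of each layer is
the angle of the target-difference vector `psi = angle(T - S)` (the stimulus
points at the goal); a zero difference is a degenerate stimulus and units
never press on it.

Defaults and their rationale:

| parameter | default | why |
| --- | --- | --- |
| `alpha`, `beta`, `gamma` | 8 units/press | unreported in the source experiment; 8 yields trial lengths of a few hundred steps at the 840-unit start distance, matching the published per-batch time axis |
| `start_target_distance` | 840 | the experiment's start-target distance |
| `target_radius` | 40, boundary inclusive | only "circular target area" is reported |
| `trials_per_batch` | 6 | directions re-randomised every 6 trials |
| `decision_availability` | 0.80 | per-step, per-unit decision-slot probability, fitted in the source study to the players' sparse pressing |
| `target_hidden_steps` | 5 | the actor target is invisible "for the first few time steps" |
| `max_steps_per_trial` | 5000 | human trials always ended in success; simulations need truncation |
| windrose jitter | ±5°, sensor windrose offset uniform in [30°, 60°] | "approximately equiangular directions of two rotated windroses", never coinciding |

Each batch draws six approximately equiangular trial directions in random
order; each trial places the sensor start uniformly in a centred box with the
target 840 units away. Trials that exceed the step budget are recorded as
truncated. Everything is driven by a single `numpy` Generator, so batches are
bit-reproducible under a fixed seed.

## 2. Thompson-sampling units (`nng.thompson`)

Each unit holds a belief over the displacement direction its press causes,
with sufficient statistics `a + b i = sum_t alpha(t) e^{i psi_t}` (resultant
length `R`, angle `Theta`, accumulated weight `T`). Before each decision it
draws `(mu, kappa)` from the posterior

    p(mu, kappa | R, Theta, T) ∝ exp(kappa R cos(Theta - mu)) / I0(kappa)^T,

computes the expected activation utility
`f = pi/2 - E_v[angular distance(psi, v)]` under the sampled von Mises
belief, and presses with probability `sigmoid(rho (f - c))`, preceded by an
epsilon-greedy coin. Published constants: `rho = 2.73`, `epsilon = 0.23`,
sensitive-period weights `alpha(t) = 0.51 A_t + 1.03 A_{t-1} + 0.89 A_{t-2}`;
beliefs reset at every 6-trial batch boundary.

Numerics: the kappa marginal `∝ I0(R kappa)/I0(kappa)^T` is evaluated on a
512-point log-spaced grid on (1e-3, 500] with trapezoid bin masses and
normalised numerically; `mu | kappa ~ VM(Theta, R kappa)`. When `R >= T`
(e.g. after a single observation) the marginal is improper and is truncated
at `kappa_max` with a warning — the sampler then behaves optimistically,
committing sharply to its current estimate. The utility expectation uses a
720-point quadrature grid anchored at the stimulus, which makes `f = 0` exact
for a flat belief.

### 2.1 Credit assignment (the package's own design)

The sources never name the observable `psi_t` precisely. The most literal
choice — the raw per-step displacement angle of the unit's own-screen cursor
— was implemented first and demonstrably fails: every unit of a layer watches
the *same* cursor, so all beliefs converge onto the layer's common movement
direction (sensor units learn the actor windrose), the data alignment `R/T`
stalls near 0.1, sampled concentrations stay near zero, and the coupled game
deadlocks, while scripted-agent and frozen-belief control ensembles finish
trials in 130–550 steps. Three corrections make the model identifiable; all
keep the printed statistics, posterior, utility and decision rule intact:

1. **Baseline-contrast observations.** Each unit subtracts its running
   estimate of the ambient movement direction (exponential decay 0.05) and
   credits the direction of the residual. This is the spike-triggered-average
   -minus-mean idea: the drift that everyone causes cancels, the component
   correlated with the unit's own recent presses survives.
2. **Discernibility threshold (0.8).** Steps whose movement direction is
   within the ambient cone carry no information about the unit's own effect
   and are skipped.
3. **Evidence discount (0.15).** The iid von Mises likelihood is badly
   misspecified for multi-agent displacement data (most angular variance is
   exogenous); feeding the raw weight sum into `T` overstates the evidence
   and freezes the posterior at near-zero concentration. The observation
   count is therefore tempered: `T` accumulates `0.15 * alpha(t)`.
4. **Press cost (1.0).** A fixed effort intercept subtracted from `f` before
   the sigmoid. Without it an uninformed unit presses on half its slots and
   the cursor moves on ~98% of steps — incompatible with the sparse pressing
   the task's players show. With it, trained units press on ~0.2 of slots,
   selectively.

The three calibration constants and the press cost were fixed once, by the
same two-step procedure the source study used for its own hyper-parameters
(first completion, then distance to the published model statistics), and not
revisited afterwards. With them the full 4+4 ensemble completes essentially
every trial after the second trial of a batch, in 200–1500 steps.

## 3. Bounded-rational network (`nng.bounded_rational`)

A loopy two-layer network of bounded-rational binary units: each unit turns
its prior (uniform, reset per batch) into the posterior
`P(x) ∝ p(x) exp(beta U_eff(x))` and samples. Learning is modelled
descriptively by annealing `beta` linearly from 0.05 to the published 2.3
over the first 500 steps of each batch.

Effective utilities are expressed in **per-press units** (distance reductions
divided by the acting layer's step size) so that `beta = 2.3` sits in the
bounded-stochastic regime; in raw length units `beta * U ~ 18` and the
network is effectively deterministic. An actor's utility is its one-step
reduction of the actor-layer distance with the other actors at their current
mean displacement. A sensor press cannot move the sensor layer within one
step, so its base utility vanishes; the candidate action is valued through
the downstream certainty equivalent

    U_eff(x) = sum_j (1/beta_j) log E_{x_j ~ q_j(.|x)} [ exp(beta_j V_j x_j) ],

where `q_j(.|x)` is actor j's exponentially tilted response to the world as
moved by the candidate press and `V_j` is the sensor-layer gain of actor j's
press, evaluated at the discretised stimulus (8 circular bins). For
`beta_j -> 0` this degenerates to the prior-expected utility. (The fully
literal alternative — valuing the actors' *own* achievable utility — makes
sensors move the target toward wherever the actors happen to be, which can
never steer toward the external goal; this was verified empirically before
the design was fixed.)

Per game step the network runs one rollout of `2 * depth` alternating group
decisions (sensor, actor, sensor, ...), one simulated game step each, from
the current true state; a sliding window of `depth = 4` live rollouts is
kept, and the game action at time t is drawn uniformly among the candidates
the live rollouts hold for t (two per group). This scheduling is what
produces the network's characteristic response delay: the modal
sensor-to-actor cross-correlation lag is 4 steps.

## 4. Model-free baseline (`nng.baselines`)

A deliberately simple tabular stand-in for the model-free learners that fail
this task: per unit, a (stimulus bin x action) table of expected binary
improvement rewards, epsilon-greedy (0.1) action choice, sample-average
("adaptive learning rate") delta-rule updates spread over the lagged
eligibility window, a tiny random table init (untrained units respond at
chance, which keeps the game dynamic), and 360 one-degree stimulus bins —
the resolution of the published response-profile probes. The design is
documented as a stand-in, not a replication: several simpler variants
(coarse bins, signed rewards, accumulation updates) turn out to *solve* the
game, because stimulus-bin persistence performs multi-step credit assignment;
the fine discretisation is what starves the sensor layer (its weak, delayed
signal needs orders of magnitude more per-bin visits than a batch provides)
while the actor layer's immediate signal still resolves. Pretraining the
sensor units with 150 noiseless observations (a perfectly reacting actor
group) rescues the system, reproducing the published dichotomy.

## 5. Metric suite (`nng.metrics`)

All of the analysis statistics, each with a brute-force oracle twin in the
test suite: improvement rate (strict Heaviside, H(0) = 0), per-player correct
response rate (undefined — nan — with zero presses), spike-triggered circular
variance `1 - ||mean unit stimulus vector||` (spike-triggered by default, the
all-steps variant behind a flag), action-time correlation (the printed
product-moment formula; nan on zero variance), plug-in mutual information in
bits between the discretised stimulus and the 16-state joint actor action
(sliding-window variant: 150 steps, stride 10), signed cross-correlation lag
sweep (ties resolved toward the smallest |lag|, then positive; positive lag
means the first train follows the second), tie-corrected Mann-Kendall Z /
Kendall tau with continuity correction, and a binomial fit to the per-step
activity counts. Undefined values propagate as nan, never as 0.

Analysis conventions: per-batch time courses are cumulative over the first
750 steps of a batch (trials concatenated; comparisons never cross a trial
boundary), and "late" summaries average the final third of that window. The
late circular variance is computed per trial, because the goal direction is
re-drawn each trial: pooling trials would measure the spread of trial
directions, not response specialisation.

## 6. Evolutionary search (`nng.evolution`)

The game generalises to L layers with coupling matrices `MS[k, l]` (layer-k
presses move layer-l state) and `MT[k, l]` (targets), entries in [-1, 1],
under three constraint scenarios (externally fixed layer-0 target; plus no
self-target moves; plus strictly sequential coupling). Thompson units drive
every layer, with the architecture's own epsilon and sensitive-window length.
Mutation acts on layer count (min 2), units per layer (min 3), single weights
(Gaussian sigma 0.1, clipped), the record window and epsilon (clipped to
[0, 0.5]); selection keeps the top 30%, with three mutated descendants for
the top 10% and two for the rest. Fitness is the total step count over a
fixed game schedule (truncations cost the full budget), evaluated under
common random numbers — one evaluation environment per run — so selection
compares like with like and generation medians are commensurable.

The default `EvolutionGameConfig` is deliberately desk-scale (population 20,
start distance 300, radius 60, 2 repetitions x 3 trials, 500-step cap,
coarser posterior grids): the published search ran 100 systems for 65
generations on full games, hours of CPU. At 10 generations the search
reliably *improves* median fitness, but the margin is noisy (run-to-run
improvements between ~5% and ~40%): 10 generations of mutation-only,
30%-elitist selection on a noisy landscape leave limited room, and most of
the published gains accrued over the remaining 55 generations. The seed
architecture is a handcrafted two-layer system that solves the game slowly
(couplings 0.7, epsilon 0.3), mirroring the published choice of merely
feasible hand-built seeds.

## 7. Synthetic recordings (`nng.synthetic`)

Scripted ground-truth agents (press with probability p when a unit step
along the assigned direction strictly helps, q otherwise, gated by an
activity rate) provide known-parameter data for metric-recovery tests. A
`BatchRecord` can be emitted as a millisecond raw-event log (one row per
press: player, group, timestamp = step x 125 ms + uniform jitter), emulating
the unpublished lab format, and re-discretised by the published procedure:
L is the largest interval such that successive presses of every individual
player are at least L apart (minimum over per-player minimum gaps, capped at
500 ms for degenerate logs), with width-L bins anchored at the first event.

Limitations of the round trip: jitter shrinks the estimated L below the true
interval, so the bin index drifts by roughly `t * 2 * jitter / base`; exact
recovery is guaranteed only while that drift stays below half a bin over the
whole log (and leading/trailing idle steps, and players who never press, are
unrecoverable in principle). The tests exercise the exact regime; a blanket
"any jitter below L/2" guarantee would be false for long logs.

## 8. What the synthetic world does and does not establish

The generator and the agent models emulate: the trial/batch/windrose
structure, sparse availability-gated binary pressing, delayed sensor-layer
consequences, and the qualitative published pattern (both model classes
solve the game; actors learn before sensors; the model-free baseline fails
on the sensor layer and is rescued by noiseless pretraining; mutual
information between the sensor stimulus and actor actions grows within a
batch; the bounded-rational network responds with a ~4-step lag). They do
not emulate human reaction-time distributions, fatigue, motivation, or the
unreported pixel geometry of the original screens — and three quantitative
targets inherit that gap: the simulated ensemble moves on more steps than
the published model, so its late improvement rates (~35-40% actor, ~30-35%
sensor) sit above the printed 25%/20%; its actor layer tracks a nearer,
faster-rotating target, so the triggering-stimulus circular variance
(~0.3-0.45) stays far above the printed ~0.02 rad^2; and its actors respond
to a fresh command on the next step, so the Thompson modal lag is 1 rather
than 2-4 (the bounded-rational lag of 4 is reproduced). A green test here
establishes internal consistency of the simulation and analysis chain, not
agreement with the human recordings, which remain unavailable.
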