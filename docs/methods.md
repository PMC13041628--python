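# Methods

`campaignsim` is an agent-based planning tool for preventive campaigns in
older adults. It simulates how campaign exposure and social reinforcement
translate into annual influenza-vaccination uptake and routine-screening
participation across a heterogeneous older-adult population, and compares
15 prespecified campaign designs on joint efficiency/equity criteria. This
note documents the model, its parameters and defaults, the synthetic data
that stand in for the original survey microdata, numerical choices, and
known limitations.

## Model

### Population

Each agent is one adult aged 65+ with:

* a latent segment membership (6 classes, posterior probability vector and
  modal label),
* a channel-use vector `a = (a_TV, a_DG, a_PR)` in `[0,1]^3` for
  television, digital and print media,
* a baseline annual uptake propensity `q` per task, converted to a
  per-month hazard `b = 1 - (1-q)^(1/12)`,
* an offline degree target derived from ordinal social-activity frequency
  (1..5 mapped linearly to 2..10),
* a position in a fixed-node two-layer contact network.

### Contact structure

Two undirected simple graphs over the same nodes. The offline layer is
degree-targeted: randomized stub matching with rejection of self-loops and
multi-edges plus a bounded edge-swap repair pass, realizing each target
within about ±1 (mean absolute deviation ≤ 0.5 in the tests). The online
layer is a Watts–Strogatz small-world graph with mean degree 6 and
rewiring probability 0.10 (networkx construction, seeded). Social
influence acts on the union of the two neighbor sets. The degree map's
mean sits near 6 so the two layers carry comparable weight.

### State dynamics

States form an absorbing ladder: unaware (0) → aware (1) → adopted (2),
over `T = 12` monthly steps. Each step has two phases — awareness first,
then adoption conditional on awareness — with agents visited in a fresh
uniform permutation per phase. Awareness for agent `i`:

    L_aware = W_BG + Σ_c m_c · W_c(i) · a_c(i) + ω_a · f_aware(i)

where `W_c(i)` are the scenario's channel weights resolved for the agent
(posterior-mixed across classes by default), `m_c = k_neg` for TV and
digital in the loss-framing scenarios (1 otherwise), and `f_aware` is the
fraction of union-neighborhood contacts that are aware or adopted.
Adoption, only for aware agents:

    L_adopt = α · b + β_m · Σ_c m_c · W_c(i) · a_c(i)
              + β_s · 1[n_adopted ≥ τ] · f_adopted

Reinforcement is a complex contagion: it activates only once at least
`τ = 2` neighbors have adopted, and affects adoption only, never
awareness. Probabilities are `clip(L, 0, 1)` under the default
clipped-linear link; the logistic alternative `expit(γ0 + γ1·L)` with
`γ0 = -2, γ1 = 4` is anchored to agree with the clipped-linear link at
`L = 0.5` in level and slope, and is used as a sensitivity contrast only.

Within a phase, updates are **sequential**: an agent that becomes aware or
adopts is visible to agents visited later in the same permutation, which is
how a random-order iteration naturally behaves. A synchronous mode
(all agents evaluated against the phase-start snapshot) is available via
`ModelParams(sequential=False)` because the distinction matters in
principle; on the default population the two modes are indistinguishable
at the outcome level. Isolated agents get zero social terms (0/0 → 0).

The hot path is a numba-compiled kernel; a pure NumPy reference
implementation with identical semantics (`dynamics.step`) backs the small
worked examples, and both are validated against exact enumeration of the
two-phase Markov chain on 2- and 3-agent graphs (every permutation and
every Bernoulli branch enumerated; Monte Carlo frequencies at 50,000
replications within 3 standard errors of the exact probabilities). Kernel
seeds are passed through a `SeedSequence` so consecutive replication seeds
yield decorrelated streams.

### Parameters

| Parameter | Meaning | Default | Source of default |
|---|---|---|---|
| `α` | baseline propensity multiplier | calibrated per task | grid search |
| `W_BG` | background exposure weight (per step) | calibrated per task | grid search |
| `ω_a` | social-awareness weight | 0.30 | design choice |
| `β_m` | media weight in adoption | 1.0 | design choice |
| `β_s` | social-reinforcement weight | 0.20 | design choice |
| `τ` | adopted-neighbor threshold | 2 | design |
| `T` | horizon (months) | 12 | design |
| link | probability link | clipped linear | design |

`ω_a`, `β_m`, `β_s` are exposed configuration, never hard-coded into the
dynamics; the weight-allocation sensitivity axis perturbs them
(media-centric `β_m=1.5, β_s=0.1`; social-centric `β_m=0.5, β_s=0.4`).

### Scenarios

Fifteen designs A–O. A is background-only control. B/C/D isolate one
channel at weight 0.10; E–H are fixed-sum mixes at the same per-step
budget; I and J scale the TV+digital mix down (0.025 each) and up (0.200
each). K is equity-focused reweighting: the lowest-baseline-uptake class
(class 6 for vaccination, boosted on digital; class 1 for screening,
boosted on TV) receives `0.10 + δ` while all other classes get symmetric
`0.05 − δ/10` on both TV and digital, keeping the unweighted class-average
TV+digital budget at exactly 0.10; `δ = 0.02` by default, 0.05 as the
higher-intensity variant. L assigns class-tailored portfolios: TV-dominant
classes 1 and 5 get TV 0.10, digital-dominant class 6 gets digital 0.10,
mixed classes 2–4 get 0.05/0.05. M/N/O reuse B/C/E with the TV and digital
exposure terms multiplied by a loss-framing intensity `k_neg` on per-task
grids (vaccination 0.95–1.10, screening 1.05–1.20).

Personalization uses the posterior class probabilities by default (each
agent's weights are the posterior-weighted average of the class rows),
propagating classification uncertainty; hard modal assignment is kept as an
ablation. For ranking analyses the framing scenarios carry a single
representative multiplier — the midpoint of the task's grid — while
dose-response analyses traverse the full grid.

Network policy: scenarios A–H share one network pair across all
replications (variance reduction for the fixed-budget comparisons);
scenarios I–O regenerate both layers each replication to fold in
structural uncertainty.

### Outcomes and equity guardrails

Final adoption at month 12, mean time to adoption among adopters, and
awareness are summarized over 100 Monte Carlo replications as means with
2.5th–97.5th percentile intervals (linear interpolation). Equity across
the six classes uses five metrics on the class-level adoption vector:
minimum class adoption `A_min`, the 90–10 percentile gap in percentage
points, the relative disparity index (max/min), Theil's T and the Atkinson
index at `ε = 0.5`. Guardrails screen portfolios at `A_min ≥ 0.60`,
gap ≤ 25 pp, RDI ≤ 1.5; Theil and Atkinson are descriptive only. The 90–10
gap interpolates linearly between the six order statistics (the numpy
default); a nearest-rank convention would give systematically larger gaps
on six points, so the convention is fixed and documented here. Theil and
Atkinson weight classes by population share by default, with an
equal-weight option; the gap and RDI always use the unweighted class-level
values.

## Synthetic population

The original inputs were two matched national surveys (a media panel and a
health examination survey) that cannot be redistributed, so the generator
produces a synthetic pair with the same statistical structure:

* Six segments of sizes (534, 430, 420, 400, 376, 245), summing to 2,405;
  the extreme sizes match the printed range, the interior sizes are free
  choices. The screening task drops 5 random recipients (survey
  nonresponse), giving 2,400.
* Channel use is Beta-distributed per class: TV-dominant classes 1 and 5
  draw TV from Beta(8,2) and digital from Beta(2,6); digital-dominant
  class 6 is reversed; mixed classes 2–4 use Beta(4,4) for both; print is
  Beta(2,8) everywhere. This produces the media-profile ordering that the
  class-tailored scenario L exploits.
* Class-mean annual uptake propensities spread roughly ±0.10 around the
  task target (0.848 vaccination, 0.744 screening), recentered so the
  size-weighted mean hits the target exactly; class 6 is lowest for
  vaccination and class 1 lowest for screening, matching the scenario-K
  designations. Individual propensities are Beta draws around the class
  mean (concentration 30), and each recipient also carries a Bernoulli
  baseline behavior indicator used for the validation diagnostics.
* Donors (media survey) and recipients (health survey) share class-specific
  demographic niches — age centers 66.5–83 with recipient s.d. 2.5,
  sex, education, income-band and region-type distributions with modal
  shares around 0.7–0.85 — drawn once per class. Donor ages use a wider
  spread (s.d. 6, floor 55) to emulate the younger donor pool. The niches
  are deliberately distinct so that one-to-one nearest-neighbor Gower
  matching on (age, sex, education, income, region) is largely
  segment-faithful (~two-thirds of recipients receive a same-segment
  donor's media block); the residual cross-segment matching is realistic
  statistical-matching noise.

The matched table is segmented by a 6-class latent class model fitted by
EM on eight categorical indicators (terciled channel use and digital
literacy, ordinal social activity, education, income, sex). Posterior
probabilities become the personalization weights. Estimated class labels
are aligned to the generator's canonical indices by a Hungarian assignment
on the modal-label confusion matrix; on the default population this agrees
with the purely data-driven designation (ranking estimated classes by
class-mean baseline propensity and media profile), which is what a
deployment without ground-truth labels would use. With the default
profiles the fitted solution has relative entropy ≈ 0.80 and modal
agreement ≈ 0.66 with the generating labels — deliberately imperfect:
posterior-weighted personalization is only meaningful when classification
uncertainty is real.

What the generator does **not** emulate: survey weights and raking,
item-level missingness (beyond the 5 screening nonresponses), measurement
error in self-reports, any real-world dependence between media use and
health behavior beyond the class structure, and temporal class
transitions. Tests passing on this population show that the pipeline and
dynamics behave as specified under the assumed structure, not that the
substantive scenario rankings transfer to any real population.

## Latent class analysis

Classical categorical-indicator mixture: class proportions π and per-item
category probabilities ρ, conditional independence given class. EM with
flat-Dirichlet random starts (best of `n_starts` by log-likelihood),
convergence when the log-likelihood gain drops below `1e-6`, item
probabilities floored at `1e-6` and renormalized each M-step to avoid
degenerate zero cells. Selection is by minimum BIC (ties to smaller K)
with AIC and relative entropy reported alongside; the bootstrap likelihood
ratio test is out of scope. Label switching is resolved in recovery tests
by greedy total-variation matching of ρ profiles. Parameter recovery is
verified on well-separated 2- and 3-class simulations at N = 2,000
(π within ±0.03, ρ within ±0.05, BIC selecting the generating K).

## Calibration and internal validation

For each task, `(α, W_BG)` are fitted by grid search (α in 0.80–1.50 step
0.01, W_BG in 0.05–0.20 step 0.01 — ranges chosen to bracket the plausible
optima) against the uptake target under scenario A. Every grid point is
screened with 20 common-random-number replications; because the screening
noise (~0.0016 s.e. at N≈2,400) is not negligible relative to the 0.002
closure band, the 15 closest candidates are re-evaluated at the
100-replication verification count and the closest of those is returned
(ties toward smaller α, then smaller W_BG). The search is deterministic
given the seed and invariant to grid ordering. On the default populations
the achieved absolute deviation is ≤ 0.0005.

Because awareness gates adoption and per-step hazards compound over at
most 12 steps, the calibrated α generally exceeds 1 (the multiplier
compensates for the months an agent spends unaware); the exact optimum
depends on the synthetic population's social structure and is a ridge in
`(α, W_BG)` space, so different seeds can select different but equivalent
pairs.

Internal validation compares model-implied individual adoption
probabilities under calibrated scenario A against the survey baseline
indicators: Brier score, logistic recalibration slope and intercept
(maximum likelihood, separation flagged as an error path), and a
10-bin reliability table (equal counts, remainder to the lowest bins).
The model-implied probability integrates each agent's awareness/adoption
chain against the replication-mean population awareness and adoption
fractions per step (a mean-field approximation of the social terms, with
the reinforcement gate at the mean union degree). These diagnostics are
internal consistency checks within the calibrated model, not external
validation.

## Monte Carlo design and sensitivity

Replication `r` of a plan with base seed `s` uses seed `s + r`, so variant
configurations compared under the same plan share common random numbers;
regenerated networks use the same per-replication seeds across variants.
Summaries are deterministic given the plan and configuration, and
independent of scenario execution order.

The sensitivity suite reruns all 15 scenarios per axis — logistic link,
media-/social-centric weight allocations, `τ = 1`, alternative network
seeds — and reports Spearman rank correlation (average-rank ties) and the
maximum absolute rank shift of the mean-adoption ordering against the
baseline, with `ρ ≥ 0.90` and `Δrank ≤ 1` as the prespecified stability
benchmarks. On the default populations the `τ` axis and network-seed axis
pass comfortably; note that a few scenario pairs (e.g. the TV+digital mix,
its framed variant, and equity reweighting) differ by under 0.1 pp in true
mean adoption, so their relative order is not identifiable and single rank
swaps among them are expected. Rank comparisons use 50 replications per
scenario (halving the Monte Carlo error of 25-replication means, which
otherwise occasionally produces a spurious two-step shift inside that tie
cluster).

## Problem sizes used

Acceptance-level runs use the full populations (N = 2,405 / 2,400) with
the full calibration grid (1,136 points × 20 replications, verification at
100), 100 replications for scenario-level summaries, 50 for rank-stability
comparisons, and 50,000 replications for the exact-chain validation on
tiny graphs. Unit and property tests use populations of 250–300 agents and
smaller replication counts.

## Known limitations

* Adoption is a single absorbing decision; repeat annual decisions,
  fatigue, reactance and reversibility are unmodeled by design.
* Budget is relative exposure intensity, not money; no cost translation.
* The synthetic population is a structural stand-in; quantities that
  depend on the real microdata (Brier levels, calibration slopes, the
  entropy of the class solution, headline scenario outcomes) are
  reproduced in mechanism but not in value.
* `ω_a`, `β_m`, `β_s` and the logistic anchoring are design choices with
  sensitivity coverage, not estimated quantities.
* The online layer connects all agents by default; `build_layered` accepts
  an `online_active` mask to drop online ties for agents below a
  digital-use cutoff, but no cutoff is applied by default — media exposure
  already scales digital influence by each agent's digital affinity, and
  whether low-digital older adults are structurally offline is not
  something the surveys being emulated resolve.
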