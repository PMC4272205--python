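# Methods

This note documents the models, estimators and numerical choices behind
`flocknet`, and what the synthetic-data generator does and does not
emulate.

## The problem

RFID-equipped feeders log a timestamped stream of PIT-tag reads as birds
visit. The scientific questions live several layers above that stream:
which reads form a foraging flock, how strongly pairs of individuals
associate, whether association concentrates within families and mated
pairs, and whether an experimental developmental treatment (dietary
corticosterone given to half of each brood of chicks) shifts individuals'
positions in the resulting social network. `flocknet` implements that
chain — event detection, association networks, assortment, node metrics,
and mixed models tested by constrained permutation — together with a
generator that produces streams with known ground truth so every stage can
be scored.

## Synthetic detection streams

The generator emulates the design of a two-room captive study: 13
families (two parents plus a brood), split 7 + 6 between rooms, 37 chicks
of which 20 are corticosterone-treated (CORT) and 17 controls, the split
falling within each brood as evenly as parity allows; two feeders per
room; 35 observation days. Brood sizes default to eleven broods of three
and two of two — the only near-even partition of 37 chicks over 13 broods
— and are configurable because real brood-size distributions vary.

Foraging is modelled as discrete gathering events. Per feeder-day the
event count is Poisson (mean 20) and windows are placed uniformly in the
day, non-overlapping within a feeder, with lognormal durations (median
60 s, σ = 0.5 on the log scale). For each event, room members are
recruited sequentially — parents first, then chicks, in random order — and
each joins with probability

    p = p_join_base × kin_bias^[family member already in]
                    × pair_bias^[mate already in]
                    × cort_gregariousness_effect^[CORT chick]
                    × cort_parent_effect^[CORT chick and parent already in]

clipped to [0, 1]. Each joining bird emits a geometric number of reads
(support ≥ 1, mean 4) at uniform times inside the window. Defaults
(p_join_base = 0.12, kin_bias = 3, pair_bias = 4, cort_parent_effect =
0.5, cort_gregariousness_effect = 1.5) were chosen once to give realistic
flock sizes (about four birds in a ~30-bird room) and clearly present but
not extreme family, pair and treatment structure.

Randomness is split across three child generators of a single seed —
event skeleton, memberships, and reads (the last keyed per event) — so
that changing a membership parameter leaves the event skeleton and read
layout of unaffected events untouched. This makes effect-monotonicity
checks (e.g. chick–parent association non-increasing in
`cort_parent_effect`) well posed.

What the generator does **not** emulate: circadian visit structure, feeder
preference or dominance, tag-read failures (an optional uniform background
noise rate exists, off by default), within-event spatial structure, and
any behavioural carry-over between events. Passing tests therefore show
that the analysis chain recovers structure *of the kind it assumes*; they
do not validate the chain against sensor artefacts or temporal
autocorrelation found in real streams.

## Gathering-event detection

Read streams are bursty: dense while a flock occupies a feeder, silent
otherwise. Events are recovered per feeder-day by fitting a 1-D Gaussian
mixture over timestamps:

* coarse pre-segmentation at silences > 600 s (`gap_threshold`) bounds
  the problem; this is an efficiency device set far above within-event
  read spacing (seconds), not a flock definition;
* within a segment, EM is run for K = 1…k_cap with k-means++-style
  initialisation (two restarts), a variance floor of 1e-6 s² (survives
  duplicate timestamps), and convergence at |Δ log L| < 1e-6;
* K is chosen by minimum BIC, stopping after BIC worsens twice;
* components whose means are closer than c·(sd_i + sd_j), c = 1 by
  default, are pooled by moment-matching and reads re-assigned by maximum
  responsibility (ties to the nearer mean, then the lower index).

Two guards matter in practice. First, candidate solutions containing a
floor-variance "spike" component that carries fewer than two reads *and*
sits inside another component's support are rejected before model
selection — this is the classical EM degeneracy, and unchecked it inflates
the likelihood enough to beat the BIC penalty. An isolated single-read
burst still gets its own component. Second, k_cap is bounded by one plus
the number of internal silences longer than `micro_gap` (60 s): a segment
cannot contain more bursts than such silences allow, and without the bound
BIC over-splits uniform-within-window bursts (which are flat-topped, not
Gaussian). On default streams detection recovers ~98% of true events with
mean membership Jaccard ≈ 0.99.

Day boundaries are calendar cuts at multiples of 86 400 s from study
start. Detection is therefore invariant to shifting all timestamps by
whole days, and to any shift that moves no burst across midnight; a
generic shift can relabel the day of a midnight-straddling burst, which is
inherent to calendar-day networks.

## Networks and node metrics

The association weight is the simple ratio index, w_ij = x/(x + y_i +
y_j): the proportion of gathering events involving either bird that
involved both. With single-group gathering events the "both seen in
different groups" term of the general index is structurally zero, so the
SRI is exactly the Jaccard index of event sets (the four-term general form
is provided for external sighting data). One network covers the whole
study; daily networks use each day's events only, over the full roster,
with the two rooms as disconnected blocks.

Node metrics per day: unweighted degree (positive edges), strength (sum
of weights; proportional to mean group size), betweenness (raw
shortest-path counts; weighted paths use the standard 1/w distance
transform; normalised values available), eigenvector centrality (leading
eigenvector per connected component by power iteration on the matrix
shifted by its largest row sum — the shift keeps the spectrum positive so
iteration cannot oscillate on bipartite components — rescaled to max 1,
tolerance 1e-10), social differentiation (coefficient of variation of a
bird's edge weights to same-room others, zero edges included by default:
a bird ignoring most of the room is maximally "choosy"; an
exclude-zeros variant exists), and a chick's mean weight to its two
parents. Repeatability of any daily metric is the one-way ANOVA
intraclass correlation with the mean-adjusted group size k₀ for unbalanced
data, reported raw and clipped to [0, 1].

## Assortment

The weighted categorical assortment coefficient is computed from the
mixing matrix e_kl (share of edge weight between categories k and l):
r = (Σ e_kk − Σ a_k²)/(1 − Σ a_k²). Family labels include parents by
default (a chick-only variant exists); pair labels give each mated pair
its own category and every other bird a singleton. The standard error is
a delete-one-positive-edge jackknife. Significance comes from 1000
node-label shuffles within room. Because singleton categories pull the
null distribution of r below zero, the two-tailed p locates the observed
r within the null distribution *around the null's own centre* (add-one
estimator); a zero-centred comparison would never reject for pair
assortment no matter how strong the pair structure.

## Mixed models and data-stream permutation

Daily metrics of chicks are modelled with a linear mixed model (REML):
fixed effects treatment, day (centred continuous by default; categorical
available), sex, treatment×day and treatment×sex; random intercepts for
room, family within room, and individual within family (statsmodels
MixedLM with variance components). Singular or failed fits fall back by
dropping the innermost component, ending at OLS, and the estimator
actually used is recorded. The permutation framework requires only that
the *identical* routine scores observed and permuted data, so a plain OLS
estimator is available for permutation-heavy runs.

The null model for coefficient significance is a constrained permutation
of the group-by-individual matrix: checkerboard swaps within (day, room)
strata (optionally also feeder) that exchange two birds between two
events, preserving every event's size and every bird's per-stratum event
count. One serial chain is used: 1000 burn-in swaps, then a sample every
100 accepted swaps (all three knobs exposed), daily networks and metrics
rebuilt and the model refit at each sample. Under a structureless
simulation with homogeneous joining probabilities, the observed GBI is
uniform on its margin class, so the test is exact; empirically the
rejection rate at α = 0.05 is ~0.05–0.06 over 200 replicate chains.

Because the swaps preserve each bird's sampling effort, the null
distribution of a coefficient is *not* centred at zero — it carries
whatever part of the effect is encoded in event counts. The p-value
therefore locates the observed coefficient within the permutation
distribution (two-tailed around the null centre; one-tailed options
available). A corollary worth knowing: effects that act mainly through
how *often* a bird forages (gregariousness) are largely absorbed by the
null, so power against them comes only from group-composition residuals
and is moderate (~40% at the default design for a doubled joining rate);
effects on *whom* a bird forages with (parent association, kin structure)
are tested at full power. This is the price of the stricter null, and it
is the standard trade-off for association data derived from gathering
events.

No multiple-testing correction is applied across the several response
metrics; p-values are reported per response.

## Problem sizes used in the checks

Oracle-equivalence checks run exhaustively on graphs of ≤ 8 nodes and
GBIs of ≤ 10 events × 6 birds. Event-recovery runs 10 independent
default-design streams. Type-I calibration uses 200 replicates of a
one-room, five-brood, five-day design with 200 permutations each, with
the OLS estimator inside the permutation loop. Effect-direction recovery
uses 20 replicates of the default two-room design over 15 days with the
mixed-model estimator. These sizes were chosen to make the stochastic
assertions sharp (binomial confidence bands around the nominal level)
while keeping a full run of the suite inexpensive.

## Known limitations

* The event-membership model is the simplest generative structure that
  produces family/pair assortment and treatment effects; it is declared,
  not derived from data.
* The mixture model assumes Gaussian bursts; simulated reads are uniform
  within a window, which the merge step and burst-count bound absorb, but
  heavily overlapping same-feeder flocks are not separable in time alone.
* With only two rooms the room-level random intercept is weakly
  identified; the fallback chain handles the resulting singular fits.
* Permutation p-values for gregariousness-type effects are conservative
  by design (see above); interpret non-significance there accordingly.
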