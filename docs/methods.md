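# Methods

This note documents the models implemented in `misinfosim`, the assumptions
they make, the defaults and why, and what the synthetic world does and does
not establish.

## Information-flow network

Edges are inferred from behavior, not from declared follow relationships: a
directed edge *i → j* with weight |R₍ij₎| exists iff *j* reshared at least one
of *i*'s posts in the window. |R₍ij₎| counts **distinct** posts (R₍ij₎ is a set
of posts): repeated reshares of one post do not inflate the weight.
Self-reshares create no edge. Reshares whose parent post is missing from the
log are skipped, counted and logged.

The snowball selection scores each candidate outside the current set by the
sum of incoming and outgoing reshare weights with the set, equally weighted,
and adds the best candidate one at a time (ties: smallest user id, for
determinism). Candidates are drawn from the full pool minus the current set;
scores are maintained incrementally but are identical to full recomputation
(property-tested against a brute-force oracle).

Community detection symmetrizes the graph (weights summed across directions)
and runs Leiden (RB-configuration objective, resolution parameter exposed,
seeded). Directionality matters for simulation, not for the modularity-style
objective. c-TF-IDF labels use `tf(t, c) · log(1 + A / f(t))` with A the
average term count per community; tokenization is lowercase, split on
non-alphanumerics, tokens of length ≥ 2.

## Features

Each candidate transmission (follower f, originator k, tweet T) yields a
158-dim vector: 7 behavioral statistics per user (follower count, followee
count, their ratio, reshares-received per post, reshares-made per followee
post observed, QT and RT counts), a 24-dim mean embedding of k's authored
texts, a 24-dim mean embedding of the content f reshared, and a 96-dim
embedding of T. The tweet block is deliberately the largest so the model
stays sensitive to the spreading text. Follower/followee counts use profile
metadata when supplied, otherwise information-flow degrees. Users with no
history in a role get the zero vector (the mean-free neutral element);
users with no activity get zero rates.

The text embedder is pluggable (any `text -> R^384` map). The default is a
seeded random projection of token counts: each token hashes to a fixed
Gaussian direction, texts embed to the normalized sum. It is deterministic,
needs no pretrained weights, and inverts the synthetic generator's topic
vocabulary. The dimensionality reducers (384→24 user-level, 384→96
tweet-level) are linear autoencoders fit at their exact optimum via SVD of
the pooled embedding matrix, with a deterministic sign convention; the
optimum coincides with the principal subspace, which the test suite checks
against an eigendecomposition oracle. Both reducers are trained on the same
pooled embeddings of all texts in the window. A nonlinear variant was
considered and dropped: the architecture is otherwise unconstrained and the
linear optimum is the only checkable choice.

## Infection model

Exposure labeling assumes every follower sees every post of the accounts
they follow; a missing reshare is a negative. The classifier is a histogram
gradient-boosted tree (scikit-learn), trained on 20% of rows with the
remaining 80% held out — the unusual split direction is intentional and
kept configurable; the large held-out part feeds calibration and
evaluation. An optional seeded random search over a small hyperparameter
space is available but off by default. For desk-scale runs negatives can be
downsampled; the calibration step absorbs the induced prior shift via the
odds correction r → κr/(κr + 1 − r), κ the kept-negative fraction.

**Calibration.** Held-out observations are split into 100 equal-count bins
by raw score and each bin's empirical positive rate is computed. The
smoothing polynomial (degree 11, coefficients constrained non-negative via
NNLS) is fit over the **quantile level** of the score, not the score
itself: a raw score is first mapped through the stored piecewise-linear
empirical CDF, then through the polynomial, then clipped to [0, 1]. The
non-negative-coefficient constraint makes the polynomial non-decreasing on
[0, ∞), and the CDF map is monotone, so calibrated probabilities are
monotone in raw scores. The quantile parameterization is a deliberate
choice: a non-negative-coefficient polynomial is convex, so in score space
it cannot represent the concave calibration curves that regularized
rare-event classifiers typically need (measured: mean absolute error 0.057
on a quadratic score distortion, versus 0.002 in quantile space).

**α.** Calibrated probabilities are multiplied by a constant α and clipped
at 1. α compensates for simulating a truncated subnetwork of a much larger
platform (the cascade cannot recruit users the clone does not contain); it
is applied after calibration so the calibration curve is reusable across α.
The synthetic world is complete — there is no truncation to compensate —
so examples and the acceptance pipeline use α = 1; the parameter exists for
clone-of-real-network deployments.

## Cascade simulator

States are Susceptible, Exposed (infected, will reshare, not yet infective)
and Infective. The event loop pops the minimum-infection-time exposed user
(ties by user id), marks them infective and gives each *susceptible*
follower one Bernoulli attempt with IP computed from the tweet's
**originator** — not the immediate sharer — exactly as the branching rule
defines; exposed-but-not-infective users do not transmit. Waiting times are
Exponential(1), so layer-k infection times have mean k (tested on a certain
chain). Infection occurs when the uniform draw is strictly below IP, making
IP = 0 exactly safe and IP = 1 certain. The QT/RT draw happens at exposure:
a quote rewrites the carried tweet to `commentary + ": " + parent` and
reassigns its originator to the quoter, so downstream IPs are recomputed
against the new text and author; ineligible or failed generation degrades
to a verbatim retweet. QM is computed from whatever history a user has (the
25/20 QT eligibility thresholds gate commentary *generation and evaluation*
cohorts, not the branching draw).

Each trial's randomness comes from a child of `SeedSequence(base_seed)`;
interventions draw from a second, independent child so common-random-number
comparisons across intervention settings stay paired. `max_layers` stops
transmission (not infection) at the given layer, with the seed at layer 0.
Debug mode asserts the state machine on every event: S→E→I only,
conservation, at most one attempt per (infective, susceptible) pair, layer
increments of one, strictly increasing times.

With mutations off and fixed per-edge probabilities the final-set
distribution equals the independent-cascade model's; the test suite checks
this by exhaustive edge-subset enumeration (χ² goodness of fit) on small
graphs.

## Countermeasures

Interventions are multiplicative transforms of a user's *outgoing* IP at
predict time — no graph surgery — so they compose with any transmission
model. Quarantined users can still be infected and are counted; they
transmit nothing. Inoculation samples ⌊fraction · size⌋ community members
per trial (resampling models campaign-membership uncertainty; a fixed-subset
mode exists) and draws each member's reduction uniformly from [0.18, 0.22];
the distribution family is a package choice, only the 20% ± 2% range is
given. Spreaders are ranked by total children across all trial infection
trees, descending, ties by id. The static baseline replaces the trained
model with a single probability — total reshares over total exposure pairs —
for every edge and tweet. Topic sweeps min-max normalize mean cascade sizes
across seed posts; identical means are reported all-zero with a degenerate
flag rather than dividing by zero.

## Synthetic world

The generator emulates the statistical structure the pipeline assumes:
K communities with orthonormalized topic centroids in a d-dim latent space;
unit-norm user preferences scattered around their centroid; a
degree-corrected stochastic-block-model follow graph (within/across block
probabilities scaled by Pareto popularity weights → heavy-tailed follower
counts); Poisson posting with topics near the author's preference; reshare
decisions Bernoulli(σ(base_logit + λ·⟨preference, topic⟩)); reshares
trailing their parent by an Exponential(6 h) delay; quote-vs-retweet by a
per-user fraction, with commentary drawn from vocabulary near the quoter's
preference. Texts are deterministic token strings derived from topic
vectors, so the hashing embedder can recover topical structure without any
language model.

Defaults (500 users, 5 communities, d = 8, within/across follow 0.05/0.02,
Pareto 2.5, Poisson(40) posts/user, base_logit −5.5, λ = 6, preference/post
noise 0.2/0.1) were chosen so the planted signal is *recoverable*: the
network only contains pairs with an observed reshare — a selection effect
that compresses planted contrast — and milder worlds leave even the oracle
(true probability as score) near AUC 0.6, in which case recovery tests
measure nothing. Under the defaults the oracle reaches ≈ 0.77 and the
trained model ≈ 0.70 with Spearman ≈ 0.7 against the planted truth across
seeds. The resulting ≈ 20% reshare-per-exposure rate is far above the
per-platform-follower rates of real data (fractions of a percent over tens
of millions of exposures): the synthetic network conditions on engaged
edges and must produce enough positives at 10⁵ rows for a desk-scale
classifier. A green recovery test therefore establishes that the pipeline
recovers a planted topic-affinity signal through the full feature →
classifier → calibration chain — not that it would achieve any particular
AUC on platform-scale rare-event data, and not that the synthetic text has
natural-language structure.

## Numerical choices and degenerate inputs

- Calibration with fewer observations than bins reduces the bin count with
  a warning; single-class AUC slices return NaN with a warning.
- Zero-follower authors make the infection rate undefined: NaN, flagged.
- Empty commentary from a generator (or a generator exception) falls back
  to a verbatim retweet.
- All stage seeds derive from one base seed by hashing stage names
  (`config.derive_seed`), each below 2³¹.

## Limitations

- Exposure is all-followers-see-everything; recommendation-algorithm
  feeds, refutation/debunking dynamics and recovery states are out of scope.
- The commentary generator interface ships with retrieval mocks only; no
  hosted language model is called, so absolute commentary-similarity
  numbers reflect the synthetic vocabulary, not LLM capability.
- The snowball subnetwork inherits the known biases of snowball sampling
  (centrality, path length) relative to the full network.
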