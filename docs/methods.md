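# Methods

## The generative model and its temporal structure

The package works with categorical hidden-Markov generative models: a
likelihood matrix **A** of shape (n_outcomes × n_states), transition kernels
**B** of shape (n_states × n_states) and an initial prior **D**. All matrices
are column-stochastic — columns index the conditioning variable — so both
mappings act by left matrix–vector products, and validation enforces column
sums within 1e-12. **B** is stored as an ordered list to allow a different
kernel per step; a homogeneous model stores one shared matrix, which is also
the default everywhere (per-step kernels are representable but no packaged
scenario requires them).

Time is indexed twice: an objective step *t* and a subjective offset *τ*
relative to a declared reference event. The `temporal_graph` module realizes
three dependency structures as DAGs. The sequential order is the familiar
causal chain in *t*. The interpenetrated order models subjective temporality
alone: deeper retentions and protentions flow inward so the present is a
collider with in-degree 2. The integrated continuity is a two-coordinate
lattice: hidden nodes at offsets 0..depth and observed retention nodes at
offsets −depth..−1 are replicated at every objective step, and every hidden
node (t, τ) takes parents {hidden (t−1, τ+1), hidden (t, τ+1),
observed (t, τ−1)} — the same conditioning set the belief update reads —
applied homogeneously across the lattice. Finite lattices truncate: nodes
missing some parents are boundary nodes, and deep retention nodes (τ ≤ −2)
have no outgoing edges because observations never feed observations.

Markov blankets are computed by the graph rule (parents ∪ children ∪
co-parents of children) and verified against a d-separation oracle that
enumerates every undirected path and applies the chain/fork/collider
blocking rules directly. Path enumeration is exponential in general but the
lattices analysed here have at most tens of nodes; clarity of the oracle was
preferred over the Bayes-ball optimization, and the test suite additionally
cross-checks it against networkx's independent implementation. On the
integrated lattice the present node's blanket is its three parents: it spans
two objective times and contains two past-side members against one
future-side member. This asymmetry — the present statistically bounded by
more past than future — is the structural sense in which the lattice keeps
experience flowing rather than slicing it into isolated nows.

## Belief updating

Beliefs live on a chain of positions p = 0..T−1; the two index conventions
are coordinate charts on that chain. The `stationary` chart fixes one
objective time and walks τ. The `integrated` chart assigns a hidden node
(t, τ) to position 2t + τ and an observation (t, τ) to position 2t + τ + 1,
so the neighbours read by an update — (t−1, τ+1), (t, τ+1) and the
observation (t, τ−1) — resolve to positions p−1, p+1 and p. The two
labellings therefore address the same chain positions through different
temporal descriptions, which is exactly the point: updates under the
integrated chart demonstrably consume coordinates at two distinct objective
times (checked structurally in the tests; chain-start updates are the
exception since the truncated lattice gives them no past-side neighbour).

The single-site update is

    s_p = σ( ln(B_{p−1}) s_{p−1} + ln(B_p)ᵀ s_{p+1} + ln(A)ᵀ o_p ),

with the initial prior ln **D** replacing the forward term at p = 0 and
missing backward/likelihood terms omitted at boundaries. The gradient flow

    v ← ln s + Δt · (messages − ln s),  s ← σ(v)

is explicit Euler on the log-potential followed by renormalization; it is
gradient descent on the mean-field variational free energy

    F = Σ_p E_q[ln q(s_p)] − E_q[ln p(s_p | s_{p−1})] − E_q[ln p(o_p | s_p)],

whose stationary points on the simplex are precisely the fixed points of the
single-site map. Δt = 1 collapses the flow to direct fixed-point iteration
(`solve_stationary`). Two printed forms of the message dynamics circulate
that differ in the sign of the self-term; only the variant with the −ln s
decay inside the bracket makes the softmax-of-messages expression a true
stationary solution, so that variant is implemented.

Numerical choices:

* **Step size** Δt defaults to 0.1; Δt ≤ 1 is the supported regime. Values
  above 1 are allowed with a warning so that overshoot-induced
  non-convergence can be studied; a near-deterministic fixture in the tests
  oscillates indefinitely at Δt = 2 while relaxing at Δt = 0.1.
* **Log floor**: probabilities are clipped at 1e-16 before any logarithm,
  making deterministic matrices first-class. Exact zeros in belief vectors
  annihilate floored logs in the free-energy expectations, so perfect-fit
  instances evaluate to F = 0 exactly.
* **Sweep schedule**: positions are updated in chain order within each sweep
  (deterministic Gauss–Seidel), for bit-reproducibility.
* **Convergence**: a sweep's largest belief change below 1e-8 stops the
  iteration; hitting `max_iterations` (default 10,000) is flagged in the
  convergence record, never raised.
* **Initialization**: uniform beliefs. The free-energy landscape is
  non-convex and different dynamics can reach different local fixed points
  from the same start; each solver is therefore validated against the
  stationarity condition itself (pointwise self-consistency) rather than
  against the other solver's endpoint. A filtering-based warm start was
  evaluated and does not materially change accuracy, so the simpler default
  stands.

**Message reading.** The notation "ln B s" is ambiguous between
(elementwise ln B) @ s and ln(B @ s). The default follows the former,
reading the printed juxtaposition literally; `UpdateConfig.log_of_product`
switches to the latter. The two are not numerically equivalent: by Jensen's
inequality the elementwise reading lower-bounds the log-predictive and
over-sharpens the posterior, a known over-confidence of this family of
message approximations. Accuracy statements about closeness to exact
smoothed marginals (the KL-beats-uniform guarantee below) are therefore
made under the calibrated ln(B @ s) reading; equation-fidelity tests use the
default. With a noiseless likelihood and deterministic transitions both
readings recover the exact marginals to machine precision.

`present_moment_inference` implements the three-message present-moment
update in its bare form — log-protention + log-primal-impression +
likelihood message, softmaxed — and is validated against a linear-domain
product-of-factors oracle.

## Exact oracles

With no action the model is an ordinary hidden Markov model, so ground truth
is available: scaled forward–backward smoothing (evidence reconstructed from
the per-step scale factors) and, for instances with n_states^T ≤ 10^6, a
brute-force sum over all state paths. The two agree to 1e-10 on random
instances and one test cross-checks marginals and evidence against hmmlearn.
Impossible observation sequences return a −inf log evidence and a
uniform-marginal sentinel with a warning flag rather than raising. The
converged mean-field beliefs satisfy F ≥ −ln p(o) (the variational bound)
on every tested instance; their per-index KL divergence from the exact
marginals beats the uniform baseline on ≈ 95% of random instances
(91–98 across suite seeds), the remainder being local-minimum cases.

## The demos and the synthetic conditions

**Melody.** `make_melody_model(p, q)` has five hidden states (toneA..toneD,
silence) and five outcomes. The progression advances with probability *p*
and otherwise falls silent; toneD resolves into silence; silence is
absorbing; the likelihood reports each tone's own outcome with probability
1 − *q*, spreading *q* uniformly over the rest; the prior is certain on
toneA. Defaults p = 0.9, q = 0.05 describe a mostly reliable melody heard
through slight noise — enough fidelity for strong protention, enough noise
to keep every outcome possible. The demo relaxes the beliefs over each
heard prefix, pushes the last belief through the kernel to form the one-step
predictive, and scores the incoming outcome's surprisal −ln p(o). With the
residual progression mass flowing to silence, the anticipated tone is
cheaper than the abrupt end whenever the predictive favours the next tone —
analytically p > 1/2 at small q for the one-step predictive, with the
smoothed posterior's accumulated silence mass tightening the requirement as
q grows; the tests therefore assert the ordering on the p ≥ 0.55, q ≤ 0.1
grid where it provably holds, and its failure near chance-level fidelity is
a property of the scenario, not a defect.

**Serial dependence.** A circular stimulus space of 12 positions (the
coarsest grid that still resolves graded biases, and comfortably above the
8-position minimum enforced); i.i.d. uniform stimuli; a von-Mises-like
likelihood (concentration 2.0, a clearly noisy but informative observer);
and a von-Mises-like carry-over kernel (concentration 2.0) that diffuses the
previous trial's posterior into the current trial's prior. The estimate is
the posterior circular mean — MAP would quantize away small shifts. The
attraction statistic is the mean signed estimation error projected onto the
direction of the previous observation; its significance is assessed with a
one-sided sign test. 1,000 trials put the standard error near 0.06 grid
units, far below the observed effect (~0.5). The uniform-kernel control
retains nothing and stays within two standard errors of zero; a noiseless
likelihood pins the posterior to the stimulus and abolishes the bias.

What the synthetic conditions do **not** emulate: continuous stimulus
spaces, response noise, attention or confidence modulation, multi-step
retention kernels, and any fit to human psychophysics. Passing tests show
that the implemented belief dynamics produce the qualitative phenomena
(anticipation, violation surprise, attractive history bias) under the stated
conditions — not that these parameters describe human observers.

## Scale of the packaged experiments

The property suites run 100 random models of 2–5 states and 3–8 steps
(belief dynamics), 50 instances for oracle agreement, exhaustive blanket
verification on integrated lattices up to 12 nodes, and 1,000-trial
serial-dependence runs — sizes at which every check is exact or tightly
converged while the whole suite stays fast on one CPU.

## Known limitations

* Action selection, policies and expected free energy are out of scope; the
  dynamics analysed are pure perception.
* The mean-field beliefs are approximate away from deterministic limits;
  exactness holds only for noiseless likelihood + deterministic transitions.
* The free-energy landscape is non-convex; convergence is to a local fixed
  point dependent on initialization and step size.
* The interpenetrated order is implemented purely structurally; what joint
  distribution retention and protention should share under that order alone
  is left open, as is any clinical mapping of "malfunctioning" integration —
  only the generic knobs (kernel width, message reading, step size) are
  exposed.
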