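# livingpresent

Discrete-state belief propagation over temporal Bayesian networks, built for
computational studies of time-consciousness. The package is aimed at
researchers in computational neuroscience and computational phenomenology who
want an executable, testable version of the idea that the experienced present
is not a point but a *duration-block*: at every moment an agent
simultaneously intends the just-past (**retention**), the now-phase
(**primal impression**) and the about-to-occur (**protention**).

## The model

An agent entertains a categorical generative model with likelihood **A**
(`p(o|s)`, column-stochastic), transition kernels **B** (`p(s'|s)`) and an
initial prior **D**. Time carries two coordinates: an objective step *t*
(superscript) and a subjective offset *τ* (subscript) relative to a reference
event, so a state belief is written **s**_τ^t. Three temporal orders are
representable as DAGs:

* *sequential* — a causal chain in objective time;
* *interpenetrated* — subjective temporality, where the present is a
  collider fed by retention and protention;
* *integrated continuity* — the two combined: each hidden node (t, τ)
  depends on the previous step's anticipation **s**_{τ+1}^{t−1}, the current
  prediction **s**_{τ+1}^{t}, and the retained observation o_{τ−1}^{t}.

The posterior belief at each node is the softmax of three log-domain
messages,

```
s_τ = σ( ln(B_{τ−1}) s_{τ−1}  +  ln(B_τ)ᵀ s_{τ+1}  +  ln(A)ᵀ o_τ ),
```

which is the stationary point of the gradient flow
`v̇_τ = messages − ln s_τ` on the mean-field variational free energy
F of the chain. The package implements the flow (explicit Euler with
renormalization), the fixed-point map, the free energy and its
decomposition, outcome surprisal, Markov-blanket extraction with a
brute-force d-separation oracle, and exact forward–backward /
path-enumeration oracles (the model with no action is an ordinary hidden
Markov model).

## Worked example

```python
import livingpresent as lp

# the Markov blanket of the present moment on the integrated lattice
dag = lp.build_temporal_dag("integrated", objective_horizon=4, subjective_depth=2)
blanket = lp.markov_blanket(dag, dag.reference)
print(sorted(m.node_id() for m in blanket.members))
print(lp.blanket_asynchrony(blanket))

# melody surprise: A, B, C, then either D or an abrupt end
for condition in ("completed", "truncated"):
    result = lp.run_melody_demo(fidelity=0.9, noise=0.05, condition=condition)
    print(condition, [round(s, 3) for s in result.surprisals])

# serial dependence: retained posteriors attract the current estimate
sd = lp.run_serial_dependence_demo(n_states=12, kernel_concentration=2.0,
                                   likelihood_concentration=2.0,
                                   n_trials=1000, seed=11)
print(f"attraction = {sd.attraction_statistic:.3f} "
      f"(SE {sd.standard_error:.3f}, sign-test p = {sd.sign_test_pvalue:.2e})")
```

prints

```
['h:1:1', 'h:2:1', 'o:2:-1']
AsynchronyRecord(objective_span=1, past_count=2, future_count=1, imbalanced=True)
completed [0.051, 0.155, 0.157, 0.157]
truncated [0.051, 0.155, 0.157, 2.23]
attraction = 0.534 (SE 0.060, sign-test p = 5.94e-34)
```

The blanket of the present hidden node `h:2:0` contains its two anticipation
parents and the just-past observation: it straddles two objective times and
holds more past than future members — the asynchronous, imbalanced structure
that keeps the past flowing into the present. In the melody, each anticipated
tone costs ≈ 0.16 nats while the abrupt end costs 2.23 nats (with a fully
deterministic progression the completion costs 0 nats and the abrupt end is
unboundedly surprising). The serial-dependence run shows a significantly
positive attraction of the perceptual estimate toward the previous stimulus,
which vanishes when the carry-over kernel is uniform.

A command-line interface mirrors the library:

```bash
livingpresent graph --order integrated --horizon 4 --depth 2 --out out/
livingpresent demo melody --fidelity 1.0 --noise 0.0 --condition truncated --out out/
livingpresent infer --model model.yaml --obs obs.csv --out out/
```

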