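# evomotif

Higher-order network motifs and rates of fixation in graph-structured
populations.

Evolutionary graph theory represents a population as a graph: each node
is an individual, each edge a possible replacement between neighbours.
Whether a new beneficial mutant takes over — and how long that sweep
takes — depends on the graph's topology. Degree distributions and mixing
patterns (the dK hierarchy's levels 1 and 2) move the *probability* of
fixation; this package is about the next level up: three-node motifs
(wedges and triangles), which tune the *time* to fixation while leaving
the probability essentially untouched. That independent control matters
for directed-evolution and evolutionary-optimization applications, where
the fastest population structure depends on the shape of the fitness
landscape.

`evomotif` provides, for researchers in evolutionary dynamics and
evolutionary computation:

- **Graph generation with motif control** (`evomotif.generate`):
  annealed degree-preserving edge-swap chains that drive a graph's
  global transitivity φ = 3·triangles/wedges to a target, a
  joint-degree-preserving (2K) variant that holds the mixing pattern and
  assortativity *exactly* fixed while tuning φ, and two-degree-class
  graph builders with tunable assortativity.
- **Moran dynamics** (`evomotif.moran`): fast exact stochastic
  simulation of Birth-death (Bd) and death-Birth (dB) updating with a
  mutant of fitness 1+s, Monte Carlo fixation probabilities and
  conditional fixation times with standard errors, frequency-trajectory
  recording, and a brute-force 2^N configuration-chain solver for small
  graphs used as an oracle.
- **Analytic theory** (`evomotif.theory`): the pair-approximation drift
  terms, the inbreeding-like parameter

      F = 1 / ((k−1)(1−φ)),

  under which the mixed-edge frequency equilibrates at
  p_Aa* = (1−F)·p_A·p_a, the diffusion fixation probability
  P(p₀) = (1−e^{−Nsp₀})/(1−e^{−Ns}), the conditional fixation time
  T = T_wm/(1−F) (with T_wm the exact well-mixed Moran chain solution),
  the amplified probability P = (1−e^{−αs})/(1−e^{−Nαs}) for
  degree-heterogeneous graphs, and the dB amplification factor
  α = (E[i])²/E[i²].
- **Evolutionary optimization on graphs** (`evomotif.optimize`): rank
  selection (linear fitness 1+s … 1−s), Bd reproduction with Gaussian
  mutation, a smooth quadratic benchmark and the rugged inverted
  Rastrigin benchmark, with time-to-threshold summaries.

## Worked example

Generate a 5-regular graph of 100 nodes annealed to transitivity 0.3,
estimate fixation statistics for a mutant with s = 0.01 under Bd
updating, and compare with the theory:

```console
$ evomotif netgen regular --n 100 --k 5 --phi 0.3 --seed 7 --out graph.edgelist
wrote graph.edgelist (N=100, E=250, phi=0.2910, r=nan) + graph.edgelist.json

$ evomotif fixation --graph graph.edgelist --rule Bd --s 0.01 --reps 20000 --seed 1 --out est.json
P_MC = 0.015650 +- 0.000878 (n=20000, fixed=313, censored=0)
conditional fixation time = 14871.4 events (148.71 generations)

$ evomotif theory condtime --n 100 --s 0.01 --k 5 --phi 0.3
{"N": 100, "s": 0.01, "k": 5, "phi": 0.3, "units": "events",
 "T": 15039.15, "T_wellmixed": 9668.03, "acceleration": 0.6429}
```

Reading the numbers: the Monte Carlo fixation probability 0.01565 ±
0.00088 agrees with the φ-independent diffusion value
(1−e^{−0.01})/(1−e^{−1}) = 0.015741 — triangles do not move the
probability on regular graphs. The measured conditional fixation time,
14 871 events (one generation = N = 100 events), sits close to the
pair-approximation prediction T_wm/(1−F) = 9668/0.643 = 15 039: at
φ = 0.3 the graph decelerates fixation by the factor 1/(1−F) ≈ 1.56
relative to a well-mixed population of the same size.

The same objects are available as a library:

```python
import evomotif as em

g = em.tuned_regular_graph(100, 5, 0.3, seed=7)
est = em.estimate_fixation(g, em.MoranConfig(s=0.01, rule="Bd"), 20_000, seed=1)
print(est.probability, est.cond_time_events)
print(em.conditional_time_regular(100, 0.01, 5, 0.3))
```

## Layout

| module | contents |
| --- | --- |
| `evomotif.graphs` | motif counting, transitivity, assortativity, edge-swap primitives |
| `evomotif.generate` | random regular / two-class generators, annealed φ and r tuning |
| `evomotif.moran` | Bd/dB simulation, fixation estimates, exact small-graph solver |
| `evomotif.theory` | pair approximation, diffusion formulas, amplification factors |
| `evomotif.optimize` | rank selection, benchmark objectives, optimizer on graphs |
| `evomotif.experiments` | end-to-end study drivers (φ sweeps, correlation, crossover) |
| `evomotif.io`, `evomotif.cli` | edge-list/GraphML/CSV/JSON I/O and the `evomotif` CLI |

See `docs/methods.md` for the model details, parameter defaults and
numerical choices.
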