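# Methods

This note records the models implemented by `evomotif`, the defaults and
the reasoning behind them, the numerical choices, and the known limits
of the approximations. It states nothing the test suite or
`scripts/acceptance.py` does not itself compute.

## Population model

A population of fixed size N lives on an unweighted, undirected, simple,
connected graph; node ids are 0-based contiguous integers. A resident
allele A has fitness 1, the invading allele a has fitness 1+s. One
*event* is one replacement:

- **Birth-death (Bd)**: a reproducer is drawn from the whole population
  with probability proportional to fitness; a uniformly random neighbour
  dies and is replaced by the offspring.
- **death-Birth (dB)**: a uniformly random individual dies; the
  neighbours of the vacancy compete fitness-proportionally to fill it.

A *generation* is N events. All internal times are in events; every
result object exposes a generations accessor, and all theory/simulation
comparisons in the tests are made through dimensionless ratios so that
the unit convention cannot affect them.

The simulator is event-exact (no approximation): it maintains the mutant
set with O(1) sampling and the mixed-edge count incrementally by
scanning only the replaced node's neighbourhood, O(degree) per event.
The kernel also returns the final mixed-edge count so tests can audit
the incremental bookkeeping against a from-scratch recount. Replicates
draw independent sub-seeds from a master seed, so ensembles are
reproducible and embarrassingly parallel. A replicate that hits the
event cap (default 10^8) is reported as *censored*, counted separately,
and never folded into fixation or loss statistics.

### Edge-frequency convention

Edge-type frequencies use the *ordered edge-end* convention:
p_Aa = (# mixed edges)/(2E). Under this convention (and only this one)
the bookkeeping identities p_AA = (1−p_a) − p_Aa and p_aa = p_a − p_Aa
close exactly on regular graphs, where the node frequency equals the
edge-end frequency; on degree-heterogeneous graphs the recorded p_a is
the node frequency and the identities are approximate.

## Structural hierarchy and generators

Graph structure is organised by motif dimension: mean degree (d=0),
degree distribution (d=1), joint degree matrix / mixing (d=2, summarised
by the degree assortativity r, the Pearson correlation of degrees across
edge ends), wedges and triangles (d=3, summarised by the *global*
transitivity φ = 3·triangles/wedges). The global ratio — not mean local
clustering — is used because the pair approximation needs a single
graph-level φ. φ is undefined (NaN) without wedges, r is undefined (NaN)
on regular graphs; NaN is deliberately returned instead of 0.

Two rewiring primitives, both degree-preserving by construction:

- **double edge swap**: (a,b),(c,d) → (a,c),(b,d) (or crossed);
- **2K swap**: only same-degree-type edge pairs, re-paired so each new
  edge joins the same degree classes as before; the joint degree matrix
  — hence degree distribution *and* assortativity — is conserved
  exactly, while the triangle count may change.

Proposals that would create self-loops or parallel edges are re-drawn
without consuming budget (preserving the uniformity of the underlying
swap chain); after every accepted swap a traversal checks connectivity
and reverts the swap if the graph disconnected (the reverted proposal
still consumes budget). Triangle-count changes are computed
incrementally from common-neighbour counts (O(k) per proposal), and the
wedge count is constant under degree-preserving swaps, so φ updates are
exact integers over a constant denominator.

### Annealing schedules

*Gaussian Metropolis–Hastings chain* (regular graphs, and assortativity
tuning): a proposed swap taking φ (or r) from x to x′ is accepted with
probability min[1, P(x′|target)/P(x|target)] where P is a Gaussian
density centred on the target with width σ. Moves toward the target are
always accepted. σ starts at σ₀ = 0.005 and is *grown* by ×1.001 every
N·k proposals; the default budget is k·10⁶ proposals. The growth
schedule makes the early phase nearly greedy and progressively restores
mobility.

σ₀ matters: the chain's stationary distribution balances the Gaussian
factor against the number of graphs at each φ, which decays steeply in
φ. At σ₀ = 0.01 the 5-regular N=100 chain equilibrates ≈ 0.04 *below*
targets ≥ 0.3; at σ₀ = 0.005 every achievable target (φ up to ≈ 0.65
for k=5, N=100) is reached. 0.005 is therefore the default.

*Temperature chain* (2K rewiring on heterogeneous graphs): swaps moving
φ toward the target are always accepted, swaps away with probability γ
(1/γ is the annealing temperature); γ starts at 0.5 and is multiplied by
0.99 every N·k̄ proposals. γ = 0 is a strict hill-climb, γ = 1 accepts
every valid proposal.

Both chains track the best state visited and return it; if the target
was not reached within the budget the best-found graph is returned with
`graph["converged"] = False` and a warning — never silently. An optional
`tol` stops the chain early once |φ−target| ≤ tol; with `tol=None` the
full budget runs and the returned sample is (close to) stationary.
The experiment drivers use the full-budget stationary protocol: greedily
early-stopped graphs systematically carry slightly more higher-order
(4-clique-like) structure at the same φ and measurably longer fixation
times than triangle-level theory predicts.

*Two-class graphs* are built from two independent random regular graphs
wired together by random degree-preserving swaps until connected (≈ 2E
mixing swaps), optionally followed by assortativity annealing; the 2K
chain then tunes φ without touching the mixing. For the 50/50 mixture of
degree-12 and degree-4 nodes this yields mean degree 8 and degree
standard deviation 4 exactly.

## Pair approximation and diffusion theory

For k-regular graphs with transitivity φ, the expected per-generation
changes are

    μ(Δp_a)  = (s/w)·p_Aa,                w = 1 + s·p_a,
    μ(Δp_Aa) = (1/k)·p_Aa·[(k−1)(1−φ)(1 − p_Aa/(p_A p_a)) − 1] + O(s).

Node dynamics are O(s), edge dynamics O(1): under weak selection the
edges equilibrate on the fast timescale at

    p_Aa* = (1−F)·p_A·p_a,    F = 1/((k−1)(1−φ)).

F acts like an inbreeding coefficient: triangles raise the chance that
neighbours share a recent common ancestor, depressing mixed edges.
Substituting p_Aa* gives

- fixation probability P(p₀) = (1−e^{−Nsp₀})/(1−e^{−Ns}) — the
  well-mixed value, independent of φ (regular graphs are isothermal);
- conditional fixation time T(p₀) = T_wm(p₀)/(1−F), where T_wm is the
  *exact* conditional absorption time of the (N+1)-state well-mixed
  Moran frequency chain, obtained by solving (I−Q)h = b for the fixation
  probability and (I−Q)u = h for u = E[T·1_fix] (the Doob h-transform),
  with self-loop transitions kept so times count events. 1−F is the
  *acceleration factor* (well-mixed over structured time); it is < 1 for
  every k ≥ 2, so regular graphs never accelerate fixation, and F ≥ 1
  (e.g. the cycle, k = 2, φ = 0) is flagged as the divergence regime.

For degree-heterogeneous graphs the probability generalises to
P = (1−e^{−αs})/(1−e^{−Nαs}) with an amplification factor α supplied by
the caller; the death-Birth value α = (E[i])²/E[i²] over the degree
distribution is implemented (it is 1 for regular graphs and 0.8 for the
12/4 half-half design). The Birth-death α for heterogeneous graphs comes
from a diffusion system not re-derived here; the parameterised interface
accepts any externally computed value.

Monte Carlo probability estimates carry the binomial standard error
√(P(1−P)/n_MC); conditional times carry the sampling standard error of
the fixing-replicate mean.

### Numerical choices

- Exponential closed forms use `expm1`; the s < 0 branches are
  rearranged so every exponent is non-positive (no overflow up to
  |Ns| ~ 10³ and beyond; relative error < 1e−12 in the supported range).
  s = 0 is handled by the analytic limit, not an epsilon.
- The well-mixed chain solve uses a banded LU (`solve_banded`); the 2^N
  configuration-chain oracle builds a sparse transition matrix and is
  capped at N ≤ 14.
- The exact solver and the chain solve are two independent constructions
  that the tests require to agree to solver tolerance on complete
  graphs.

## Optimization experiments

Each node carries a 2-D genotype. Fitness is the population *rank* of
the objective value, linear from 1+s (best) to 1−s (worst) — mean
fitness exactly 1, constant selection pressure. Reproduction is Bd with
the reproducer drawn rank-fitness-proportionally; every reproduction
mutates either the parent or the offspring (fair coin) with isotropic
Gaussian noise. Ranks are exact at every event: the implementation keeps
the population in an incrementally maintained sort order and draws the
reproducer's rank from the static linear distribution in O(log N). The
initial all-tied order is a uniformly random permutation; subsequent
exact ties are measure-zero. The population-mean objective value is
recorded every N events, and the time-to-threshold is the first recorded
time the mean reaches θ (censored if never, reported separately).

Study conditions (defaults): N = 100, 5-regular graphs, s = 1
(Ns = 100).

- *Quadratic landscape*: 1 − ‖x − x*‖², maximum 1; the functional form
  is a design choice (only "maximum value 1" is pinned externally), with
  the optimum at the origin and the whole population starting at a
  common genotype at distance 1 — (1, 0). Mutation sd 0.012, threshold
  θ = 0.95. Correlation-based summaries are insensitive to the exact
  bowl.
- *Rugged landscape*: inverted Rastrigin, −(10d + Σᵢ(xᵢ² −
  10cos 2πxᵢ)), global maximum 0 at the origin, standard domain
  [−5.12, 5.12]²; mutation sd 0.12 (10× larger — the landscape is much
  slower to traverse). The common start (2, 2) is a local optimum of
  the inverted function several ridges away from the global optimum,
  which places the dynamics in the regime where landscape-hopping
  matters; the start point is configurable.

## Scale of the shipped studies

The test suite and the reproduction script run the full pipelines at
sizes chosen to keep the whole suite in the minutes range while leaving
the Monte Carlo errors small enough for the assertions they make:
fixation ensembles of 50 000 replicates (probability SE ≈ 6e−4 at
P ≈ 0.016), 20 000 replicates per small-graph oracle comparison,
100 optimization replicates per graph for the quadratic time-to-
threshold sweep (6 graphs spanning φ = 0–0.5), 60 replicates over
150 000 events for the rugged-landscape comparison, and 8 000 recorded
sweeps for the mixed-edge plateau. The original study used 10⁷-replicate
fixation ensembles and 500–1000 optimization replicates; the package
reproduces the same quantities at any scale by changing `n_mc` /
`n_replicates`.

## Known limitations

- The pair approximation treats triangles as uniformly spread over
  triples. Its time prediction degrades as F → 1: at k = 5 the measured
  conditional-time ratio T(φ)/T(0) agrees within ~2 Monte Carlo SE (at
  50k replicates) up to φ ≈ 0.4 but sits ~9% above the predicted 1.5 at
  φ = 0.5. The φ-independence of the *probability* shows no such
  degradation.
- The mixed-edge plateau p_Aa/(p_A·p_a) measured mid-sweep deviates from
  1−F by ~3–4% at k = 5 (within the 10% band the tests assert).
- Heterogeneous-graph fixation *times* have no closed form here; only
  the dB probability (via α) is covered analytically.
- The swap chains sample uniformly at fixed φ only for regular graphs;
  for heterogeneous graphs uniform sampling over φ is not guaranteed,
  and the generator's bias toward high-degree triples is inherited by
  anything computed on those graphs.
- The generators emulate the study's synthetic designs (regular and
  two-degree-class graphs). Real interaction networks have broad degree
  distributions, degree–clustering correlations and community structure
  that none of the shipped generators produce, so passing tests
  demonstrate correctness of the machinery and the theory's accuracy on
  these designed ensembles, not on arbitrary empirical networks.
- Mutation during sweeps (clonal interference), weighted or directed
  replacement, and d ≥ 4 motif tuning are out of scope.
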