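# Methods

## Circuit mapping

An undirected network with per-edge conductances $c_{ij} > 0$ (parallel
edges merged by conductance addition, which is exact for resistors) is
treated as a resistor network. For a source–target pair $(s, t)$ a unit
current enters at $s$ and leaves at $t$; Kirchhoff's current law plus Ohm's
law give the Laplacian system $LV = e_s - e_t$ with the target grounded
($V_t = 0$). The production solver grounds one reference node per connected
component, inverts the reduced Laplacian once, and reads every pair's
potentials off column differences of that grounded inverse; the per-pair
interface (`solve_undirected`) additionally offers a Jacobi iteration —
each node's potential repeatedly replaced by the conductance-weighted
average of its neighbours' — kept for cross-validation of the linear
algebra. Jacobi stops only when both the largest potential update and the
worst Kirchhoff residual fall below `tol` (default 1e-10, `max_iter` 1e5).

Directed networks use ideal diodes: arc $u \to v$ conducts with its edge
conductance while $V_u > V_v$ and blocks otherwise (ties carry zero
current; no forward voltage drop is modelled). Every node additionally
carries a ground branch of conductance `ground_conductance` (default 1.0,
exposed because the physics fixes only its existence, not its value) to a
universal sink at potential zero, and the source injects a constant unit
current — the constant-current convention keeps the directed centrality on
the same scale as the undirected one. The solver is a damped Jacobi
relaxation (damping 0.5 by default): a node receiving more current than it
sheds rises in potential and vice versa, with the diode-conducting set
re-evaluated each sweep. The strictly positive ground conductance on the
diagonal makes the update a contraction away from switching boundaries;
damping suppresses chatter at the boundaries themselves. Convergence is
declared on the Kirchhoff residual (max node imbalance below
`tol × injected`), never on the update size alone, and the solution is
verified in the tests against an exhaustive enumeration of all diode on/off
patterns on small instances.

## Scores

**Current-flow centrality.** For interior nodes, throughflow is half the
sum of absolute incident currents; the endpoints are assigned the injected
current itself. This endpoint convention was calibrated on the bundled
two-group example, whose printed centrality table it reproduces exactly to
the published precision; excluding endpoints does not. $C$ averages the
throughflow over all unordered pairs within each connected component
($M = \sum_c n_c(n_c-1)/2$). Directed $C$ averages over all $N$ choices of
source against the ground, counting each node's ground branch among its
incident edges — otherwise Kirchhoff's law at that node would not halve
correctly.

**Accumulated flows and imbalance.** The sweep also accumulates per-edge
absolute currents $T_{ij}$ (for directed networks, opposite arcs merged by
addition) and, per configuration, each node's max-minus-median of incident
absolute currents (even counts take the midpoint of the two middle values;
degree-0 and degree-1 nodes score zero). The pipeline's imbalance index
$D$ is the per-configuration accumulation, normalized by the global
maximum. The alternative of evaluating max-minus-median once on the pooled
totals $T$ is available (`imbalance="accumulated"`, and as the `d_index`
function) but is not the default: a node whose dominant edge *changes* with
the configuration — typical of well-connected hubs that straddle
communities — pools into a flat profile, masking exactly the distinction
the index exists to draw. The per-configuration form scores a bridging node
high whenever *some* edge dominates in each configuration, which is the
physical signature of funnelling. On the karate-club fixture only the
per-configuration form separates the instructor/administrator pair
(D ≈ 0.94–1.0) from the overlapping node 3 (D ≈ 0.46); the pooled form
places node 3 at 0.67 on the bridging side. Whether a node's ground branch
participates in the directed imbalance is configurable and off by default
($D$ is meant to compare network edges).

**Betweenness baseline.** Standard shortest-path betweenness with even
splitting over tied shortest paths, normalized by $(N-1)(N-2)/2$, computed
on the unweighted topology (networkx implementation, cross-checked in the
tests against explicit shortest-path enumeration).

## Key-node rule

Key nodes are the top fraction $q$ (default 0.10) by $C$: the threshold is
the score of the $\lfloor qN \rfloor$-th ranked node (at least one), i.e.
the point where the empirical CDF of $C$ reaches $1-q$, and all nodes tied
with the threshold (relative tolerance 1e-9, which captures exact
symmetries) are included — favouring recall of connectors. If every node
scores identically the key set is empty with a warning. Classification:
normalized $D \ge$ `d_threshold` (default 0.5) is bridging, else
overlapping. No principled universal threshold exists — communities
themselves are only implicitly defined — so both knobs are declared
heuristics; a 2-means split of the key nodes' $D$ values is available as an
alternative classifier. The quantile is applied globally on disconnected
inputs.

## Synthetic generators

`generate_two_group_toy` builds two mirrored groups (hub adjacent to all
group members, gateway adjacent to hub and the two mid nodes, remaining
nodes on a path between the mids), joins the gateways directly and through
a central connector, and marks the connector in the truth. The direct
gateway–gateway edge puts the connector off every shortest path, so its
betweenness is exactly zero while its current flow is not — the
betweenness-blindness construction. At `group_size=6` it reproduces the
bundled 13-node fixture node for node.

`generate_planted_network` draws dense Bernoulli community blocks
(defaults: four communities of 25 at within-community probability 0.3) and
plants the connectors explicitly: bridging nodes are ordinary members given
exactly `bridging_out_degree` (default 2) uniform cross edges, overlapping
nodes are additional nodes given `overlap_degree_per_community` (default 4)
edges into each of two host communities. The background cross-edge
probability `p_out` defaults to **0**: the generator emulates networks
whose communities communicate *only* through connector nodes, so that the
planted labels coincide with the network's actual connectors. With a
positive `p_out`, background cross edges become unlabelled connectors in
their own right and ground-truth recovery is no longer a well-posed check
(the parameter is exposed for exactly such robustness experiments).
Cross-edge targets are resampled under the seed until the network is
connected.

`generate_lfr_like` produces heterogeneous benchmarks: degrees sampled from
a discrete power law with exponent `tau1` truncated to
$[\,$`min_degree`$, \sqrt{n}\,]$ (truncation keeps desk-scale instances
manageable and near-connected), community sizes from a power law with
exponent `tau2`, a fraction `mu` of each node's stubs matched across
communities and the rest within, rejecting self-loops and parallel edges
with bounded retries (a few stubs may be dropped). Repository defaults
`tau1=2`, `tau2=1`, `mu=0.1` are the standard values of the benchmark
literature. The truth marks nodes with cross edges as bridging; no
overlapping membership is planted — by construction this family separates
communities by edge mixing, not by shared nodes.

All generators are driven by one integer seed through a single
`numpy.random.Generator` and are reproducible bit for bit.

## What the synthetic tests do and do not show

The planted-recovery suite (50 seeds at generator defaults; ~100-node
networks, so the full sweep of ~5×10³ configurations per replicate stays
fast) checks that planted connectors land in the top-decile $C$ set, that
planted bridging nodes' mean normalized $D$ exceeds the planted overlapping
nodes', and that threshold classification is mostly correct. Passing these
shows the indices behave as designed when communities are dense,
comparable in size, and joined only through connectors. Real networks have
degree heterogeneity, nested and fuzzy communities, and connectors of mixed
character; there the method ranks candidates rather than certifies them,
and the bundled karate-club analysis is the more honest indicator of
real-data behaviour.

## Numerical choices and limitations

* Direct solves use dense inversion of the reduced Laplacian per component;
  this is exact to machine precision and fine to a few thousand nodes, but
  the all-pairs sweep is $O(N^2 E)$ overall — the method is meant for
  networks of that scale, not millions of nodes. (Note: `numpy.linalg.pinv`
  with its default cutoff can fail to truncate a graph Laplacian's null
  singular value; the package never relies on it.)
* The all-pairs sweep is exact, not sampled; pair subsampling is out of
  scope.
* Node labels are strings throughout; numeric labels keep their textual
  form and sort naturally in all outputs.
* Ties at the key-node threshold are resolved inclusively; ties in diode
  potentials carry zero current.
* The directed relaxation is a heuristic fixed-point scheme; it is
  validated against exhaustive diode-state enumeration on small instances
  and always reports its final residual, but no global convergence proof is
  claimed for adversarial instances.
* Multigraph semantics beyond parallel-edge merging, attribute-rich
  GraphML, complex impedances and non-ideal diode models are out of scope.
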