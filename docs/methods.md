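# Methods

## Problem and model

A genome-scale metabolic model (GEM) describes a cell's metabolism as a set
of reactions over metabolites. With `n` internal metabolites and `m`
reactions, the stoichiometric matrix `N` has `N[i][j]` equal to the signed
coefficient of metabolite `i` in reaction `j`. At steady state the net
production of every internal metabolite is zero, `N v = 0`, and each flux is
confined to bounds `lb_j <= v_j <= ub_j` (here in μmol·100g⁻¹·min⁻¹).
Classical flux balance analysis (FBA) picks one flux vector from this
polytope by maximizing a stated cellular objective (typically biomass). For
differentiated human cells such as adipocytes no single objective is
defensible, so this package instead fits the flux pattern to condition-level
gene expression: the expression of the genes catalyzing a reaction is treated
as a noisy readout of that reaction's activity, and the fit finds the
steady-state flux vector whose activity pattern agrees best with it. The
fitted fluxes then induce condition-specific directed networks whose
topology is compared between two conditions (e.g. lean vs obese donors,
preprandial vs postprandial exchange constraints).

## Expression summarization and GPR mapping

Each condition is summarized per gene as the arithmetic mean and sample
standard deviation (n−1 denominator) of the group's expression values.
Gene–protein–reaction (GPR) boolean rules map genes to reactions:

- **AND** (enzyme complex): the value is the minimum over children — the
  scarcest subunit limits capacity. The SD of the limiting child propagates.
  If any child is unmeasured the reaction is treated as unmeasured.
- **OR** (isoenzymes): the default is the **sum** over measured children —
  isoenzyme capacities add. SDs combine as the root sum of squares.
  Unmeasured branches are dropped. `max` and `mean` variants are available
  through the `gpr_policy` config (`min_sum` default, `min_max`, `min_mean`).

This yields per-reaction data `d_j >= 0` (expression units) and a weight
`w_j = 1 / max(sd_j, 1e-6)`: precisely measured reactions pull harder on the
fit. Reactions with no GPR (exchanges, spontaneous reactions) carry no data.

## The flux fit

The fit is a weighted L1 regression of reaction *throughput* onto the
expression data under the steady-state and bound constraints:

1. Every reaction is split into non-negative forward/backward components,
   `v_j = v_j⁺ − v_j⁻`, and the throughput is `t_j = v_j⁺ + v_j⁻` (the
   unsigned activity level that expression can plausibly report on).
2. The core linear program is

       minimize    Σ_{j measured} w_j · | t_j − d̂_j |
       subject to  N v = 0,   lb <= v <= ub,

   solved with HiGHS via `scipy.optimize.linprog` (residuals are encoded
   with the standard auxiliary-variable trick, so the problem stays linear
   and deterministic).
3. Expression units are arbitrary, so the data scale is re-estimated between
   solves: after each LP, `d̂ <- d̂ · (Σ w t d̂)/(Σ w d̂²)` (the weighted
   least-squares projection of the data scale onto the current throughputs),
   and the LP is repeated until the Spearman rank correlation ρ between
   throughputs and data changes by less than `rho_tol`, or `max_iter` is hit.
4. Among optima of the final LP, a lexicographic second stage returns a
   deterministic point: by default the solution minimizing total throughput
   (parsimonious flux, which also removes futile forward+backward flux on
   reversible reactions); a `least_squares` variant instead minimizes
   `Σ (t_j − d̂_j)²` on the optimal face (solved with SLSQP from the LP
   vertex; intended for small models and degenerate-segment cases).

Rank (Spearman) correlation is the default agreement measure because fluxes
and expression live on incommensurable scales; Pearson is available via
config. Fewer than three measured reactions leave the correlation undefined,
in which case the single weighted L1 solve is returned as-is.

### Data scaling options

`FitOptions.data_scaling` controls the initial placement of the data on the
flux scale:

- `"none"` (default): `d̂ = d`. The iterative rescale in step 3 adapts any
  magnitude mismatch within a few iterations. This keeps hand-constructed
  flux-scale data exactly as given, which is what every worked example in
  the test suite assumes.
- `"median_range"`: a one-off pre-scale matches the median data value to the
  median midpoint of the measured reactions' achievable throughput ranges
  (computed by per-reaction flux-variability LPs). This makes the final flux
  solution exactly invariant to multiplying all expression values by a
  positive constant, which is the right behavior for raw microarray/RNA-seq
  intensity scales.

### Numerical choices

- `steady_tol = 1e-6` (max |N v| on any returned solution), `lp_tol = 1e-9`
  (objective cap slack in the tiebreak stage), `active_tol = 1e-6` (a flux
  below this is "zero": inactive in graphs and flux-change classification).
- Before ranking, throughputs are quantized at `active_tol` so that genuine
  ties broken only by solver round-off (≈1e-15 relative) still rank as ties.
- Forward/backward complementarity (`v⁺·v⁻ = 0`) is not imposed in the LP;
  the parsimonious stage removes futile two-way flux unless the data demand
  extra throughput on a reversible reaction, in which case a warning is
  logged and the throughput (not the net flux) carries the excess.
- Reactions with no data are determined only up to alternative optima of the
  fit; recovery metrics are therefore computed over data-carrying reactions,
  while the hand fixture (whose optimum is unique) is checked flux-by-flux.
- Infeasible constraint systems (e.g. clamps that contradict mass balance)
  raise an error naming the stage and, when detectable, the conflicting
  bounds.

## Measured exchange constraints

Clinically measured exchange rates (e.g. glucose uptake and triacylglycerol
extraction at a given time point) enter as bound clamps: the named reactions'
lower and upper bounds are replaced by the measured value (point clamp
`[x, x]`) or by an interval such as `[mean − SD, mean + SD]`. Constraint sets
are keyed by time-point label (e.g. `tp4` preprandial, `tp5` postprandial)
and are always user inputs, never defaults.

## Condition networks

From a fitted solution, reactions with `|v| <= zero_tol` (default 1e-6) are
removed and every remaining reversible reaction is oriented by the sign of
its flux (negative flux swaps products and reagents). The **reaction graph**
has active reactions as nodes and a directed edge `p -> c` whenever `p`
produces and `c` consumes a shared metabolite under the effective
orientation; the edge records all shared metabolites. Isolated active
reactions remain as nodes, since node-presence comparisons count them.
Ubiquitous currency metabolites are excluded from edge construction to avoid
biologically meaningless shortcuts (every path would otherwise run through
ATP or water). The default list — H2O, CO2, O2, ATP, ADP, AMP, Pi, PPi,
NADH, NAD+, NADPH, NADP+, FADH2, FAD, H+, CoA — is a versioned config, not a
claim about any published analysis; ids match by compartment-stripped base
name in any compartment. Removing a name from the list can only add edges.

The **gene graph** replaces each reaction by the genes in its GPR: every
reaction edge `a -> b` expands to gene edges `g -> h` for all `g` regulating
`a` and `h` regulating `b` (all genes in a GPR count as regulating,
regardless of AND/OR position; self-edges are excluded; reactions without
GPRs bridge nothing).

## Differential topology

Two condition graphs of the same kind merge into a union **reference
network**; every node and edge is labeled `both`, `A_only`, or `B_only`.
Three summaries are computed:

- **Shortest-path distribution**: unweighted directed BFS from every node;
  the histogram counts ordered reachable pairs per finite length ≥ 1
  (unreachable pairs are excluded, not infinite); the modal length breaks
  ties toward the smaller length.
- **Rewiring (Dn) scores** for nodes present in both conditions: incident
  union edges (in and out pooled) each contribute the population variance of
  their presence indicator across the two states — 0.25 if present in
  exactly one condition, 0 if in both — summed into `dn_raw`, with
  `dn_degree_corrected = dn_raw / union degree`. For two states this equals
  0.25 × |symmetric difference of incident edge sets|. This reimplements the
  published description of the DyNet rewiring metric ("changes in the
  identity of interacting neighbours"); numerical agreement with the DyNet
  Cytoscape app is not claimed, since its normalization details are not
  published. Nodes present in only one condition are membership signals, not
  rewiring signals, and receive no score.
- **Flux fold changes**: per reaction, reversible reactions running in
  opposite directions in the two conditions are flagged (both active, signs
  differ), and active pairs are classified by `log2(|v_B| / |v_A|)` against
  a fold-change threshold (default 2) into lower_in_B / higher_in_B /
  unchanged; pairs inactive in either condition are "inactive".

Rankings are deterministic: `dn_raw` descending, ties by node id.

## Synthetic data: what it emulates and what it does not

Real inputs (a curated human GEM, microarray group summaries, clinical
exchange fluxes) require downloads and are never bundled; the
`synthetic_data` module generates desk-scale stand-ins with known ground
truth:

- `fixture_model()`: a hand-specified 7-reaction network (clamped uptake,
  a branched interior reconverging through a reversible bridge, an ATP/ADP
  currency couple with a gene-less recharge reaction) with an exactly
  balanced flux vector. All worked examples in the tests are hand-derivable
  on it.
- `make_toy_gem(spec)`: seeded random networks built as a backbone chain
  from an uptake to a sink plus random forward branches and currency-coupled
  reactions. The ground truth superposes one random positive source-to-sink
  path flow per internal edge, so `N v = 0` holds to machine precision and
  every reaction is active. Default shape: 8 internal metabolites, 20
  reactions, 20% reversible, one currency couple, one gene per reaction.
- `make_expression_from_flux`: gene means solved greedily from the GPRs so
  the default policy reproduces `|v_true|` per reaction (exact for private
  genes), then perturbed with multiplicative gaussian noise
  (`sd = noise_sd_frac × mean`, microarray-like); the profile's `sd` field
  records that noise level. Defaults used in validation: 5% noise for
  end-to-end recovery, 10% for fit robustness.
- `make_condition_pair`: plants knockouts by zeroing the knocked reactions'
  gene expression (not by deleting bounds), so a loss must propagate through
  the fit to disappear from the network; the knocked flux is rerouted
  through the remaining paths by a minimal-L1 rebalancing LP with exchanges
  held at their ground-truth rates. A global `scale_b` factor emulates an
  overall metabolic slowdown.

What passing these tests shows: the fit recovers planted activity patterns
under modest multiplicative noise, the graph rules are implemented exactly
as specified, and planted presence/rewiring differences survive the full
pipeline. What it does not show: performance on genome-scale models
(thousands of reactions, extensive alternative optima, incomplete GPRs),
robustness to microarray normalization artifacts, probe-to-gene mapping
noise, or biological correctness of any specific currency list.

## Validation problem sizes

The validation suite and the reproduction script run entirely on generated
inputs: the 7-reaction fixture, a 2-free-dimension clamped toy checked
against a 0.01-step grid-search oracle, 20 seeded random GEMs of 20–25
reactions for conservation/recovery checks, and 20 seeded end-to-end
knockout-recovery trials at 5% noise. These sizes keep every check exact or
statistically stable while the whole suite runs in seconds.

## Known limitations

- The iterative rescale adapts the data's magnitude but not its shape; badly
  mis-scaled heavy-tailed data may converge to a rank-suboptimal fixed point.
- The `least_squares` tiebreak uses a dense SLSQP solve and is not intended
  for genome-scale models.
- Gene-level graphs treat every GPR gene as regulating its reaction; AND/OR
  structure does not weight the expansion.
- The Dn score is the two-state variance form; multi-state (>2) comparisons
  are out of scope.
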