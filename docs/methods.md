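# Methods

## The model

`dhcnet` treats every continuous measurement — transcript intensity
(red/green ratio), metabolite concentration, respiration rate, experimental
setup parameter — as a node of a Bayesian network over samples. A network
is a DAG in which each child *y* follows a linear-Gaussian local model

    y = β₀ + Σ_j β_j x_j + ε,   ε ~ N(0, σ²),

with parents *x_j* drawn from the other continuous variables. Discrete
variables are never nodes. They enter as **modulators** of a local model:

* *switched-conditional*: parent terms are multiplied by the indicator of a
  binary modulator's active level — the relationship exists only while the
  switch is on (e.g. while a chlorinated substrate is being respired, or
  while a metabolite is above detection: censoring switches are modulators
  like any other discrete variable);
* *linearly-conditional*: a separate slope per modulator level, for tiered
  operators such as the electron-acceptor type.

All continuous data are eighth-root transformed before inference. The
transform is monotone, compresses the heavy right tail of intensity and
concentration data toward something a Gaussian local model can fit, and is
gentler than a log around zero, which matters because censored values are
pinned at small positive detection limits (10⁻⁴ when no limit is defined;
10⁻⁴^(1/8) ≈ 0.316 on the analysis scale). Values *at* the detection limit
are treated as censored (switch 0); the boundary convention is ours.

## Fragment scoring

A *fragment* is one child plus one parent set (size ≤ `max_parents`,
default 3 — consensus networks in this domain run well under one edge per
node, so small in-degree suffices) plus an optional (modulator, class)
annotation. Each fragment is fitted by OLS and scored with

    score = log L̂ − (q/2) · log n,

the BIC-penalized maximum Gaussian log-likelihood, where q counts the
regression coefficients plus the noise variance. A conjugate alternative
(Zellner g-prior marginal likelihood, g = n, flat on intercept and σ²) is
available via `score="marginal"`; BIC is the default because it is
parameter-free and score-equivalent across DAGs in the same Markov
equivalence class. The ML variance is floored at 1e-12 so noiseless
fixtures stay finite. Rank-deficient designs (duplicated parents) raise a
degenerate-fit error and are skipped during enumeration.

Per child, all parent sets up to the cap are crossed with
{no modulator} ∪ {each discrete variable × each enabled class}
(switched requires a binary modulator). Only the top `top_fragments`
(default 200) fragments per child are kept for sampling — the empty
fragment always survives so every child can be parentless; exhaustive
retention (`top_fragments=None`) backs the enumeration oracle. A causal-
ordering prior forbids transcripts as parents of setup parameters;
conditions may drive conditions and transcripts.

## Ensemble sampling

A network is a choice of one fragment per child whose union is acyclic;
its unnormalized posterior weight is the product of exp(score) over the
chosen fragments (uniform prior over structures under the in-degree cap).
The sampler is a Gibbs-style structure MCMC:

* a **sweep** visits children in random order and resamples each child's
  fragment ∝ exp(score) among fragments keeping the graph acyclic;
* after each sweep, **blocked two-child updates** (default 6) jointly
  resample a random pair of children over all acyclic fragment
  combinations. These are essential: single-child updates cannot cross
  between structure modes that require coordinated changes (reversing an
  edge inside a Markov equivalence class, trading a collider for a
  covering edge), and without them ensemble frequencies deviated from the
  exact posterior by up to 0.22 on adversarial 4-variable fixtures; with
  them the worst deviation over twenty random datasets is ≈ 0.03–0.04 at
  M = 1,000 (the Monte-Carlo floor alone is 3·√(0.25/1000) ≈ 0.047).

Each of the M = 1,000 ensemble members is the end state of an independent
chain started from the empty network with burn-in 100 sweeps, so members
are exchangeable and the whole ensemble is reproducible from a single
seed (sub-seeds come from `numpy.random.SeedSequence`). The inner loop is
JIT-compiled (numba) over uint64 adjacency bitmasks for graphs of ≤ 63
nodes, with a pure-Python big-integer fallback above that.

**Frequency accounting.** Within one network a node pair is linked by at
most one fragment annotation, and acyclicity forbids both orientations, so
frequencies are tallied per *unordered pair × (modulator, class) variant*
and lie in [0, 1]. Curves and consensus extraction aggregate variants per
pair (the pair is linked either way); conditional-edge reports use the
per-variant table. Pair-level accounting is deliberate: a Gaussian
likelihood cannot orient most edges (score equivalence), so directed
frequencies would split orientation-equivalent mass and cap an isolated,
perfectly supported edge at f ≈ 0.5. The reported sign r is the Pearson
correlation of the two variables on the transformed data across all
samples — a property of the data, not the ensemble.

**Validation oracle.** For ≤ 5 variables with an exhaustive library,
`exact_edge_posterior` enumerates every fragment assignment (543 labeled
DAGs at 4 nodes, 25 at 3), weights acyclic ones by their fragment-product
posterior, and returns exact inclusion probabilities. The sampler is
checked against it in the test battery; the oracle shares no code with the
sampling path.

**Forward simulation.** `simulate_from_ensemble` draws members uniformly,
bootstraps discrete modulator rows from the observed data, and simulates
the fitted local models in topological order — the "forward" half used for
sanity-checking implied covariances against Gaussian path rules.

## Consensus extraction

E(f) and N(f) are counted exactly on a cutoff grid (floor 0.001, step
0.01). The slope of E(f) is a central difference of a moving-average
smoothed curve (window 5 grid steps). The consensus cutoff f\* minimizes
|slope| inside a search window (default [0.2, 0.9]): E(f) is
nonincreasing, so the raw most-negative slope always sits in the
false-positive mass near f = 0; the informative feature is the plateau
before the high-confidence edges. Ties — including exactly flat stretches
— resolve to the smallest cutoff, which is conservative toward larger
networks. The threshold is inclusive (f ≥ f\*), nodes are the endpoints
of retained edges, and `edges_per_node = |E|/|N|` (0.72 and 0.85 at the
two study-scale layouts the tests reconstruct from printed counts).

## Strain analysis

Probes carry percent identity to each lineage representative
(Cornell/Victoria vs Pinellas in the motivating system). A probe is
assigned to the single lineage with identity ≥ 85% (inclusive); two
qualifying lineages → ambiguous, none → unassigned; both are excluded from
within/between tallies, as are edges touching non-probe nodes.
Correlograms order probes by ortholog bin, then lineage, then id, and
compute Pearson r on log intensities — the same scale the ortholog
collapse uses (the study figures do not state their scale; log is the
natural one for ratio data). Zero-variance probes yield missing
correlations; the diagonal stays 1.

## The synthetic generator

`SimulationConfig` defaults emulate the study conditions the pipeline
targets: a few dozen samples (default 48; the motivating datasets have 47
and 24), sparse DAGs (edge density 0.1 → ≈ 0.1·n(n−1)/2 edges), effect
sizes drawn uniformly from ±[0.5, 1.5] with child noise σ = 0.5 (chosen
once so edges are detectable but not trivial at n ≈ 24–48), balanced
binary modulators plus optional ≥ 3-level tiered ones, and censoring
applied only to metabolite-like variables (transcripts are never
below-detection after filtering, mirroring the real pipeline). Detection
limits are the empirical `censor_fraction` quantile of each metabolite, so
censoring is value-driven. The probe layer spawns `probes_per_node` probes
round-robin across lineages — lineage 0 reports the latent signal, other
lineages an independent program standing in for a co-resident strain —
with intensity = 200·exp(latent + probe noise) + background
(N(50, 10) by default, truncated at 0), each probe printed in ≥ 4 replicate
spots; identity annotation draws target lineage from U(95, 100) and
off-target from U(60, 80), straddling the 85% cutoff. Everything is a pure
function of the seed.

What the generator does **not** emulate: scanner optics, dye bias and
LOESS-removable spatial trends (inputs are assumed normalized; a smoother
is out of scope), heavy-tailed or count-like expression noise,
autocorrelated time-series structure, and latent confounders. Passing the
synthetic battery therefore shows the machinery is correct and calibrated
under its own assumptions, not that real arrays satisfy them.

## Measured calibration (what the tests assert)

* Sampler vs exact posterior: max |f − posterior| ≤ 0.05 over twenty
  4-variable, 30-sample datasets at M = 1,000 (measured ≈ 0.036).
* Structure recovery: mean precision ≥ 0.8 and recall ≥ 0.5 at f ≥ 0.6
  over ten 20-node, 48-sample planted DAGs (measured ≈ 0.83 / 0.93 at the
  committed seeds; other seed batches range ≈ 0.78–0.88 for precision —
  the false positives are distance-2 shortcut pairs with genuine posterior
  support at this sample size, not sampler artifacts).
* Conditional recovery: a planted switched edge (n = 48, balanced binary
  switch, effect 1.0) is reported as conditional (switched + linearly-
  conditional mass on the true modulator) at f ≥ 0.6, with the plain
  variant below 0.6, in ≥ 8/10 seeds (measured 9–10/10; for a binary
  switch the linearly-conditional form nests the same on/off model, which
  is why variant mass is pooled).
* Cutoff detection: on a beta-mixture of edge frequencies the detected f\*
  lands within ±0.05 of the analytic density minimum.
* Preprocessing: filter survivors and collapse representatives equal
  independent brute-force implementations exactly; collapse is idempotent
  (single-linkage components make cross-cluster correlations ≤ r_min by
  construction).

Problem sizes (4-variable oracles, 20-node recovery, M = 1,000) are the
package's benchmark protocol: large enough to exercise every code path and
small enough that the whole battery replays in minutes.

## Known limitations

* Orientation is not reported; only pair-level relationships with signs.
  With purely observational Gaussian data this is a property of the model
  class, not of the implementation.
* BIC at n ≈ 48 admits distance-2 shortcut edges at non-trivial
  frequency; the f ≥ 0.6 consensus accepts a ≈ 10–20% false-positive rate
  in exchange for high recall, consistent with the cutoff's design intent.
* The exhaustive oracle is limited to five variables; beyond that the
  sampler is validated only indirectly (acyclicity, seed reproducibility,
  frequency normalization, planted-structure recovery).
* Chains are finite; residual mixing bias on adversarial posteriors is
  bounded empirically (oracle battery), not theoretically.
* The GEO series-matrix reader parses the value block and sample metadata
  only; platform annotation tables must be supplied separately.
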