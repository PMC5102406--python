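# dhcnet

Ensemble Bayesian gene-network inference for mixed transcript, metabolite
and culture-condition datasets — built around the kind of data produced
when organohalide-respiring communities of *Dehalococcoides mccartyi*
(*Dhc*) are monitored with two-color microarrays across many feeding,
stress and starvation conditions.

For a non-model organism where most genes are hypothetical and genetics is
intractable, network inference on perturbation series is one of the few
ways to attach hypotheses to unannotated genes. `dhcnet` implements the
whole chain for that setting:

1. **Preprocessing** — replicate array spots are geometrically averaged
   per probe; probes that never rise two standard deviations above
   background fluorescence are dropped; on pangenome arrays (several
   probes per ortholog across strain genomes) probes whose expression
   correlates at r > 0.9 within an ortholog bin are collapsed onto the
   brightest representative. Metabolite values at or below detection are
   replaced by the detection limit (or 10⁻⁴) with a paired *censoring
   switch* set to 0, and every continuous variable is eighth-root
   transformed.
2. **Fragment scoring** — for every continuous child variable *y* and
   candidate parent set *X* (|X| ≤ K, default 3), the local linear-Gaussian
   model *y = β₀ + βᵀX + ε* is fitted and scored with the BIC-penalized
   log-likelihood, score = log L̂ − (q/2)·log n. Discrete variables
   (censoring switches, binary culture-state operators, tiered
   electron-acceptor codes) never become nodes; they *modulate* fragments:
   **switched-conditional** (parent terms enter only where a binary switch
   is at its active level) or **linearly-conditional** (one slope per
   modulator level).
3. **Ensemble sampling** — M = 1,000 acyclic networks are drawn by
   structure MCMC over fragment assignments (Gibbs sweeps plus blocked
   two-child updates; each network is the end state of an independent
   chain). The strength of a relationship is its frequency
   f = (networks containing it)/M, tallied per node pair and per
   conditional variant; the sign r is the plain Pearson correlation of the
   two variables across all samples.
4. **Consensus** — edge and node counts are scanned against the cutoff;
   the consensus cutoff f\* sits where |dE/df| is minimal (the plateau
   between low-f false-positive mass and the high-confidence edges,
   typically near 0.6). Consensus networks export to XGMML/GraphML/TSV,
   support k-hop neighborhood queries, and can be resolved into
   within-/between-strain-lineage edges using percent-identity probe
   annotation (85% cutoff).

A first-class synthetic-data generator (`dhcnet.synth`) produces ground
truth DAGs, conditional edges, censored metabolites, and probe/spot-level
redundancy with background noise, so every stage is testable end to end
without downloads; `dhcnet.benchmarks` packages the validation protocols,
including an exhaustive-enumeration posterior oracle for graphs of up to
five variables.

## Worked example

`examples/01_simulate_and_recover.py` plants a 12-node network, simulates
48 samples, and infers the consensus:

```
planted edges:   9
consensus edges: 11 at f >= 0.6 (11 nodes, 1.00 edges/node)
precision 0.82  recall 1.00

top relationships (f = fraction of the 1,000 networks; r = sign of the correlation):
  v000 -- v006   f=1.000  r=+0.91
  v000 -- v010   f=1.000  r=-0.93
  v001 -- v008   f=1.000  r=+0.77
  v002 -- v004   f=1.000  r=-0.53
  v004 -- v005   f=1.000  r=+0.79
```

All nine planted relationships are recovered (recall 1.00); the two extra
edges are distance-2 shortcuts that the data genuinely support at this
sample size. `f=1.000` means the relationship appeared in every one of the
1,000 sampled networks; the sign of `r` distinguishes positive from
inverse co-expression (dashed vs solid edges in the usual drawings).

The other examples walk the preprocessing chain (`02`), conditional-edge
detection (`03`), cutoff selection and XGMML export (`04`), and strain
deconvolution with correlograms (`05`); each prints a short, annotated
summary.

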