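# ictonet

Stage-wise dynamic Bayesian network (DBN) inference of functional brain
connectivity across acute seizure induction.

## The problem

During controlled pentylenetetrazole (PTZ) infusion, a rat's brain passes
through well-defined stages — basal state, infusion, myoclonic seizure
(MYO) and, in part of the cohort, generalized tonic-clonic seizure (GTCS).
Multichannel local-field-potential (LFP) recordings from thalamus (TH),
dorsal hippocampus (HP) and parietal cortex (CX) at 1 kHz capture how the
coupling between these areas reorganizes along the way.  `ictonet` treats
each (channel, stage) pair as one random variable of an unrolled DBN and
asks, purely from data: *which directed dependencies between brain areas
are consistently supported across animals, and how do they change from the
basal state to the seizure?*

## The method

For each animal *k* of a cohort of *K*:

1. **Segmentation** — channels are cut into stage epochs at the annotated
   onsets (half-open sample intervals; the post-GTCS refractory period is
   discarded) and linearly resampled to the length of the animal's longest
   stage, giving a variable table with `#channels × #stages` columns
   (12 for a GTCS-group animal, 9 for a MYO-group animal).
2. **Adaptive discretization** — each column is quantized with Knuth's
   Bayesian optimal equal-width binning, maximizing
   `N ln M + lnΓ(M/2) − M lnΓ(½) − lnΓ(N+M/2) + Σ_k lnΓ(n_k+½)`
   over `M ∈ {1..128}` (a 7-bit cap).
3. **Structure learning** — a DAG `G_k` over the (channel, stage) variables
   is learned by random-restart hill climbing on the BDeu score
   (equivalent sample size α = 10 by default), under acyclicity and
   temporal precedence (no arc from a later stage into an earlier one),
   with a budget of candidate-move score evaluations (10⁶ by default) as
   the stop criterion.

The *K* replicate DAGs are then model-averaged: for every node pair the
states →, ← and *absent* are counted over the replicates containing both
nodes, and a directed arc is accepted into the consensus iff its frequency
reaches the analytical threshold

    f = 1/3 + 2/K

evaluated against the pair's *effective* K (GTCS variables exist only in
the GTCS group).  Sub-threshold "gray" arcs are retained for reporting, and
a stage-level projection of the consensus shows which stages carry
information into which later stages.

Because the raw recordings of the study this emulates are not public, the
package ships a first-order vector-autoregressive cohort simulator that
plants per-stage directed coupling (the published consensus pattern by
default: TH→HP with a bidirectional TH↔CX loop preictally; CX→TH→HP during
GTCS) and cross-stage carry-over, with known ground truth for validation.

## Worked example

```sh
ictonet run-all --out results/demo --seed 1 --scale 0.05 \
    --max-iterations 100000
```

generates the default 21-animal cohort (11 reaching GTCS) with stage
durations scaled to 5 %, learns one DAG per animal and prints

```
K=21, f=0.4286, 11 accepted arcs -> results/demo
```

`results/demo/report.json` then contains, among others:

```
"threshold_global": 0.42857142857142855,      # f at K=21
"threshold_gtcs_group": 0.5151515151515151,   # f at K=11 (GTCS pairs)
"accepted_arcs": { "CX_gtcs->TH_gtcs": 9, "TH_gtcs->HP_gtcs": 10,
                   "TH_infusion->HP_infusion": 20, ... }
```

Read: the arc CX→TH inside the GTCS stage appeared in 9 of the 11 animals
that reached GTCS (frequency 0.82 ≥ f = 0.52, accepted), and the
stage-level projection (`slice_graph.json`) shows the chain
basal → infusion → myo → gtcs with **no** direct basal → gtcs edge — the
qualitative finding that GTCS dynamics are not explained by the basal
state.  `arc_frequency_table.csv` is the per-group arc table and
`arc_histograms.csv` holds the per-stage frequency-vs-threshold data; DOT
and GraphML exports accompany every graph.  Each stage is also available
as its own subcommand (`simulate`, `preprocess`, `discretize`, `learn`,
`consensus`, `report`).

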