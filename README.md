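# logicpath

Perturbation-effect prediction on logic-graph pathway networks.

A *logic network* is a signed directed graph derived from a curated pathway:
edges carry a polarity (activating `+` / inhibiting `-`) and each node
combines its incoming edges under `AND` or `OR` logic. Root inputs are nodes
the pathway never produces (in-degree 0); terminal outputs are nodes it never
consumes (out-degree 0). Given a bidirectional perturbation of a single root
input (up- or downregulation), the package predicts the response of key
output nodes two ways and scores both against observed outcomes:

- **Path-parity rules** (`logicpath.curator_rules`) — enumerate the simple
  directed paths from root to output; a path with an even number of
  inhibitory edges transmits the perturbation direction, odd parity inverts
  it; no path or an even/odd tie means no change, and >2 paths are decided by
  majority vote.
- **Constraint-based activity propagation** (`logicpath.mpbiopath_core`) —
  every node carries a continuous activity in [0.01, 100] (1 = normal).
  AND fan-ins multiply their inputs (reciprocals for inhibitory edges), OR
  fan-ins average them. Each node has a paired input-side/output-side value
  and the solver minimizes the total disagreement between the pairs, so
  inconsistent systems (feedback loops, saturation) still solve. Internally
  the model is solved in log10 space with `scipy` (an LP for pure-AND /
  geometric-OR instances, SLSQP for the raw-arithmetic OR average).

Around these two predictors:

- `logicpath.logic_network` — the data model, TSV logic-table I/O, role
  inference and bidirectional test-case enumeration.
- `logicpath.synthetic_networks` — seeded generators of layered networks
  (negative-edge / OR-gate / skip / feedback probabilities, entity-set
  fan-in) with ground truth from an independent brute-force path oracle.
- `logicpath.calibration` — discretization of continuous activities into
  up / down / no change and cutoff sweeps that pick the F1-optimal threshold
  (ROC points included).
- `logicpath.evaluation` — direction-aware confusion matrix (false positives
  in the wrong direction tracked separately), pooled and averaged metrics,
  percent agreement, Cohen's and Fleiss' kappa, stratified summaries.

## CLI

```sh
# generate a seeded synthetic network + oracle ground truth
logicpath synth --seed 1 --layers 4 --width 3 --p-neg 0.25 \
    --out net.tsv --truth cases.tsv

# path-parity predictions (adds predicted_class, shortest_path_length)
logicpath curator --network net.tsv --cases cases.tsv --out predictions.tsv

# continuous activity propagation under a perturbation
logicpath mpbiopath --network net.tsv --perturb N00_00=up \
    --or-mode arithmetic_raw --objective l1 --out values.tsv

# cutoff sweep against reference classes
logicpath calibrate --pred continuous.tsv --ref classes.tsv \
    --grid default --out sweep.tsv

# confusion-matrix report and inter-rater agreement
logicpath evaluate --pred predictions.tsv --group-by pathway --out report.json
logicpath agree --ratings ratings.tsv
```

Network files are tab-separated logic tables: an optional `# nodes` section
(`id  name  entity_class`) followed by an `# edges` section
(`source_id  target_id  polarity  logic`). Bare edge tables with common
header variants (`source`/`from`, `sign`, `gate`, ...) are also accepted.

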