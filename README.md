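# gemtailor

Condition- and time-specific genome-scale metabolic modelling from
expression data. The package tailors a global GEM to (condition, day)
contexts with GIMME, estimates flux distributions by norm-regularized
FBA, screens reactions for their impact on biomass production, and
compares conditions through flux and flux-sum fold-change clustering.
A fully planted synthetic drought scenario makes every stage testable
offline.

## What it does

1. **Model core** (`gemtailor.model_core`) — read/write SBML (L3 + fbc
   on write; legacy L2 "notes dialect" understood on read), strip preset
   bounds (irreversible → [0, ∞), reversible → (−∞, ∞)), expose the
   stoichiometric matrix.
2. **Expression contexts** (`gemtailor.expression_context`) — average
   replicates per (condition, day), map gene values onto reactions
   through boolean gene-association rules (AND → min, OR → max), and
   compute pooled quantile thresholds.
3. **Flux analysis** (`gemtailor.flux_analysis`) — FBA (HiGHS via
   scipy), two-stage min-norm FBA (LP then strictly convex QP with an
   exact KKT polish, reproducible solutions), flux-sums (half the
   absolute stoichiometry-weighted throughput of a metabolite),
   single-reaction deletion screens and reaction insertion.
4. **GIMME tailoring** (`gemtailor.gimme_tailoring`) — minimize
   Σ weight·|v| subject to biomass ≥ 90% of the parent optimum, extract
   per-context sub-models (below-threshold reactions that still carry
   flux are recorded as reinserted), sweep threshold quantiles
   0.70–0.90 and select the one whose simulated biomass trajectory best
   matches the observed fresh-weight increase rate.
5. **Comparative analysis** (`gemtailor.comparative_analysis`) —
   context × reaction (or metabolite) magnitude matrices with the
   min-positive/10 fill rule, log2(drought/control) fold-changes,
   average-linkage correlation clustering cut at distance 0.5,
   occurrence percentages against a reported-metabolite list, and
   model census tables.
6. **Synthetic data** (`gemtailor.synthetic_data`) — a compartmentalized
   toy GEM with a planted key reaction, a 13-day × 2-condition × 4-replicate
   expression series, growth trajectories that diverge late, and a
   `truths.json` with the planted ground truths.
7. **Pipeline CLI** (`gemtailor.pipeline_cli`) — orchestration with a
   YAML config, deterministic artifacts, and a checksummed manifest.

## Quick start

```bash
# generate the synthetic drought scenario (writes gem.xml, expression.tsv,
# sample_sheet.tsv, growth.tsv, truths.json and a ready run.yaml)
gemtailor simulate --seed 7 --out scenario/

# run the whole pipeline
gemtailor run --config scenario/run.yaml --out run/

# inspect individual stages
gemtailor fba --gem scenario/gem.xml --out flux.tsv
gemtailor screen --run-dir run/          # final-day deletion/insertion screen
gemtailor compare --run-dir run/         # fold-changes + clustering
gemtailor census --run-dir run/          # per-context model census
```

A run directory contains the stripped global model, one SBML file and
one flux table per context (`{condition}_day{D}`), the tailoring report
with per-quantile scores, the deletion/insertion screen report, flux and
flux-sum fold-change tables, cluster memberships, census tables, and a
`manifest.json` whose checksums are byte-stable across reruns.

Running on your own data needs four inputs (see `PipelineConfig`):
an SBML model, a genes × samples expression TSV, a sample sheet
(`sample_id  condition  day  replicate`), and a growth table
(`condition  day  fresh_weight_g`); optionally a reported-metabolite
list and a metabolite → KEGG sidecar TSV.

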