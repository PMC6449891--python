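"""Run the full four-stage fusion pipeline and compare against the
expression-only ablation.

Stage 1 clusters expression into pathways, stage 2 extends the protein
network, stage 3 fuses both into refined scores, stage 4 learns the
directed network under those constraints.  The ablation skips every use of
protein evidence.
"""

from grnfuse.pipeline import PipelineConfig, run_pipeline
from grnfuse.synthetic_fixtures import (SyntheticScenario, generate_expression,
                                        generate_truth_and_ppin)

scn = SyntheticScenario(seed=0)  # 30 genes, 40 experiments, 4 pathways
expr, membership = generate_expression(scn)
truth, ppin = generate_truth_and_ppin(scn, membership)
print(f"inputs: {scn.I} genes x {scn.J} experiments, "
      f"{len(ppin)} observed interactions, {len(truth)} true regulations")

shared = dict(n_models=5, n_iter=800, L_max=6)
fused = run_pipeline(expr, ppin, truth,
                     PipelineConfig(seed=0, mode="fused", **shared))
ge_only = run_pipeline(expr, None, truth,
                       PipelineConfig(seed=0, mode="expression-only", **shared))

for name, res in [("fused", fused), ("expression-only", ge_only)]:
    r = res.report
    print(f"{name:16s} L={res.L_selected}  edges={len(res.grn)}  "
          f"precision {r.precision:.2f}  recall {r.recall:.2f}  "
          f"F1 {r.f1:.2f}  AUROC {r.auroc:.3f}")
# The fused run constrains parents to shared pathways ranked by the
# refined scores R and rewards structures consistent with R; it finds
# more true regulations at similar precision than expression alone.
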