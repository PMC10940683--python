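"""The full pipeline on synthetic data: generate, preprocess, cross-validate.

Five cases per grade, two scans each, three random 256-px crops per scan,
blank-patch QC, and a case-level stratified 5-fold split feeding a tiny
CNN with the strip-pooling attention operator.  Grades differ by nucleus
density, so a working pipeline separates them far above the 33% chance
level.  Takes a couple of minutes on one CPU.
"""

import tempfile

from dieanet.train import smoke_experiment

with tempfile.TemporaryDirectory() as work:
    res = smoke_experiment(work, seed=1)

m = res["manifest"]
print(f"patches: {len(m)} cropped, {int(m['qc_pass'].sum())} passed the "
      f"75%-blank QC rule")
print("fold sizes (cases):",
      m.groupby("fold")["case_id"].nunique().to_dict())

print("\nper-fold validation accuracy:",
      [round(r.acc, 3) for r in res["reports"]])
agg = res["aggregate"]
for k in ("acc", "auc", "mcc", "kappa", "f1_m"):
    print(f"{k:6s} = {agg[k]['mean']:.3f} ± {agg[k]['sd']:.3f}")
print("\nMean accuracy far above 1/3 confirms the stages compose correctly "
      "and that no case leaks between training and validation folds.")
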