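"""Train the tiny two-step FC-DenseNet on a few phantoms (~2 min on CPU).

Step 1 localizes all structures at once on the downsampled field of view;
step 2 segments each structure at full resolution inside a fixed-size ROI
anchored at the predicted middle point.
"""

from adaptseg.phantom import generate_cohort
from adaptseg.profiles import desk_anatomy, desk_protocol_config
from adaptseg.protocols import SplitPlan, run_protocol

subjects, _ = generate_cohort(5, desk_anatomy(), seed=3,
                              shrink_fraction={"glandular": 0.10})
cohort = {s.subject_id: s for s in subjects}
ids = list(cohort)

plan = SplitPlan(test_subjects=(ids[0],), shared_train_subjects=tuple(ids[1:]),
                 extra_train_subjects=(), mode="matched")
config = desk_protocol_config(seed=0)
models, report = run_protocol(plan, cohort, config)

h = models["histories"]["step1"]
print(f"step-1 loss: {h[0]:.3f} -> {h[-1]:.3f} over {len(h)} epochs")
print(report[["subject", "structure", "DSC", "HD95_mm"]].round(3)
      .to_string(index=False))

# The held-out subject's adaptive scan is segmented with DSC ~0.8-1.0 per
# structure; the visible, high-contrast mandible is near-perfect while the
# faint-rimmed parotids carry most of the residual error.
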