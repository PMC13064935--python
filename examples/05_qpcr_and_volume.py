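"""Closed-form bench quantifications: delta-delta-CT fold change and
ellipsoid tumor volume.
"""

import coexkit as ck

records = [
    ck.CtRecord("luc_1", target_ct=22.1, reference_ct=15.0, condition="control"),
    ck.CtRecord("luc_2", target_ct=21.9, reference_ct=15.1, condition="control"),
    ck.CtRecord("oe_1", target_ct=19.8, reference_ct=15.0, condition="treatment"),
    ck.CtRecord("oe_2", target_ct=20.1, reference_ct=15.2, condition="treatment"),
]
folds = ck.ddct_fold_change(records)
print(folds.round(3).to_string(index=False))
mean_fold = folds[folds["condition"] == "treatment"]["fold_change"].mean()
print(f"mean overexpression fold change vs control: {mean_fold:.2f}x")

vol = ck.ellipsoid_volume(ck.TumorMeasure(length_mm=10.0, width_mm=8.0))
print(f"tumor 10 x 8 mm -> volume {vol:.0f} mm^3 (L*W^2/2)")

# A ~2-cycle drop in target CT relative to the reference gene corresponds
# to a ~4-fold expression increase (fold = 2^-ddCT).
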