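"""Compare gene behavior with ALAN.

ALAN compares two genes by the similarity of their genome-wide
association profiles (rows of the all-pairs Spearman matrix) instead of
their direct correlation. Genes in the same planted program get a high
ALAN score; genes from anti-correlated programs get a negative one, and
a gene's behavior against a panel summarizes its subtype alignment.
"""

import coexkit as ck

spec = ck.default_demo_spec(seed=1, n_samples=208, n_genes=500)
matrix, _, _, truth = ck.generate_cohort(spec)
behavior = ck.build_behavior_matrix(ck.log_transform(matrix))

print(f"potential interactions at {behavior.data.shape[0]} genes: "
      f"{ck.count_potential_interactions(behavior.data.shape[0]):,}")
print(f"ALAN(BAS001, BAS002) = {ck.alan_score(behavior, 'BAS001', 'BAS002'):+.3f}  (same program)")
print(f"ALAN(BAS001, LUM001) = {ck.alan_score(behavior, 'BAS001', 'LUM001'):+.3f}  (opposed programs)")

panel = ck.GeneSet("basal_panel", truth.modules["basal"][1:6])
heatmap = ck.geneset_alan_heatmap(behavior, ["BAS001", "LUM001"], panel)
print("\nALAN scores vs basal panel:")
print(heatmap.round(3).to_string())

r2, slope, intercept = ck.compare_profiles_r2(behavior.profile("BAS001"),
                                              behavior.profile("BAS002"))
print(f"\nprofile concordance BAS001 vs BAS002: R^2 = {r2:.3f}, slope = {slope:.3f}")

# Two genes driven by the same latent factor show near-identical behavior
# vectors (R^2 close to 1), the network-level analogue of co-regulation.
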