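"""Small cohort study: strengths, correlations, PCA and regression.

Runs the full pipeline on a 12-femur cohort at a coarse mesh (for
speed), then prints which morphological parameters correlate with the
sideways-fall strength and how the retained principal components
predict it.  With only 12 femurs the significance pattern is noisier
than in a full-sized study; the point is the mechanics of the chain.
"""

from femurmech import GeneratorConfig, RunConfig, run_cohort

cfg = RunConfig(generator=GeneratorConfig(cohort_size=12, seed=42,
                                          edge_length=3.0))
rep = run_cohort(cfg)

tab = rep.table
for col in ("F_stumbling", "F_lateral_fall"):
    print(f"{col}: mean {tab[col].mean():6.0f} N, "
          f"range {tab[col].min():.0f}-{tab[col].max():.0f} N")

stats = rep.stats
corr = stats.correlations["F_lateral_fall"].sort_values("p")
print("\nstrongest correlations with the sideways-fall strength:")
print(corr.head(6).to_string(float_format=lambda v: f"{v:7.3f}"))

case = "F_lateral_fall"
if stats.pca[case] is not None:
    block = stats.pca[case]
    print(f"\nPCA of {len(block.variables)} significant parameters: "
          f"{block.n_retained} component(s) retained "
          f"(KMO {block.kmo:.2f})" if block.kmo else "")
    print(block.loadings.to_string(float_format=lambda v: f"{v:6.2f}"))
    reg = stats.regression[case]
    if reg is not None:
        print(f"\nregression on PC scores: r = {reg.model_r:.2f}, "
              f"SEE = {reg.see:.0f} N, intercept = {reg.intercept:.0f} N")
        print("(the intercept equals the cohort-mean strength because the")
        print(" scores are standardized)")
else:
    print(f"\nPCA skipped: {stats.pca_skip_reason[case]}")
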