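"""Decide whether two sub-sites of one body site should be merged.

Sub-sites drawn from one distribution score near zero silhouette
(merge); a strong planted shift scores high (keep separate)."""

from tissuenorm import assess_merge, simulate_mergeable_subsites

for shift in (0.0, 4.0):
    expr, _ = simulate_mergeable_subsites(shift, shifted_fraction=0.3, seed=3)
    res = assess_merge(expr, "major", n_top_genes=200)
    print(
        f"shift {shift} log2: silhouette = {res.separation_score:+.3f} "
        f"-> {res.recommendation}"
    )
# The silhouette measures sub-site separation in the first two principal
# coordinates: ~0 means the sub-sites are transcriptionally
# indistinguishable and can be pooled for power; >0.5 means they are
# distinct populations and should stay separate.
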