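"""Full reconstruction: Schulz-Snyder vs Anchor-Update vs direct fusion.

Simulates the 12-view study acquisition, reconstructs it four ways and
scores each result against the known phantom (normalized correlation,
maximized over the shift/flip ambiguity of de-autocorrelation).
Runtime: a couple of minutes.
"""

from corrtomo import phantom_experiment

res = phantom_experiment(seed=1, n_iter=5000, mode="circular")

print(f"{len(res['views'])} views reconstructed; recovery scores:")
for name in ("direct_unregistered", "direct_registered", "ss", "au"):
    print(f"  {name:22s} {res['scores'][name]:.4f}")

div = res["ss_state"].divergences
print(f"SS I-divergence: {div[0]:.3e} -> {div[-1]:.3e} over "
      f"{res['ss_state'].t} iterations (monotone)")
# Expected ordering: unregistered direct fusion is worst (misalignments
# blur it); SS beats it without ever estimating a shift; AU sharpens
# further by deconvolving the known PSF during the inversion.
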