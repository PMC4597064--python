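"""Copy-number-weighted VAF kernel density with a plug-in bandwidth.

Simulates a sample with two planted clones, runs the integration
pipeline, and estimates the VAF density; the recovered modes should sit
near the planted clone centers.
"""

import pandas as pd

from omiclone.clonality import kde_modes, plugin_bandwidth, weighted_kde
from omiclone.fixtures import FixtureConfig, generate_bundle
from omiclone.integration import distinct_mutations, integrate

cfg = FixtureConfig(seed=13, n_variants=300, clone_centers=(22.0, 58.0),
                    clone_weights=(0.5, 0.5), vaf_sd=3.0)
bundle = generate_bundle(cfg)
w_hat = distinct_mutations(integrate(bundle))

vafs = w_hat["dna_allelic_freq"].astype(float).to_numpy()
weights = [2.0 if pd.isna(c) else float(c) for c in w_hat["copy_number"]]

h = plugin_bandwidth(vafs)
curve = weighted_kde(vafs, weights, h=h)
modes = sorted(kde_modes(curve))

print(f"retained mutations : {len(vafs)}")
print(f"plug-in bandwidth  : {h:.3f} VAF points")
print(f"density integral   : {curve.integral():.4f} (should be ~1)")
print(f"planted clones     : {sorted(cfg.clone_centers)}")
print(f"recovered modes    : {[round(float(m), 2) for m in modes]}")
print("\nEach density peak suggests a clonal cluster; copy-number weighting")
print("keeps amplified loci from being under-represented in the density.")
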