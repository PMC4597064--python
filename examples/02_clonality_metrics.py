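"""Per-sample clonality metrics: mutation count, key genes, Shannon diversity.

Each retained mutation is one molecular species with abundance
VAF * depth * copy number; the Shannon diversity index (in nats) rises
with both the number of mutations and the evenness of their abundances.
"""

from omiclone.clonality import calculate_metrics
from omiclone.fixtures import example_case_bundle, key_genes_of
from omiclone.integration import distinct_mutations, integrate

for sample in ("presentation", "relapse"):
    bundle = example_case_bundle(sample)
    w_hat = distinct_mutations(integrate(bundle))
    m = calculate_metrics(w_hat, key_genes_of(bundle.key_genes))
    print(f"{sample:>12}: N={m.n_mutations}  KG={m.n_key_genes}  SDI={m.sdi:.4f} nats")

print("\nA higher SDI at relapse indicates diversification of the mutational")
print("landscape (more clones and/or more even clone abundances).")
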