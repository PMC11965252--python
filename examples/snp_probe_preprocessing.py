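"""SNP-array probe preprocessing: exclusion filters, duplicate
aggregation, and the logR = 0.55*log2(R) transform that feeds
allele-specific copy-number segmentation.

Run:  python examples/snp_probe_preprocessing.py
"""

from neurodish import synth
from neurodish.snp_qc import preprocess

table, truth = synth.gen_probe_table(n_probes=1000, seed=11)
result, counts = preprocess(table)

print(f"input probes  : {len(table)}")
for name, n in counts.items():
    print(f"  removed by {name:<22}: {n}")
print(f"retained      : {len(result)} (unique ids: {result['probe_id'].is_unique})")
print(f"planted counts: {truth.planted_filter_counts}")
print(result[["probe_id", "chromosome", "R", "BAF", "logR"]].head(3).to_string(index=False))
print("Each per-filter removal count matches the number of excludable "
      "probes the generator planted; logR/BAF per probe are what a "
      "segmentation tool consumes.")
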