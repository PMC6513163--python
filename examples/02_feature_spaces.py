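"""Encode regions as TF-IDF vectors and build the similarity kernel.

Shows the keyword space on two related annotations ('WD repeat' vs
'WD repeat-containing' share tokens, so their regions stay similar), the
k-mer space, and how the 95th-percentile cutoff sparsifies the cosine
kernel that drives label propagation between regions.
"""

import numpy as np

from regionfp import build_kernel, extract_keywords, extract_kmers, tfidf_fit_transform

print("3-mers of 'ABCDE':", extract_kmers("ABCDE", k=3))
print("keywords of 'WD repeat-containing':",
      extract_keywords(["WD repeat-containing"]))

counts = [
    extract_keywords(["WD repeat"]),
    extract_keywords(["WD repeat-containing"]),
    extract_keywords(["SH3 domain"]),
    extract_keywords(["protein kinase domain"]),
    extract_keywords(["kinase catalytic domain"]),
]
matrix, _ = tfidf_fit_transform(counts, [f"r{i}" for i in range(len(counts))])
sims = (matrix.weights @ matrix.weights.T).toarray()
print("\ncosine similarity, 'WD repeat' vs 'WD repeat-containing': "
      f"{sims[0, 1]:.3f} (shared tokens keep it non-zero)")
print(f"cosine similarity, 'WD repeat' vs 'SH3 domain': {sims[0, 2]:.3f}")

kernel = build_kernel(matrix, percentile=95.0, seed=0)
retained = kernel.values.toarray()
off = retained[~np.eye(len(counts), dtype=bool)]
print(f"\nkernel threshold (95th pct of off-diagonal sims): "
      f"{kernel.threshold:.3f}")
print(f"off-diagonal pairs retained: {int((off > 0).sum())} of {off.size} "
      "(everything below the cutoff is zeroed)")
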