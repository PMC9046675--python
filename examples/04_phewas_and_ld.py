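"""Offline phenome-wide scan and LD pruning of correlated variants.

Builds a 778-phenotype summary table (the 14 packaged phenome-wide hits
for one variant plus 764 null phenotypes), applies the Bonferroni family
threshold, and prunes a ten-variant set consisting of two tight LD blocks.
"""

import numpy as np

from metasynopsis import (
    LDMatrix,
    PhewasRow,
    bonferroni_threshold,
    ld_prune,
    load_phewas_hits,
    phewas_scan,
    representatives,
)

hits = load_phewas_hits()
hits = hits[hits["variant_id"] == "rs2228145"]
rows = [
    PhewasRow(rec["phenotype"], None, float(rec["or"]), float(rec["p"]),
              int(rec["n_cases"]))
    for _, rec in hits.iterrows()
]
rng = np.random.default_rng(0)
rows += [
    PhewasRow(f"null phenotype {i}", None, None, float(p))
    for i, p in enumerate(rng.uniform(0.01, 1.0, size=778 - len(rows)))
]

cut = bonferroni_threshold(len(rows), 0.05)
found = phewas_scan(rows, 0.05)
print(f"Bonferroni threshold for {len(rows)} phenotypes: {cut:.3g}")
print(f"{len(found)} phenome-wide significant associations, strongest first:")
for r in found[:5]:
    print(f"  {r.phenotype}: p = {r.p:.3g}")

blocks = [
    ["rs2228145", "rs7518199", "rs4537545", "rs7529229", "rs4129267"],
    ["rs4845625", "rs4845618", "rs4845371", "rs6667434", "rs4553185"],
]
ids = blocks[0] + blocks[1]
r2 = np.eye(10)
index = {v: i for i, v in enumerate(ids)}
for block in blocks:
    for a in block:
        for b in block:
            if a != b:
                r2[index[a], index[b]] = 0.9

clusters = ld_prune(LDMatrix(ids, r2), cutoff=0.8)
print(f"\nLD pruning at r^2 > 0.8 leaves {len(clusters)} independent signals:")
for cluster in clusters:
    print(f"  {cluster[0]} tags {', '.join(cluster[1:])}")
print(
    "Variants inside a block carry the same association signal, so the "
    "phenome-wide scan is run only for each cluster representative."
)
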