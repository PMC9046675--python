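"""Replay evidence grading over the packaged pooled association tables.

The packaged fixtures transcribe 58 published pooled associations (27
disease rows, 31 categorical-phenotype rows) with their printed Venice
letters, FPRP values and cumulative labels. This script recounts the
significant associations, re-runs the category combination rule, and
recomputes FPRP for one row from nothing but its printed OR, CI and p.
"""

from metasynopsis import (
    SynopsisConfig,
    count_significant,
    load_disease_table,
    load_phenotype_table,
    recompute_fprp,
    replay_pooled,
)

diseases = load_disease_table()
phenotypes = load_phenotype_table()

for name, rows in (("disease", diseases), ("phenotype", phenotypes)):
    total, sig = count_significant(rows)
    print(f"{name} table: {sig}/{total} associations significant at p < 0.05")

replays = replay_pooled(diseases + phenotypes)
agree = sum(bool(r.agrees) for r in replays)
print(f"combination rule reproduces {agree}/{len(replays)} printed labels")
for r in replays:
    if r.agrees is False:
        print(f"  known anomaly: {r.row.variant_id} / {r.row.outcome} "
              f"(rule says {r.predicted}, table prints {r.printed})")

row = next(r for r in diseases if r.outcome == "Ulcerative colitis")
res = recompute_fprp(row, SynopsisConfig(fprp_alpha_source="reported_p"))
print(
    f"\nrs2228145 / ulcerative colitis: OR {row.or_} ({row.ci_low}-{row.ci_high}), "
    f"p {row.p} -> FPRP {res.value:.3f} ({res.category})"
)
print(
    "FPRP is the probability this significant finding is a false positive "
    "given prior 0.05 and power to detect OR 1.2; values above 0.20 are "
    "weak evidence and downgrade the Venice category."
)
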