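"""Founder-variant ages and founder-list intersection.

Loads the packaged literature-curated table of haplotype-dated founder PVs
in DNA-repair genes, finds the oldest, partitions by a 4,000-year
threshold, and intersects population founder lists with a cohort.
"""

from paleopv.founder import (
    filter_by_age,
    founder_intersection,
    load_reference_founders,
    oldest_founder,
    parse_age,
)

records = load_reference_founders()
rec, age = oldest_founder(records)
print(f"{len(records)} dated founder PVs loaded")
print(f"oldest: {rec.gene} {rec.cdna} ({rec.population}) at {age:.0f} BP")

within, exceeding = filter_by_age(records, 4000)
print(f"{len(within)} founders arose within the last 4,000 years; "
      f"{len(exceeding)} are older:")
for r in exceeding:
    print(f"  {r.gene} {r.cdna}: {r.age.representative:.0f} BP")

# age notation covers points, ranges and bounds
for text in ("8,675", "1,500-750", ">250", "<200"):
    a = parse_age(text)
    print(f"  {text!r} -> {a.kind}, representative {a.representative:.0f} BP")

# founder transmission through admixture: Portuguese BRCA founder lists
# intersected with a cohort's variants (14 BRCA1 + 15 BRCA2 matches)
brca1 = {f"brca1_f{i}" for i in range(14)}
brca2 = {f"brca2_f{i}" for i in range(15)}
cohort = brca1 | brca2 | {f"other{i}" for i in range(226)}
gene_of = {**{p: "BRCA1" for p in brca1}, **{p: "BRCA2" for p in brca2}}
res = founder_intersection(cohort, {"Portuguese": brca1 | brca2}, gene_of)
print(f"\nPortuguese founder PVs in the cohort: {res.total} "
      f"({len(res.per_gene['Portuguese']['BRCA1'])} BRCA1, "
      f"{len(res.per_gene['Portuguese']['BRCA2'])} BRCA2)")
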