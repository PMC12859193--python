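"""Cohort sharing summaries: percentages, Venn partition, temporal profile.

Uses the published cohort-scale counts where arithmetic suffices, and a
small hand-built carrier set for the temporal profile.
"""

from paleopv.catalog import Individual
from paleopv.sharing import sharing_percentage, temporal_profile, venn_partition

# 1,266 of 1,781 catalogued pathogenic variants were found in ancient genomes
print(f"ancient-shared PVs: {sharing_percentage(1266, 1781, 0):.0f}% of the catalog")

part = venn_partition(
    ancient_pvs={"pv1", "pv2", "pv3", "pv4", "pv5"},
    african_pvs={"pv1", "pv9"},
    nonafrican_pvs={"pv1", "pv2", "pv3", "pv8"},
)
fr = part.fractions
print(f"venn of 5 ancient PVs: {len(part.only_nonafrican)} non-African only, "
      f"{len(part.both)} both, {len(part.only_african)} African only, "
      f"{len(part.neither)} in neither modern cohort")
print(f"fractions over the shared base: "
      f"{100*fr[0]:.1f}% / {100*fr[1]:.1f}% / {100*fr[2]:.1f}%")

carriers = [
    Individual("russia_1", "ancient", 37470, "Russia", {"BRCA1_c181": "het"}),
    Individual("vanuatu_1", "ancient", 190, "Vanuatu", {"MSH2_c1204": "het"}),
    Individual("europe_1", "ancient", 3200, "Europe", {"BRCA2_x": "het",
                                                       "MLH1_y": "het"}),
    Individual("undated_1", "ancient", None, "Asia", {"BRCA2_x": "het"}),
]
prof = temporal_profile(carriers, bin_width=5000)
print(f"\noldest carried PV: {prof.oldest[0]} at {prof.oldest[1]:.0f} BP")
print(f"youngest carried PV: {prof.youngest[0]} at {prof.youngest[1]:.0f} BP")
print(f"undated carrier-occurrences: {prof.n_undated}")
for start, end, count in prof.bins:
    if count:
        print(f"  [{start:.0f}, {end:.0f}) BP: {count} carrier-occurrences")
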