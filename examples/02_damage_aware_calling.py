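"""Damage-aware presence calling at one C>T variant site.

Builds a pileup by hand: two duplicate reads, one terminal-base read, and
alt support that is entirely forward-strand C→T — the signature of
post-mortem deamination.  Shows how QC filtering and the damage rule
change the call.
"""

from paleopv.catalog import PVRecord
from paleopv.presence import (
    CallerConfig,
    PileupSite,
    ReadObservation,
    call_presence,
    filter_observations,
)

pv = PVRecord("BRCA1_ex", "BRCA1", "c.181T>G", "p.(Cys61Gly)", "17", 43106487,
              "C", "T", frozenset({"HR", "FA"}), "Pathogenic")


def obs(base, strand, d5, frag_start, bq=37):
    return ReadObservation(f"r{frag_start}{strand}{base}", base, bq, 60,
                           d5, 59 - d5, strand, (frag_start, frag_start + 59, strand))

site = PileupSite("ancient_sample_1", pv.pv_id, [
    obs("C", "+", 20, 100),
    obs("C", "+", 20, 100, bq=30),   # PCR duplicate of the read above
    obs("C", "-", 1, 130),           # terminal base, trimmed by QC
    obs("T", "+", 3, 150),           # alt near 5' end: deamination-consistent
    obs("C", "-", 25, 180),
])

cfg = CallerConfig()
filtered = filter_observations(site, cfg)
print(f"reads before QC: {len(site.observations)}, after: {len(filtered.observations)}")

call = call_presence(pv, site, cfg)
print(f"call: {call.call} (alt={call.n_alt_support}, ref={call.n_ref_support}, "
      f"damage_flagged={call.damage_flagged})")
# One forward-strand C->T alt read could be pure deamination, so the
# stricter damage threshold applies and the site stays uncallable.

site.observations.append(obs("T", "-", 30, 210))  # reverse-strand alt read
call2 = call_presence(pv, site, cfg)
print(f"after adding reverse-strand alt support: {call2.call}, "
      f"zygosity={call2.zygosity}, damage_flagged={call2.damage_flagged}")
# Deamination is strand-specific; alt support on both strands is treated
# as genuine, so the variant is now called present.
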