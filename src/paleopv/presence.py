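"""Ancient-DNA damage-aware presence calling at known pathogenic-variant sites.

Instead of de-novo genotyping, each catalogued variant site is interrogated in
the read pileup of one ancient individual.  Post-mortem cytosine deamination
creates C→T substitutions (read as G→A on the reverse strand) concentrated at
fragment ends, so alt-supporting reads at C>T / G>A sites are screened:
terminal bases are trimmed, duplicates collapsed, low-quality reads dropped,
and a stricter support threshold applies when every surviving alt read could
be a deamination artifact on its own strand.  Alt support observed on both
strands overrides the damage penalty, because deamination is strand-specific.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .catalog import PVRecord

PILEUP_COLUMNS = [
    "ind_id", "pv_id", "read_id", "base", "base_qual", "map_qual",
    "dist5", "dist3", "strand", "frag_start", "frag_end",
]
CALL_COLUMNS = ["ind_id", "pv_id", "call", "zygosity", "n_alt", "n_ref", "damage_flagged"]


@dataclass(frozen=True)
class ReadObservation:
    """One read's evidence at a variant site."""

    read_id: str
    base: str
    base_qual: int
    map_qual: int
    dist_from_5p: int
    dist_from_3p: int
    strand: str  # "+" or "-"
    frag_key: tuple[int, int, str]  # (ref start, ref end, strand)

    def __post_init__(self) -> None:
        if self.dist_from_5p < 0 or self.dist_from_3p < 0:
            raise ValueError("distances from read ends must be non-negative")
        if self.base_qual < 0 or self.map_qual < 0:
            raise ValueError("Phred qualities must be non-negative")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass
class PileupSite:
    """All read observations for one (individual, variant site) pair."""

    ind_id: str
    pv_id: str
    observations: list[ReadObservation] = field(default_factory=list)


@dataclass(frozen=True)
class PresenceCall:
    ind_id: str
    pv_id: str
    call: str  # present | absent | uncallable
    zygosity: str  # het | hom | present_unknown | na
    n_alt_support: int
    n_ref_support: int
    n_other: int = 0
    damage_flagged: bool = False


@dataclass(frozen=True)
class CallerConfig:
    """Thresholds for the damage-aware caller.

    Defaults reflect common ancient-DNA practice: trim 2 terminal bases,
    base quality >= 20, mapping quality >= 30.  Support thresholds are
    permissive (a single alt read suffices off the deamination classes)
    because ancient genomes are low coverage; purely damage-consistent alt
    support needs ``min_alt_reads_damage`` reads instead.
    """

    terminal_trim: int = 2
    min_base_qual: int = 20
    min_map_qual: int = 30
    min_alt_reads: int = 1
    min_alt_reads_damage: int = 2
    min_depth: int = 1
    min_zyg_reads: int = 2
    auto_filter: bool = True


def filter_observations(site: PileupSite, cfg: CallerConfig) -> PileupSite:
    """Apply the QC cascade: terminal trim, quality filters, deduplication.

    Observations within ``terminal_trim`` bases of either read end are
    dropped, as are reads below the base/mapping quality thresholds.
    Duplicates (same fragment start, end and strand) collapse to the single
    observation with the highest base quality, first-seen on ties; output
    order follows input order of the survivors.
    """
    k = cfg.terminal_trim
    survivors = [
        o
        for o in site.observations
        if o.dist_from_5p >= k
        and o.dist_from_3p >= k
        and o.base_qual >= cfg.min_base_qual
        and o.map_qual >= cfg.min_map_qual
    ]
    best: dict[tuple[int, int, str], ReadObservation] = {}
    order: list[tuple[int, int, str]] = []
    for o in survivors:
        if o.frag_key not in best:
            best[o.frag_key] = o
            order.append(o.frag_key)
        elif o.base_qual > best[o.frag_key].base_qual:
            best[o.frag_key] = o
    return PileupSite(site.ind_id, site.pv_id, [best[key] for key in order])


def is_damage_consistent(pv: PVRecord, obs: ReadObservation) -> bool:
    """Could this alt-supporting read be a deamination artifact?

    True iff the substitution is C→T seen on the forward strand or G→A seen
    on the reverse strand — the two orientations a post-mortem C→U lesion
    produces.  Non-SNV records are never damage-consistent.
    """
    if not pv.is_snv:
        return False
    if obs.base != pv.alt_allele:
        return False
    ref, alt = pv.ref_allele, pv.alt_allele
    return (ref == "C" and alt == "T" and obs.strand == "+") or (
        ref == "G" and alt == "A" and obs.strand == "-"
    )


def call_presence(pv: PVRecord, site: PileupSite, cfg: CallerConfig | None = None) -> PresenceCall:
    """Decide present / absent / uncallable and zygosity for one site.

    present: alt support meets ``min_alt_reads`` (or ``min_alt_reads_damage``
    when every alt read is damage-consistent and single-stranded);
    absent: surviving depth >= ``min_depth`` with zero alt support;
    uncallable: anything else.  Bases matching neither allele are tallied
    separately and excluded from both supports.
    """
    cfg = cfg or CallerConfig()
    if cfg.auto_filter:
        site = filter_observations(site, cfg)

    alt_obs = [o for o in site.observations if o.base == pv.alt_allele]
    ref_obs = [o for o in site.observations if o.base == pv.ref_allele]
    n_alt, n_ref = len(alt_obs), len(ref_obs)
    n_other = len(site.observations) - n_alt - n_ref
    depth = n_alt + n_ref

    # Strand-specific deamination cannot produce alt reads on both strands.
    double_stranded = len({o.strand for o in alt_obs}) == 2
    damage_flagged = (
        n_alt > 0
        and not double_stranded
        and all(is_damage_consistent(pv, o) for o in alt_obs)
    )
    alt_threshold = cfg.min_alt_reads_damage if damage_flagged else cfg.min_alt_reads

    if n_alt >= alt_threshold:
        call = "present"
        if n_alt >= cfg.min_zyg_reads and n_ref >= cfg.min_zyg_reads:
            zyg = "het"
        elif n_alt >= cfg.min_zyg_reads and n_ref == 0:
            zyg = "hom"
        else:
            zyg = "present_unknown"
    elif depth >= cfg.min_depth and n_alt == 0:
        call, zyg = "absent", "na"
    else:
        call, zyg = "uncallable", "na"

    return PresenceCall(
        ind_id=site.ind_id,
        pv_id=site.pv_id,
        call=call,
        zygosity=zyg,
        n_alt_support=n_alt,
        n_ref_support=n_ref,
        n_other=n_other,
        damage_flagged=damage_flagged,
    )


def call_all(
    catalog: Sequence[PVRecord],
    sites: Iterable[PileupSite],
    cfg: CallerConfig | None = None,
) -> list[PresenceCall]:
    by_id = {r.pv_id: r for r in catalog}
    calls = []
    for site in sites:
        if site.pv_id not in by_id:
            raise KeyError(f"pileup references unknown pv_id {site.pv_id!r}")
        calls.append(call_presence(by_id[site.pv_id], site, cfg))
    return calls


# ---------------------------------------------------------------------------
# I/O: pileup TSV dialect and SAM extraction

def read_pileup(path: str | Path) -> list[PileupSite]:
    """Read the tab-separated pileup dialect, one row per read observation."""
    sites: dict[tuple[str, str], PileupSite] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = set(PILEUP_COLUMNS) - set(header)
        if missing:
            raise ValueError(f"{path}: missing pileup columns {sorted(missing)}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            row = dict(zip(header, line.split("\t")))
            key = (row["ind_id"], row["pv_id"])
            if key not in sites:
                sites[key] = PileupSite(*key)
            sites[key].observations.append(
                ReadObservation(
                    read_id=row["read_id"],
                    base=row["base"],
                    base_qual=int(row["base_qual"]),
                    map_qual=int(row["map_qual"]),
                    dist_from_5p=int(row["dist5"]),
                    dist_from_3p=int(row["dist3"]),
                    strand=row["strand"],
                    frag_key=(int(row["frag_start"]), int(row["frag_end"]), row["strand"]),
                )
            )
    return list(sites.values())


def write_pileup(sites: Iterable[PileupSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(PILEUP_COLUMNS) + "\n")
        for site in sites:
            for o in site.observations:
                fh.write(
                    "\t".join(
                        map(
                            str,
                            [
                                site.ind_id, site.pv_id, o.read_id, o.base,
                                o.base_qual, o.map_qual, o.dist_from_5p,
                                o.dist_from_3p, o.strand, o.frag_key[0], o.frag_key[1],
                            ],
                        )
                    )
                    + "\n"
                )


def pileup_from_alignments(
    path: str | Path,
    ind_id: str,
    catalog: Sequence[PVRecord],
) -> list[PileupSite]:
    """Extract per-site read observations from a SAM/BAM/CRAM file.

    Each catalogued site is located in every overlapping aligned read; the
    observed base, qualities and the distances from the read's sequenced 5'
    and 3' ends (strand-aware, for deamination screening) are recorded.
    Only SNV sites are extracted from alignments; indel evidence must come
    through the pileup TSV dialect.
    """
    import pysam

    mode = "rb" if str(path).endswith((".bam", ".cram")) else "r"
    sites = []
    with pysam.AlignmentFile(str(path), mode) as af:
        has_index = af.has_index()
        for pv in catalog:
            if not pv.is_snv:
                continue
            site = PileupSite(ind_id, pv.pv_id)
            pos0 = pv.pos - 1
            if has_index:
                reads = af.fetch(pv.chrom, pos0, pos0 + 1)
            else:
                reads = (
                    r
                    for r in af.fetch(until_eof=True)
                    if r.reference_name == pv.chrom
                    and r.reference_start is not None
                    and r.reference_start <= pos0 < (r.reference_end or -1)
                )
            for read in reads:
                if read.is_unmapped or read.query_sequence is None:
                    continue
                qpos = None
                for q, r in read.get_aligned_pairs(matches_only=True):
                    if r == pos0:
                        qpos = q
                        break
                if qpos is None:
                    continue
                qlen = read.query_length
                # query coordinates are left-to-right on the reference; the
                # sequenced 5' end of a reverse read is the right-hand side
                dist_left, dist_right = qpos, qlen - 1 - qpos
                if read.is_reverse:
                    strand, d5, d3 = "-", dist_right, dist_left
                else:
                    strand, d5, d3 = "+", dist_left, dist_right
                quals = read.query_qualities
                site.observations.append(
                    ReadObservation(
                        read_id=read.query_name,
                        base=read.query_sequence[qpos].upper(),
                        base_qual=int(quals[qpos]) if quals is not None else 0,
                        map_qual=int(read.mapping_quality),
                        dist_from_5p=d5,
                        dist_from_3p=d3,
                        strand=strand,
                        frag_key=(read.reference_start, read.reference_end, strand),
                    )
                )
            if site.observations:
                sites.append(site)
    return sites


def write_calls(calls: Iterable[PresenceCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(CALL_COLUMNS) + "\n")
        for c in calls:
            fh.write(
                f"{c.ind_id}\t{c.pv_id}\t{c.call}\t{c.zygosity}\t"
                f"{c.n_alt_support}\t{c.n_ref_support}\t{int(c.damage_flagged)}\n"
            )
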