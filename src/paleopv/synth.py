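"""Synthetic cohorts, catalogs, reads and tables with planted structure.

The generator emulates the statistical shape of the real study inputs at
desk scale: a ClinVar-style catalog of pathogenic variants (PVs) in DNA
damage repair genes; an ancient cohort whose carried PVs define the
"ancient-present" truth set, with dates concentrated 5,000–1,000 years BP
plus a thin tail to 40,000 BP and a small undated fraction; modern African
and non-African cohorts whose carried PVs are ancient-present with cohort
propensities 0.17 and 0.5 respectively; ancient-DNA read pileups with
terminal C→T / G→A deamination, PCR duplicates and occasional low-quality
reads; a species allele panel whose sharing probability decays from distal
clades toward Primate; and founder-age and selection-class tables.

Everything is driven by one root seed through per-component
``SeedSequence`` spawn keys, so outputs are byte-identical across runs and
independent of call order.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .catalog import (
    Individual,
    PVRecord,
    write_carriers,
    write_catalog,
)
from .founder import AgeSpec, FounderRecord, format_age
from .phylo import DEFAULT_CLADE_ORDER, SpeciesAlleleTable, write_species_table
from .presence import PileupSite, ReadObservation, write_pileup
from .selection import SelectionTable, write_selection_table

_BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_REGIONS = ("Europe", "Asia", "Oceania", "Americas", "Africa")

# stable component indices for seed derivation
_COMP_CATALOG = 0
_COMP_COHORTS = 1
_COMP_READS = 2
_COMP_SPECIES = 3
_COMP_FOUNDER = 4
_COMP_SELECTION = 5


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generator; defaults are the emulated study conditions."""

    seed: int = 0

    # catalog
    n_pvs: int = 300
    n_genes: int = 40
    second_pathway_prob: float = 0.4
    transition_prob: float = 0.6       # fraction of SNVs that are transitions
    nonpathogenic_frac: float = 0.1    # benign/VUS rows retained only on request

    # cohorts
    n_ancient: int = 400
    n_african: int = 300
    n_nonafrican: int = 600
    ancient_present_frac: float = 0.71
    mean_pvs_per_individual: float = 0.8
    ancient_mean_pvs: float = 0.5
    propensity_nonafrican: float = 0.5
    propensity_african: float = 0.17
    het_prob: float = 0.98

    # ancient dates (years BP)
    date_bulk: tuple[float, float] = (1000.0, 5000.0)
    date_tail_max: float = 40000.0
    tail_frac: float = 0.08
    undated_frac: float = 0.087        # ~110/1,266

    # aDNA read model
    read_length: int = 60
    depth_min: int = 5
    depth_mean_extra: float = 5.0
    deamination_rate: float = 0.2      # terminal C->T / G->A probability
    deamination_decay: float = 0.3     # per-base exponential decay of damage
    duplicate_rate: float = 0.15
    # None derives the miscall rate from each read's Phred quality (10^(-q/10));
    # a float forces a flat rate instead
    seq_error_rate: float | None = None
    low_qual_frac: float = 0.05

    # species panel
    n_species_per_clade: int = 5
    clade_order: tuple[str, ...] = DEFAULT_CLADE_ORDER
    # sharing prob in the most distal clade, decaying toward Primate; the
    # defaults leave ~80% of PVs absent from every species, the regime the
    # cross-species analysis operates in
    distal_share_prob: float = 0.035
    share_decay_per_clade: float = 0.35
    missing_orthology_prob: float = 0.1

    # founder / selection tables
    n_founders: int = 30
    founder_age_range: tuple[float, float] = (150.0, 9000.0)
    selection_class_probs: tuple[float, float, float] = (0.3, 0.4, 0.3)
    selection_class_means: tuple[float, float, float] = (8.0, 4.0, 2.0)


def _rng(cfg: SimulationConfig, component: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(component, *key))
    )


# ---------------------------------------------------------------------------
# catalog

@dataclass
class CatalogTruth:
    ancient_present: set[str]
    gene_of: dict[str, str]


def simulate_catalog(cfg: SimulationConfig) -> tuple[list[PVRecord], CatalogTruth]:
    """Random PV catalog plus the truth flags downstream analyses plant.

    Genes are assigned one or two repair pathways; each PV is an SNV with a
    transition bias (so C>T / G>A sites — the deamination-confusable classes
    — are well represented).  A fixed fraction of PVs is flagged
    ancient-present; ancient carried sets are drawn from exactly that set.
    """
    rng = _rng(cfg, _COMP_CATALOG)
    genes = [f"GENE{i:03d}" for i in range(cfg.n_genes)]
    pathways = list(DEFAULT_PATHWAYS)
    gene_pathways = {}
    for g in genes:
        pws = {pathways[rng.integers(len(pathways))]}
        if rng.random() < cfg.second_pathway_prob:
            pws.add(pathways[rng.integers(len(pathways))])
        gene_pathways[g] = frozenset(pws)

    records = []
    for i in range(cfg.n_pvs):
        gene = genes[rng.integers(cfg.n_genes)]
        ref = _BASES[rng.integers(4)]
        if rng.random() < cfg.transition_prob:
            alt = _TRANSITION[ref]
        else:
            alt = rng.choice([b for b in _BASES if b not in (ref, _TRANSITION[ref])])
        classification = (
            "Pathogenic"
            if rng.random() >= cfg.nonpathogenic_frac
            else ("Benign" if rng.random() < 0.5 else "VUS")
        )
        pos = int(rng.integers(1, 250_000_000))
        records.append(
            PVRecord(
                pv_id=f"PV{i:05d}",
                gene=gene,
                cdna=f"c.{1 + int(rng.integers(5000))}{ref}>{alt}",
                protein="",
                chrom=str(1 + int(rng.integers(22))),
                pos=pos,
                ref_allele=ref,
                alt_allele=str(alt),
                pathways=gene_pathways[gene],
                classification=classification,
            )
        )
    pathogenic = [r.pv_id for r in records if r.is_pathogenic]
    n_present = int(round(cfg.ancient_present_frac * len(pathogenic)))
    present = set(
        rng.choice(pathogenic, size=n_present, replace=False)
    ) if pathogenic else set()
    truth = CatalogTruth(
        ancient_present={str(p) for p in present},
        gene_of={r.pv_id: r.gene for r in records},
    )
    return records, truth


DEFAULT_PATHWAYS = ("FA", "HR", "MMR", "NER", "NHEJ", "DDR", "BER", "DR")


# ---------------------------------------------------------------------------
# cohorts

def _draw_date(cfg: SimulationConfig, rng: np.random.Generator) -> float | None:
    u = rng.random()
    if u < cfg.undated_frac:
        return None
    if u < cfg.undated_frac + cfg.tail_frac:
        lo, hi = cfg.date_bulk[1], cfg.date_tail_max
        return float(np.round(rng.uniform(lo, hi)))
    return float(np.round(rng.uniform(*cfg.date_bulk)))


def _draw_carried(
    rng: np.random.Generator,
    mean_pvs: float,
    in_pool: Sequence[str],
    out_pool: Sequence[str],
    p_in: float,
    het_prob: float,
) -> dict[str, str]:
    carried: dict[str, str] = {}
    for _ in range(rng.poisson(mean_pvs)):
        pool = in_pool if (out_pool == [] or rng.random() < p_in) else out_pool
        if not pool:
            continue
        pv = str(pool[rng.integers(len(pool))])
        carried[pv] = "het" if rng.random() < het_prob else "hom"
    return carried


def simulate_cohorts(
    cfg: SimulationConfig,
    catalog: Sequence[PVRecord],
    truth: CatalogTruth,
) -> dict[str, list[Individual]]:
    """Ancient, African and non-African cohorts with planted sharing structure.

    Ancient individuals carry only ancient-present PVs (they define the set);
    each modern carried PV is ancient-present with the cohort's propensity.
    Nearly all carriers are heterozygous.
    """
    rng = _rng(cfg, _COMP_COHORTS)
    pathogenic = [r.pv_id for r in catalog if r.is_pathogenic]
    in_pool = sorted(truth.ancient_present)
    out_pool = sorted(set(pathogenic) - truth.ancient_present)

    cohorts: dict[str, list[Individual]] = {}
    ancient = []
    for i in range(cfg.n_ancient):
        ancient.append(
            Individual(
                ind_id=f"ANC{i:05d}",
                cohort="ancient",
                date_bp=_draw_date(cfg, rng),
                region=str(_REGIONS[rng.integers(len(_REGIONS))]),
                carried=_draw_carried(
                    rng, cfg.ancient_mean_pvs, in_pool, [], 1.0, cfg.het_prob
                ),
            )
        )
    cohorts["ancient"] = ancient

    for name, n, prop, prefix, region in (
        ("modern_african", cfg.n_african, cfg.propensity_african, "AFR", "Africa"),
        ("modern_nonafrican", cfg.n_nonafrican, cfg.propensity_nonafrican, "NAF", "Europe"),
    ):
        cohorts[name] = [
            Individual(
                ind_id=f"{prefix}{i:05d}",
                cohort=name,
                date_bp=None,
                region=region,
                carried=_draw_carried(
                    rng, cfg.mean_pvs_per_individual, in_pool, out_pool,
                    prop, cfg.het_prob,
                ),
            )
            for i in range(n)
        ]
    return cohorts


# ---------------------------------------------------------------------------
# reads

def simulate_reads(
    cfg: SimulationConfig,
    pv: PVRecord,
    genotype: str,
    ind_id: str = "SIM",
    rng: np.random.Generator | None = None,
) -> PileupSite:
    """Pileup for one (individual, site) with a planted genotype.

    Genotype is "ref/ref", "het" or "hom".  Depth is ``depth_min`` plus a
    Poisson excess.  Reads overlap the site at a uniform offset; terminal
    deamination flips C→T on forward reads (G→A on reverse reads) with
    probability δ·exp(−decay·d) at distance d from the read's 5' end;
    base miscalls occur at the rate implied by each read's Phred quality;
    PCR duplicates re-emit a read (same fragment, same damage, fresh base
    quality).
    """
    if genotype not in ("ref/ref", "het", "hom"):
        raise ValueError(f"unknown genotype {genotype!r}")
    if rng is None:
        key = zlib.crc32(f"{ind_id}|{pv.pv_id}".encode()) % (2**31)
        rng = _rng(cfg, _COMP_READS, key)
    L = cfg.read_length
    depth = cfg.depth_min + int(rng.poisson(cfg.depth_mean_extra))
    site = PileupSite(ind_id, pv.pv_id)

    def base_qual() -> int:
        if rng.random() < cfg.low_qual_frac:
            return int(rng.integers(2, 20))
        return int(np.clip(np.round(rng.normal(37, 3)), 2, 41))

    def map_qual() -> int:
        return 60 if rng.random() >= 0.05 else int(rng.integers(0, 30))

    for r in range(depth):
        if genotype == "ref/ref":
            true_base = pv.ref_allele
        elif genotype == "hom":
            true_base = pv.alt_allele
        else:
            true_base = pv.alt_allele if rng.random() < 0.5 else pv.ref_allele
        strand = "+" if rng.random() < 0.5 else "-"
        offset = int(rng.integers(0, L))  # distance from the left read edge
        if strand == "+":
            d5, d3 = offset, L - 1 - offset
        else:
            d5, d3 = L - 1 - offset, offset
        base = true_base
        if pv.is_snv and base == pv.ref_allele:
            damage_p = cfg.deamination_rate * np.exp(-cfg.deamination_decay * d5)
            if pv.ref_allele == "C" and pv.alt_allele == "T" and strand == "+":
                if rng.random() < damage_p:
                    base = "T"
            elif pv.ref_allele == "G" and pv.alt_allele == "A" and strand == "-":
                if rng.random() < damage_p:
                    base = "A"
        bq = base_qual()
        err_p = cfg.seq_error_rate if cfg.seq_error_rate is not None else 10 ** (-bq / 10)
        if rng.random() < err_p:
            base = str(rng.choice([b for b in _BASES if b != base]))
        frag_start = pv.pos - offset
        frag_key = (frag_start, frag_start + L - 1, strand)
        obs = ReadObservation(
            read_id=f"{ind_id}.{pv.pv_id}.r{r}",
            base=base,
            base_qual=bq,
            map_qual=map_qual(),
            dist_from_5p=d5,
            dist_from_3p=d3,
            strand=strand,
            frag_key=frag_key,
        )
        site.observations.append(obs)
        if rng.random() < cfg.duplicate_rate:
            site.observations.append(
                ReadObservation(
                    read_id=obs.read_id + ".dup",
                    base=obs.base,
                    base_qual=base_qual(),
                    map_qual=obs.map_qual,
                    dist_from_5p=d5,
                    dist_from_3p=d3,
                    strand=strand,
                    frag_key=frag_key,
                )
            )
    return site


def simulate_pileups(
    cfg: SimulationConfig,
    catalog: Sequence[PVRecord],
    ancient: Sequence[Individual],
    n_individuals: int = 30,
    n_absent_sites: int = 10,
) -> tuple[list[PileupSite], dict[tuple[str, str], str]]:
    """Read-level evidence for a subset of the ancient cohort.

    For each selected individual, every carried PV site plus a sample of
    non-carried sites is simulated; returns the pileups and the planted
    genotype per (individual, pv) pair.
    """
    rng = _rng(cfg, _COMP_READS)
    by_id = {r.pv_id: r for r in catalog}
    chosen = list(ancient[: min(n_individuals, len(ancient))])
    sites, genotypes = [], {}
    pathogenic_ids = [r.pv_id for r in catalog if r.is_pathogenic]
    for ind in chosen:
        absent_pool = [p for p in pathogenic_ids if p not in ind.carried]
        n_abs = min(n_absent_sites, len(absent_pool))
        absent_pick = (
            [str(p) for p in rng.choice(absent_pool, size=n_abs, replace=False)]
            if n_abs
            else []
        )
        plan = [(pv, zyg) for pv, zyg in sorted(ind.carried.items())]
        plan += [(pv, "ref/ref") for pv in absent_pick]
        for pv_id, genotype in plan:
            site = simulate_reads(cfg, by_id[pv_id], genotype, ind.ind_id, rng)
            sites.append(site)
            genotypes[(ind.ind_id, pv_id)] = genotype
    return sites, genotypes


# ---------------------------------------------------------------------------
# species / founder / selection tables

def simulate_species_table(
    cfg: SimulationConfig, catalog: Sequence[PVRecord]
) -> SpeciesAlleleTable:
    """Species allele panel with sharing decaying toward the Primate clade."""
    rng = _rng(cfg, _COMP_SPECIES)
    species_clade = {}
    for clade in cfg.clade_order:
        for j in range(cfg.n_species_per_clade):
            species_clade[f"{clade}_{j}"] = clade
    n_clades = len(cfg.clade_order)
    alleles = {}
    for rec in catalog:
        for sp in sorted(species_clade):
            clade = species_clade[sp]
            # rank 0 = most distal clade in cfg.clade_order
            distal_rank = cfg.clade_order.index(clade)
            if rng.random() < cfg.missing_orthology_prob:
                continue
            share_p = cfg.distal_share_prob * cfg.share_decay_per_clade ** distal_rank
            alleles[(rec.pv_id, sp)] = (
                rec.alt_allele if rng.random() < share_p else rec.ref_allele
            )
    return SpeciesAlleleTable(species_clade, alleles, cfg.clade_order)


def simulate_founder_table(cfg: SimulationConfig) -> list[FounderRecord]:
    rng = _rng(cfg, _COMP_FOUNDER)
    genes = ("BRCA1", "BRCA2", "MLH1", "MSH2", "MSH6", "MUTYH", "TP53")
    pops = ("PopA", "PopB", "PopC", "PopD")
    lo, hi = cfg.founder_age_range
    records = []
    for i in range(cfg.n_founders):
        age_val = float(np.round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
        u = rng.random()
        if u < 0.8:
            age = AgeSpec("point", age_val)
        elif u < 0.9:
            age = AgeSpec("range", age_val, float(np.round(age_val * rng.uniform(0.4, 0.9))))
        elif u < 0.95:
            age = AgeSpec("lower_bound", age_val)
        else:
            age = AgeSpec("upper_bound", age_val)
        records.append(
            FounderRecord(
                gene=str(genes[rng.integers(len(genes))]),
                cdna=f"c.{1 + int(rng.integers(9000))}del",
                protein="",
                population=str(pops[rng.integers(len(pops))]),
                age=age,
                source_id=f"SIM{i:04d}",
            )
        )
    return records


def simulate_selection_table(
    cfg: SimulationConfig, genes: Sequence[str]
) -> SelectionTable:
    """Class labels and per-gene PV counts with a planted class effect."""
    rng = _rng(cfg, _COMP_SELECTION)
    classes = ("positive", "neutral", "negative")
    gene_class, pv_count = {}, {}
    for g in genes:
        k = int(rng.choice(3, p=cfg.selection_class_probs))
        gene_class[g] = classes[k]
        pv_count[g] = int(rng.poisson(cfg.selection_class_means[k]))
    return SelectionTable(gene_class, pv_count)


# ---------------------------------------------------------------------------
# run directory

def write_founder_table(records: Sequence[FounderRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tcdna\tprotein\tpubmed_id\tpopulation\tyears_bp\n")
        for r in records:
            fh.write(
                f"{r.gene}\t{r.cdna}\t{r.protein}\t{r.source_id}\t"
                f"{r.population}\t{format_age(r.age)}\n"
            )


def simulate_run(cfg: SimulationConfig, outdir: str | Path,
                 n_pileup_individuals: int = 30) -> dict[str, Path]:
    """Write a self-contained run directory of all pipeline inputs + truth."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    catalog, truth = simulate_catalog(cfg)
    cohorts = simulate_cohorts(cfg, catalog, truth)
    pileups, genotypes = simulate_pileups(
        cfg, catalog, cohorts["ancient"], n_individuals=n_pileup_individuals
    )
    species = simulate_species_table(cfg, catalog)
    founders = simulate_founder_table(cfg)
    selection = simulate_selection_table(
        cfg, sorted({r.gene for r in catalog})
    )

    paths = {
        "catalog": out / "catalog.tsv",
        "carriers_ancient": out / "carriers_ancient.tsv",
        "carriers_african": out / "carriers_african.tsv",
        "carriers_nonafrican": out / "carriers_nonafrican.tsv",
        "pileups": out / "pileups.tsv",
        "species": out / "species.tsv",
        "founders": out / "founders.tsv",
        "selection": out / "selection.tsv",
        "truth": out / "truth.json",
    }
    write_catalog(catalog, paths["catalog"])
    write_carriers(cohorts["ancient"], paths["carriers_ancient"])
    write_carriers(cohorts["modern_african"], paths["carriers_african"])
    write_carriers(cohorts["modern_nonafrican"], paths["carriers_nonafrican"])
    write_pileup(pileups, paths["pileups"])
    write_species_table(species, [r.pv_id for r in catalog], paths["species"])
    write_founder_table(founders, paths["founders"])
    write_selection_table(selection, paths["selection"])
    paths["truth"].write_text(
        json.dumps(
            {
                "seed": cfg.seed,
                "ancient_present": sorted(truth.ancient_present),
                "planted_genotypes": {
                    f"{i}|{p}": g for (i, p), g in sorted(genotypes.items())
                },
            },
            indent=1,
        )
    )
    return paths
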