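"""Cross-species projection of human pathogenic variants.

Each human PV is looked up at its orthologous position in a panel of
vertebrate species grouped into clades ordered by divergence from humans
(Fish most distal ... Primate closest).  A species "shares" a PV when its
observed allele equals the human alternate allele; missing orthology is
scored not-shared but tracked separately so absence-of-data stays
distinguishable from presence-of-the-reference-allele.  The per-PV nearest
shared clade — the least-diverged clade containing any sharing species —
summarizes how close to humans a variant allele is conserved.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .catalog import PVRecord
from .sharing import sharing_percentage

DEFAULT_CLADE_ORDER = (
    "Fish",
    "Sarcopterygii",
    "Aves",
    "Mammalia",
    "Afrotheria",
    "Laurasiatheria",
    "Euarchontoglires",
    "Primate",
)


@dataclass
class SpeciesAlleleTable:
    """Observed allele per (PV, species), with clade labels.

    ``clade_order`` lists clades from most distal to closest to humans;
    ``clade_rank`` is the reversed index, so rank 0 = closest (Primate by
    default) and larger ranks = more divergent.
    """

    species_clade: dict[str, str]
    alleles: dict[tuple[str, str], str]
    clade_order: tuple[str, ...] = DEFAULT_CLADE_ORDER

    def __post_init__(self) -> None:
        unknown = set(self.species_clade.values()) - set(self.clade_order)
        if unknown:
            raise ValueError(f"species assigned to unknown clades: {sorted(unknown)}")
        for (pv, sp) in self.alleles:
            if sp not in self.species_clade:
                raise ValueError(f"allele entry for unlisted species {sp!r}")

    @property
    def species(self) -> list[str]:
        return sorted(self.species_clade)

    def clade_rank(self, clade: str) -> int:
        # distance-from-human ordering: 0 = closest clade
        return len(self.clade_order) - 1 - self.clade_order.index(clade)


def read_species_table(
    path: str | Path, clade_order: Sequence[str] = DEFAULT_CLADE_ORDER
) -> SpeciesAlleleTable:
    """Read the `pv_id  species  clade  allele` TSV (empty allele = missing)."""
    species_clade: dict[str, str] = {}
    alleles: dict[tuple[str, str], str] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = {"pv_id", "species", "clade", "allele"}
        if not required <= set(header):
            raise ValueError(f"{path}: species table needs columns {sorted(required)}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            row = dict(zip(header, line.split("\t")))
            sp, clade = row["species"], row["clade"]
            if species_clade.setdefault(sp, clade) != clade:
                raise ValueError(f"species {sp!r} listed with two clades")
            if row["allele"]:
                alleles[(row["pv_id"], sp)] = row["allele"].upper()
    return SpeciesAlleleTable(species_clade, alleles, tuple(clade_order))


def write_species_table(table: SpeciesAlleleTable, pv_ids: Iterable[str],
                        path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("pv_id\tspecies\tclade\tallele\n")
        for pv in pv_ids:
            for sp in table.species:
                allele = table.alleles.get((pv, sp), "")
                fh.write(f"{pv}\t{sp}\t{table.species_clade[sp]}\t{allele}\n")


_PROTEIN_SUB = re.compile(r"^p\.\(?([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})\)?")


def _human_match_allele(pv: PVRecord, match_level: str) -> str | None:
    if match_level == "nucleotide":
        return pv.alt_allele
    m = _PROTEIN_SUB.match(pv.protein or "")
    return m.group(3) if m else None


@dataclass
class SharingMatrix:
    shared: dict[tuple[str, str], bool]
    missing: set[tuple[str, str]]
    nearest_clade: dict[str, str | None]
    pv_ids: list[str]
    table: SpeciesAlleleTable
    unknown_pv_warnings: list[str] = field(default_factory=list)

    def species_hits(self, pv_id: str) -> list[str]:
        return [sp for sp in self.table.species if self.shared.get((pv_id, sp), False)]


def project_and_match(
    catalog: Sequence[PVRecord],
    table: SpeciesAlleleTable,
    match_level: str = "nucleotide",
) -> SharingMatrix:
    """Build the PV × species boolean sharing matrix.

    ``match_level`` "nucleotide" compares the species allele with the human
    alternate base; "protein" compares it with the human mutant residue
    (three-letter code parsed from the HGVS p. substitution string; PVs whose
    protein notation is not a simple substitution are scored unmatched).
    Table keys naming pv_ids absent from the catalog are collected as
    warnings, not errors.
    """
    if match_level not in ("nucleotide", "protein"):
        raise ValueError(f"unknown match level {match_level!r}")
    by_id = {r.pv_id: r for r in catalog}
    unknown = sorted({pv for (pv, _) in table.alleles if pv not in by_id})

    shared: dict[tuple[str, str], bool] = {}
    missing: set[tuple[str, str]] = set()
    nearest: dict[str, str | None] = {}
    for pv_id, rec in by_id.items():
        target = _human_match_allele(rec, match_level)
        best_rank, best_clade = None, None
        for sp in table.species:
            allele = table.alleles.get((pv_id, sp))
            if allele is None:
                missing.add((pv_id, sp))
                shared[(pv_id, sp)] = False
                continue
            hit = target is not None and allele == target
            shared[(pv_id, sp)] = hit
            if hit:
                rank = table.clade_rank(table.species_clade[sp])
                if best_rank is None or rank < best_rank:
                    best_rank, best_clade = rank, table.species_clade[sp]
        nearest[pv_id] = best_clade
    return SharingMatrix(
        shared=shared,
        missing=missing,
        nearest_clade=nearest,
        pv_ids=[r.pv_id for r in catalog],
        table=table,
        unknown_pv_warnings=unknown,
    )


@dataclass
class CladeSummary:
    total_pvs: int
    absent_count: int
    shared_count: int
    absent_percent: float
    per_clade_pv_counts: dict[str, int]       # PVs shared with >=1 species of the clade
    per_clade_species_hits: dict[str, int]    # (pv, species) hit pairs per clade
    nearest_clade_counts: dict[str, int]

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def clade_summary(matrix: SharingMatrix) -> CladeSummary:
    """Overall and per-clade sharing report.

    A PV is "absent" when no species shares it; ``absent_percent`` is the
    headline conservation statistic (most human PVs are expected absent from
    all other vertebrates when variants arose recently in humans).
    """
    if not matrix.pv_ids:
        raise ValueError("empty sharing matrix")
    absent = sum(1 for pv in matrix.pv_ids if not matrix.species_hits(pv))
    total = len(matrix.pv_ids)
    per_clade_pv: dict[str, int] = {c: 0 for c in matrix.table.clade_order}
    per_clade_hits: dict[str, int] = {c: 0 for c in matrix.table.clade_order}
    nearest_counts: dict[str, int] = {}
    for pv in matrix.pv_ids:
        hit_clades = set()
        for sp in matrix.species_hits(pv):
            clade = matrix.table.species_clade[sp]
            hit_clades.add(clade)
            per_clade_hits[clade] += 1
        for clade in hit_clades:
            per_clade_pv[clade] += 1
        nc = matrix.nearest_clade[pv]
        if nc is not None:
            nearest_counts[nc] = nearest_counts.get(nc, 0) + 1
    return CladeSummary(
        total_pvs=total,
        absent_count=absent,
        shared_count=total - absent,
        absent_percent=sharing_percentage(absent, total, 1),
        per_clade_pv_counts=per_clade_pv,
        per_clade_species_hits=per_clade_hits,
        nearest_clade_counts=nearest_counts,
    )


def within_clade_report(matrix: SharingMatrix, clade: str) -> dict:
    """Per-species shared counts and percentages inside one focal clade.

    Percentages are over the PVs shared with at least one species of the
    focal clade (e.g. of the PVs conserved anywhere in Primate, what share
    is found in each primate species).
    """
    species = [sp for sp, c in matrix.table.species_clade.items() if c == clade]
    pvs_in_clade = {
        pv
        for pv in matrix.pv_ids
        if any(matrix.shared.get((pv, sp), False) for sp in species)
    }
    n = len(pvs_in_clade)
    rows = {}
    for sp in sorted(species):
        cnt = sum(1 for pv in pvs_in_clade if matrix.shared.get((pv, sp), False))
        rows[sp] = {
            "shared": cnt,
            "percent": sharing_percentage(cnt, n, 1) if n else None,
        }
    return {"clade": clade, "n_pvs_shared_in_clade": n, "species": rows}
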