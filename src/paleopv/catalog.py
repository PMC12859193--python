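"""Pathogenic-variant (PV) catalog and cohort carrier tables.

The catalog holds ClinVar-style records for germline variants in DNA damage
repair (DDR) genes: identity, genomic coordinates, alleles, gene symbol and
the set of repair pathways the gene participates in.  Pathway membership is
many-to-many — a gene such as ``BRCA2`` sits in both the Fanconi anemia and
homologous recombination pathways — so pathway-level counts intentionally
exceed the nonredundant variant total.

Coordinates are 1-based, fully closed, forward strand (VCF convention).
HGVS ``c.``/``p.`` strings are carried as opaque labels; the analyses key on
``pv_id`` and coordinates, never on parsed HGVS.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

PATHWAY_CODES = frozenset({"FA", "HR", "MMR", "NER", "NHEJ", "DDR", "BER", "DR"})
CLASSIFICATIONS = (
    "Pathogenic",
    "LikelyPathogenic",
    "VUS",
    "LikelyBenign",
    "Benign",
)
PATHOGENIC_CLASSES = frozenset({"Pathogenic", "LikelyPathogenic"})
COHORTS = (
    "ancient",
    "neanderthal",
    "denisovan",
    "modern_african",
    "modern_nonafrican",
)
MODERN_COHORTS = frozenset({"modern_african", "modern_nonafrican"})
ZYGOSITIES = ("het", "hom", "present_unknown")

CATALOG_COLUMNS = [
    "pv_id", "gene", "cdna", "protein", "chrom", "pos",
    "ref", "alt", "pathways", "classification",
]
CARRIER_COLUMNS = ["ind_id", "cohort", "date_bp", "region", "pv_id", "zygosity"]


class CatalogError(ValueError):
    """Malformed catalog or carrier input."""


@dataclass(frozen=True)
class PVRecord:
    """One catalogued pathogenic variant."""

    pv_id: str
    gene: str
    cdna: str
    protein: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    pathways: frozenset[str]
    classification: str = "Pathogenic"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise CatalogError(f"{self.pv_id}: position must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise CatalogError(f"{self.pv_id}: ref and alt alleles are identical")
        bad = set(self.pathways) - PATHWAY_CODES
        if bad:
            raise CatalogError(f"{self.pv_id}: unknown pathway codes {sorted(bad)}")
        if self.classification not in CLASSIFICATIONS:
            raise CatalogError(
                f"{self.pv_id}: unknown classification {self.classification!r}"
            )

    @property
    def is_snv(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1

    @property
    def is_pathogenic(self) -> bool:
        return self.classification in PATHOGENIC_CLASSES


@dataclass
class Individual:
    """One cohort member with the set of PVs it carries.

    ``date_bp`` is years before present; it may be None for modern cohorts
    and for the minority of ancient samples that lack dating information.
    ``carried`` maps pv_id -> zygosity ("het", "hom" or "present_unknown").
    """

    ind_id: str
    cohort: str
    date_bp: float | None = None
    region: str = ""
    carried: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise CatalogError(f"{self.ind_id}: unknown cohort {self.cohort!r}")
        for pv, zyg in self.carried.items():
            if zyg not in ZYGOSITIES:
                raise CatalogError(f"{self.ind_id}/{pv}: bad zygosity {zyg!r}")

    @property
    def pv_ids(self) -> set[str]:
        return set(self.carried)


@dataclass
class CountTable:
    """Per-gene and per-pathway nonredundant PV counts.

    ``per_pathway`` values are (genes_with_pv, pv_count) pairs; because a
    gene may belong to several pathways, summing pathway counts can exceed
    ``total_nonredundant``.
    """

    per_gene: dict[str, int]
    per_pathway: dict[str, tuple[int, int]]
    total_nonredundant: int


# ---------------------------------------------------------------------------
# I/O

def _parse_catalog_row(fields: Mapping[str, str], lineno: int) -> PVRecord:
    try:
        pathways = frozenset(
            p for p in fields["pathways"].split("|") if p
        )
        return PVRecord(
            pv_id=fields["pv_id"],
            gene=fields["gene"],
            cdna=fields["cdna"],
            protein=fields["protein"],
            chrom=fields["chrom"],
            pos=int(fields["pos"]),
            ref_allele=fields["ref"].upper(),
            alt_allele=fields["alt"].upper(),
            pathways=pathways,
            classification=fields["classification"],
        )
    except (KeyError, ValueError, CatalogError) as exc:
        raise CatalogError(f"line {lineno}: {exc}") from exc


def read_catalog(
    path: str | Path,
    format: str = "tsv",
    keep_all_classes: bool = False,
) -> list[PVRecord]:
    """Read a PV catalog from TSV or VCF, in file order.

    By default only Pathogenic / LikelyPathogenic records are returned;
    ``keep_all_classes=True`` retains benign and VUS rows too.  Duplicate
    ``pv_id`` values are a hard error.
    """
    if format == "tsv":
        records = list(_read_catalog_tsv(Path(path)))
    elif format == "vcf":
        records = list(_read_catalog_vcf(Path(path)))
    else:
        raise ValueError(f"unknown catalog format {format!r}")

    seen: set[str] = set()
    for rec in records:
        if rec.pv_id in seen:
            raise CatalogError(f"duplicate pv_id {rec.pv_id!r} in {path}")
        seen.add(rec.pv_id)
    if not keep_all_classes:
        records = [r for r in records if r.is_pathogenic]
    return records


def _read_catalog_tsv(path: Path) -> Iterable[PVRecord]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            return
        cols = header.split("\t")
        missing = set(CATALOG_COLUMNS) - set(cols)
        if missing:
            raise CatalogError(f"{path}: missing catalog columns {sorted(missing)}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            values = line.split("\t")
            if len(values) != len(cols):
                raise CatalogError(
                    f"line {lineno}: expected {len(cols)} fields, got {len(values)}"
                )
            yield _parse_catalog_row(dict(zip(cols, values)), lineno)


_VCF_CLNSIG = {
    "Pathogenic": "Pathogenic",
    "Likely_pathogenic": "LikelyPathogenic",
    "Uncertain_significance": "VUS",
    "Likely_benign": "LikelyBenign",
    "Benign": "Benign",
}


def _read_catalog_vcf(path: Path) -> Iterable[PVRecord]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    try:
        for lineno, var in enumerate(vcf, start=1):
            gene = var.INFO.get("GENE")
            pathways = var.INFO.get("PATHWAYS") or ""
            clnsig = var.INFO.get("CLNSIG") or "Pathogenic"
            if gene is None:
                raise CatalogError(f"VCF record {lineno}: missing GENE INFO key")
            yield PVRecord(
                pv_id=var.ID or f"{var.CHROM}:{var.POS}:{var.REF}>{var.ALT[0]}",
                gene=gene,
                cdna=var.INFO.get("CDNA") or "",
                protein=var.INFO.get("PROTEIN") or "",
                chrom=var.CHROM,
                pos=var.POS,
                ref_allele=var.REF,
                alt_allele=var.ALT[0],
                pathways=frozenset(p for p in pathways.split("|") if p),
                classification=_VCF_CLNSIG.get(clnsig, clnsig),
            )
    finally:
        vcf.close()


def write_catalog(records: Iterable[PVRecord], path: str | Path) -> None:
    """Write the catalog TSV dialect (inverse of :func:`read_catalog`)."""
    with open(path, "w") as fh:
        fh.write("\t".join(CATALOG_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.pv_id, r.gene, r.cdna, r.protein, r.chrom, str(r.pos),
                        r.ref_allele, r.alt_allele,
                        "|".join(sorted(r.pathways)), r.classification,
                    ]
                )
                + "\n"
            )


def read_carriers(path: str | Path) -> list[Individual]:
    """Read the long-format carrier TSV: one row per (individual, PV).

    Rows with an empty pv_id register the individual with no carried PVs,
    so zero-carrier cohort members survive a round trip.
    """
    individuals: dict[str, Individual] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = set(CARRIER_COLUMNS) - set(header)
        if missing:
            raise CatalogError(f"{path}: missing carrier columns {sorted(missing)}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            row = dict(zip(header, line.split("\t")))
            ind_id = row["ind_id"]
            if ind_id not in individuals:
                date = row["date_bp"]
                individuals[ind_id] = Individual(
                    ind_id=ind_id,
                    cohort=row["cohort"],
                    date_bp=float(date) if date not in ("", "NA") else None,
                    region=row["region"],
                )
            if row["pv_id"]:
                zyg = row["zygosity"] or "present_unknown"
                if zyg not in ZYGOSITIES:
                    raise CatalogError(f"line {lineno}: bad zygosity {zyg!r}")
                individuals[ind_id].carried[row["pv_id"]] = zyg
    return list(individuals.values())


def write_carriers(individuals: Iterable[Individual], path: str | Path) -> None:
    buf = io.StringIO()
    buf.write("\t".join(CARRIER_COLUMNS) + "\n")
    for ind in individuals:
        date = "" if ind.date_bp is None else f"{ind.date_bp:g}"
        base = f"{ind.ind_id}\t{ind.cohort}\t{date}\t{ind.region}"
        if not ind.carried:
            buf.write(f"{base}\t\t\n")
        for pv, zyg in sorted(ind.carried.items()):
            buf.write(f"{base}\t{pv}\t{zyg}\n")
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# Counting

def count_by_gene_and_pathway(
    catalog: Iterable[PVRecord],
    restrict_to: set[str] | None = None,
) -> CountTable:
    """Nonredundant per-gene and per-pathway PV counts.

    A variant counts once for its gene and once for *every* pathway its gene
    belongs to; ``total_nonredundant`` counts each variant exactly once.
    ``restrict_to`` limits counting to the given pv_ids (e.g. the subset
    observed in one cohort).
    """
    catalog = list(catalog)
    if restrict_to is not None:
        known = {r.pv_id for r in catalog}
        unknown = restrict_to - known
        if unknown:
            raise CatalogError(
                f"restrict_to contains ids absent from catalog: {sorted(unknown)[:5]}"
            )
        catalog = [r for r in catalog if r.pv_id in restrict_to]

    per_gene: dict[str, int] = {}
    pathway_pvs: dict[str, int] = {}
    pathway_genes: dict[str, set[str]] = {}
    for rec in catalog:
        per_gene[rec.gene] = per_gene.get(rec.gene, 0) + 1
        for pw in rec.pathways:
            pathway_pvs[pw] = pathway_pvs.get(pw, 0) + 1
            pathway_genes.setdefault(pw, set()).add(rec.gene)

    per_pathway = {
        pw: (len(pathway_genes[pw]), pathway_pvs[pw]) for pw in pathway_pvs
    }
    return CountTable(
        per_gene=per_gene,
        per_pathway=per_pathway,
        total_nonredundant=len(catalog),
    )
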