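"""Founder pathogenic variants: haplotype-dated ages and population lists.

Founder PVs descend from a single ancestral carrier and can be dated by the
length of the haplotype shared among present-day carriers.  This module
treats published ages as inputs: it parses the heterogeneous age notation
used in the literature (point ages, ranges like "1,500-750", bounds like
">250" or "<200", all in years before present), orders and filters records
by a representative age, and intersects population-specific founder lists
with cohort PV sets (e.g. Portuguese BRCA founder variants among the PVs of
an admixed cohort).

A curated table of haplotype-dated DDR founder PVs compiled from the
published literature ships with the package (``load_reference_founders``).
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

AGE_KINDS = ("point", "range", "lower_bound", "upper_bound")


class AgeParseError(ValueError):
    pass


@dataclass(frozen=True)
class AgeSpec:
    """A published founder age: point, older–younger range, or one-sided bound.

    All values are years BP.  ``representative`` collapses the age to one
    number for ordering: the older bound of a range and the stated bound for
    ">"/"<" forms — a conservative "no younger than written" reading.  The
    ``midpoint`` alternative averages range endpoints.
    """

    kind: str
    older: float
    younger: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in AGE_KINDS:
            raise AgeParseError(f"unknown age kind {self.kind!r}")
        if self.older < 0 or (self.younger is not None and self.younger < 0):
            raise AgeParseError("ages must be non-negative")
        if self.kind == "range":
            if self.younger is None or self.older < self.younger:
                raise AgeParseError("range must run older -> younger")
        elif self.younger is not None:
            raise AgeParseError(f"{self.kind} age takes a single value")

    @property
    def representative(self) -> float:
        return self.older

    @property
    def midpoint(self) -> float:
        if self.kind == "range":
            return (self.older + self.younger) / 2
        return self.older


_DASHES = "‐‑‒–—−"


def _num(text: str) -> float:
    value = float(text.replace(",", ""))
    if value < 0:
        raise AgeParseError(f"negative age {text!r}")
    return value


def parse_age(text: str) -> AgeSpec:
    """Parse an age string: "8,675", "1,500-750", ">250", "<200"."""
    raw = text
    text = text.strip()
    for d in _DASHES:
        text = text.replace(d, "-")
    if not text:
        raise AgeParseError("empty age string")
    try:
        if text.startswith(">"):
            return AgeSpec("lower_bound", _num(text[1:]))
        if text.startswith("<"):
            return AgeSpec("upper_bound", _num(text[1:]))
        if "-" in text:
            older_s, younger_s = text.split("-", 1)
            return AgeSpec("range", _num(older_s), _num(younger_s))
        return AgeSpec("point", _num(text))
    except (ValueError, AgeParseError) as exc:
        raise AgeParseError(f"cannot parse age {raw!r}: {exc}") from exc


def format_age(age: AgeSpec) -> str:
    """Inverse of :func:`parse_age` (canonical, comma-free)."""
    if age.kind == "point":
        return f"{age.older:g}"
    if age.kind == "range":
        return f"{age.older:g}-{age.younger:g}"
    prefix = ">" if age.kind == "lower_bound" else "<"
    return f"{prefix}{age.older:g}"


@dataclass(frozen=True)
class FounderRecord:
    gene: str
    cdna: str
    protein: str
    population: str
    age: AgeSpec
    source_id: str = ""

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("founder record needs a gene symbol")

    @property
    def label(self) -> str:
        return f"{self.gene} {self.cdna}"


FOUNDER_COLUMNS = ["gene", "cdna", "protein", "pubmed_id", "population", "years_bp"]


def read_founder_table(path: str | Path) -> list[FounderRecord]:
    """Read the founder TSV: gene, cdna, protein, pubmed_id, population, years_bp."""
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = set(FOUNDER_COLUMNS) - set(header)
        if missing:
            raise ValueError(f"{path}: missing founder columns {sorted(missing)}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            row = dict(zip(header, line.split("\t")))
            try:
                age = parse_age(row["years_bp"])
            except AgeParseError as exc:
                raise AgeParseError(f"line {lineno}: {exc}") from exc
            records.append(
                FounderRecord(
                    gene=row["gene"],
                    cdna=row["cdna"],
                    protein=row["protein"],
                    population=row["population"],
                    age=age,
                    source_id=row["pubmed_id"],
                )
            )
    return records


def load_reference_founders() -> list[FounderRecord]:
    """The packaged literature-curated table of haplotype-dated founder PVs."""
    ref = importlib.resources.files("paleopv.data") / "founder_ages.tsv"
    with importlib.resources.as_file(ref) as path:
        return read_founder_table(path)


def oldest_founder(records: Sequence[FounderRecord]) -> tuple[FounderRecord, float]:
    """The record with the largest representative age (first on ties)."""
    if not records:
        raise ValueError("no founder records")
    best = max(records, key=lambda r: r.age.representative)
    return best, best.age.representative


def filter_by_age(
    records: Sequence[FounderRecord], threshold_bp: float
) -> tuple[list[FounderRecord], list[FounderRecord]]:
    """Partition records into (within, exceeding) by representative age."""
    if threshold_bp <= 0:
        raise ValueError("threshold must be positive")
    within = [r for r in records if r.age.representative <= threshold_bp]
    exceeding = [r for r in records if r.age.representative > threshold_bp]
    return within, exceeding


@dataclass
class FounderIntersection:
    per_population: dict[str, set[str]]
    per_gene: dict[str, dict[str, set[str]]]
    total: int

    def to_dict(self) -> dict:
        return {
            "per_population": {p: sorted(s) for p, s in self.per_population.items()},
            "per_gene": {
                p: {g: sorted(s) for g, s in by_gene.items()}
                for p, by_gene in self.per_gene.items()
            },
            "total": self.total,
        }


def founder_intersection(
    cohort_pvs: set[str],
    founder_lists: Mapping[str, set[str]],
    gene_of: Mapping[str, str] | None = None,
) -> FounderIntersection:
    """Match a cohort's PVs against per-population founder lists.

    Returns matches per source population, an optional per-gene breakdown
    (via ``gene_of``: pv_id -> gene), and the nonredundant grand total of
    cohort PVs matching any founder list.
    """
    per_population = {
        pop: cohort_pvs & founders for pop, founders in founder_lists.items()
    }
    per_gene: dict[str, dict[str, set[str]]] = {}
    if gene_of is not None:
        for pop, matched in per_population.items():
            breakdown: dict[str, set[str]] = {}
            for pv in matched:
                breakdown.setdefault(gene_of.get(pv, "?"), set()).add(pv)
            per_gene[pop] = breakdown
    all_matched: set[str] = set()
    for matched in per_population.values():
        all_matched |= matched
    return FounderIntersection(
        per_population=per_population, per_gene=per_gene, total=len(all_matched)
    )
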