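"""Cohort-level sharing of pathogenic variants between ancient and modern humans.

Covers the three descriptive analyses: (i) the three-way Venn partition of
ancient-cohort PVs by their presence in modern African and non-African
carriers, (ii) per-gene load comparison between cohorts, and (iii) temporal
profiles of dated ancient carriers binned in years before present (BP).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

from .catalog import CountTable, Individual


def sharing_percentage(shared_count: int, total_count: int, digits: int = 1) -> float:
    """100 * shared/total, rounded half-up to ``digits`` decimals."""
    if total_count <= 0:
        raise ValueError("total_count must be positive")
    if not 0 <= shared_count <= total_count:
        raise ValueError("shared_count must lie in [0, total_count]")
    pct = Decimal(100 * shared_count) / Decimal(total_count)
    quantum = Decimal(1).scaleb(-digits)
    return float(pct.quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass
class VennPartition:
    """Partition of ancient-cohort PVs by modern-cohort membership.

    ``fractions`` are over the shared PVs only (``neither`` excluded), the
    reporting base under which the three fractions sum to 1; fractions over
    all ancient PVs are exposed as ``fractions_over_all`` since either base
    is a defensible summary.
    """

    only_nonafrican: set[str]
    both: set[str]
    only_african: set[str]
    neither: set[str]

    @property
    def n_shared(self) -> int:
        return len(self.only_nonafrican) + len(self.both) + len(self.only_african)

    @property
    def fractions(self) -> tuple[float, float, float] | None:
        n = self.n_shared
        if n == 0:
            return None
        return (
            len(self.only_nonafrican) / n,
            len(self.both) / n,
            len(self.only_african) / n,
        )

    @property
    def fractions_over_all(self) -> tuple[float, float, float] | None:
        n = self.n_shared + len(self.neither)
        if n == 0:
            return None
        return (
            len(self.only_nonafrican) / n,
            len(self.both) / n,
            len(self.only_african) / n,
        )

    def to_dict(self) -> dict:
        return {
            "only_nonafrican": sorted(self.only_nonafrican),
            "both": sorted(self.both),
            "only_african": sorted(self.only_african),
            "neither": sorted(self.neither),
            "fractions_shared_base": self.fractions,
            "fractions_all_base": self.fractions_over_all,
        }


def venn_partition(
    ancient_pvs: set[str],
    african_pvs: set[str],
    nonafrican_pvs: set[str],
) -> VennPartition:
    """Split the ancient PV set by membership in the two modern sets."""
    both = ancient_pvs & african_pvs & nonafrican_pvs
    only_african = (ancient_pvs & african_pvs) - nonafrican_pvs
    only_nonafrican = (ancient_pvs & nonafrican_pvs) - african_pvs
    neither = ancient_pvs - african_pvs - nonafrican_pvs
    return VennPartition(
        only_nonafrican=only_nonafrican,
        both=both,
        only_african=only_african,
        neither=neither,
    )


@dataclass
class GeneLoadRow:
    gene: str
    ancient_share: float
    modern_share: float

    @property
    def discordance(self) -> float:
        return self.ancient_share - self.modern_share


def load_comparison(
    ancient_counts: CountTable, modern_counts: CountTable
) -> list[GeneLoadRow]:
    """Per-gene PV load (share of the cohort's nonredundant total) in each
    cohort, ranked by absolute discordance.

    Genes seen in one cohort only get share 0 on the missing side — these are
    exactly the candidates for differential load (e.g. genes over-represented
    among ancient carriers relative to modern ones).
    """
    if ancient_counts.total_nonredundant == 0 or modern_counts.total_nonredundant == 0:
        raise ValueError("both count tables must be nonempty")
    genes = sorted(set(ancient_counts.per_gene) | set(modern_counts.per_gene))
    rows = [
        GeneLoadRow(
            gene=g,
            ancient_share=ancient_counts.per_gene.get(g, 0)
            / ancient_counts.total_nonredundant,
            modern_share=modern_counts.per_gene.get(g, 0)
            / modern_counts.total_nonredundant,
        )
        for g in genes
    ]
    rows.sort(key=lambda r: (-abs(r.discordance), r.gene))
    return rows


@dataclass
class TemporalProfile:
    """Histogram of dated ancient PV carriers on the years-BP axis.

    Bins are half-open ``[start, end)`` in BP, non-overlapping, listed from
    oldest to youngest.  ``first_occurrence`` maps each gene to the date of
    its oldest dated carrier (the gene's first appearance walking forward in
    time).  Undated carriers are excluded from bins and counted separately.
    """

    bins: list[tuple[float, float, int]]
    first_occurrence: dict[str, float]
    oldest: tuple[str, float] | None
    youngest: tuple[str, float] | None
    n_undated: int
    counting_mode: str = "carrier_occurrence"


def temporal_profile(
    individuals: Sequence[Individual],
    gene_of: Mapping[str, str] | None = None,
    bin_width: float = 1000.0,
    counting_mode: str = "carrier_occurrence",
) -> TemporalProfile:
    """Bin dated carriers by age and locate oldest/youngest carried PVs.

    ``counting_mode`` "carrier_occurrence" counts one unit per
    (individual, carried PV) pair; "individual" counts each carrier once
    regardless of how many PVs it carries.  ``gene_of`` maps pv_id -> gene
    for the per-gene first-occurrence table (omitted genes are skipped).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if counting_mode not in ("carrier_occurrence", "individual"):
        raise ValueError(f"unknown counting mode {counting_mode!r}")

    def weight(ind: Individual) -> int:
        return len(ind.carried) if counting_mode == "carrier_occurrence" else 1

    dated = [i for i in individuals if i.date_bp is not None and i.carried]
    n_undated = sum(weight(i) for i in individuals if i.date_bp is None and i.carried)

    first_occurrence: dict[str, float] = {}
    oldest: tuple[str, float] | None = None
    youngest: tuple[str, float] | None = None
    for ind in dated:
        for pv in ind.carried:
            if oldest is None or ind.date_bp > oldest[1]:
                oldest = (pv, ind.date_bp)
            if youngest is None or ind.date_bp < youngest[1]:
                youngest = (pv, ind.date_bp)
            if gene_of is not None and pv in gene_of:
                g = gene_of[pv]
                if g not in first_occurrence or ind.date_bp > first_occurrence[g]:
                    first_occurrence[g] = ind.date_bp

    bins: list[tuple[float, float, int]] = []
    if dated:
        max_bp = max(i.date_bp for i in dated)
        n_bins = int(max_bp // bin_width) + 1
        counts = [0] * n_bins
        for ind in dated:
            counts[int(ind.date_bp // bin_width)] += weight(ind)
        # oldest bin first, [start, end) descending in BP
        for b in range(n_bins - 1, -1, -1):
            bins.append(((b + 1) * bin_width, b * bin_width, counts[b]))

    return TemporalProfile(
        bins=bins,
        first_occurrence=first_occurrence,
        oldest=oldest,
        youngest=youngest,
        n_undated=n_undated,
        counting_mode=counting_mode,
    )


def plot_temporal_profile(profile: TemporalProfile, path: str) -> None:
    """Bar chart of dated-carrier counts per BP bin (oldest on the left)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    starts = [b[0] for b in profile.bins]
    counts = [b[2] for b in profile.bins]
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.bar(range(len(starts)), counts, color="#46629c")
    ax.set_xticks(range(len(starts)))
    ax.set_xticklabels([f"{int(s)}" for s in starts], rotation=90, fontsize=6)
    ax.set_xlabel("years BP (bin start)")
    ax.set_ylabel("dated carriers")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
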