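"""Rarefaction of modern cohorts against the ancient-shared PV set.

Cohorts of very different size (tens of thousands of non-Africans versus a
few thousand Africans) cannot be compared directly on "what fraction of the
PVs we discover in this cohort is also found in ancient genomes", because PV
discovery grows with sample size.  Rarefaction equalizes the footing:
repeatedly draw subgroups of n individuals without replacement, take the
union of their carried PVs as the subgroup's discovered set, and record the
proportion of discovered PVs present in the ancient cohort.  Medians and
95th percentiles per subgroup size summarize the resampling distribution.

Randomness is counter-based: each (size, rep) cell derives its own stream
from the root seed via ``numpy.random.SeedSequence`` spawn keys, so results
are bitwise reproducible and independent of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .catalog import Individual


@dataclass(frozen=True)
class RarefactionDesign:
    subgroup_sizes: tuple[int, ...]
    n_reps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if any(s < 1 for s in self.subgroup_sizes):
            raise ValueError("subgroup sizes must be positive")
        if list(self.subgroup_sizes) != sorted(self.subgroup_sizes):
            raise ValueError("subgroup sizes must be ascending")

    @classmethod
    def default_for(cls, cohort_size: int, n_sizes: int = 15,
                    smallest: int = 1000, n_reps: int = 1000, seed: int = 0
                    ) -> "RarefactionDesign":
        """Log-spaced sizes from ``smallest`` up to the cohort size."""
        smallest = min(smallest, cohort_size)
        sizes = np.unique(
            np.round(
                np.logspace(np.log10(smallest), np.log10(cohort_size), n_sizes)
            ).astype(int)
        )
        return cls(tuple(int(s) for s in sizes), n_reps=n_reps, seed=seed)


@dataclass
class SizeSummary:
    size: int
    proportions: np.ndarray          # per informative rep
    discovered_counts: np.ndarray    # per rep (all reps)
    n_zero_discovery: int

    @property
    def median(self) -> float:
        return float(np.median(self.proportions))

    @property
    def percentile_95(self) -> float:
        return float(np.percentile(self.proportions, 95))

    def percentile(self, q: float) -> float:
        return float(np.percentile(self.proportions, q))


@dataclass
class RarefactionResult:
    design: RarefactionDesign
    per_size: list[SizeSummary] = field(default_factory=list)

    def summary_rows(self) -> list[dict]:
        return [
            {
                "size": s.size,
                "median": s.median,
                "p5": s.percentile(5),
                "p95": s.percentile_95,
                "mean_discovered": float(np.mean(s.discovered_counts)),
                "n_zero_discovery": s.n_zero_discovery,
            }
            for s in self.per_size
        ]


def _rng_for(seed: int, size_index: int, rep: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(size_index, rep))
    )


def rarefy(
    cohort: Sequence[Individual],
    ancient_pvs: set[str],
    design: RarefactionDesign,
    denominator: str = "subsample",
) -> RarefactionResult:
    """Run the rarefaction resampling for one cohort.

    For each size n and replicate: sample n individuals without replacement,
    pool their carried PVs, and compute the ancient-shared proportion.  The
    default denominator is the subsample's own discovered PV set; the
    "cohort" mode divides by the full cohort's PV count instead.  Replicates
    that discover no PVs are excluded from the proportion summaries and
    reported as ``n_zero_discovery``.
    """
    if denominator not in ("subsample", "cohort"):
        raise ValueError(f"unknown denominator mode {denominator!r}")
    n_cohort = len(cohort)
    for s in design.subgroup_sizes:
        if s > n_cohort:
            raise ValueError(f"subgroup size {s} exceeds cohort size {n_cohort}")

    carried_sets = [frozenset(ind.carried) for ind in cohort]
    cohort_pv_total = len(frozenset().union(*carried_sets)) if carried_sets else 0

    result = RarefactionResult(design=design)
    for si, size in enumerate(design.subgroup_sizes):
        props: list[float] = []
        discovered_counts = np.empty(design.n_reps, dtype=np.int64)
        n_zero = 0
        for rep in range(design.n_reps):
            rng = _rng_for(design.seed, si, rep)
            idx = rng.choice(n_cohort, size=size, replace=False)
            discovered: set[str] = set()
            for i in idx:
                discovered |= carried_sets[i]
            discovered_counts[rep] = len(discovered)
            if not discovered:
                n_zero += 1
                continue
            shared = len(discovered & ancient_pvs)
            denom = len(discovered) if denominator == "subsample" else cohort_pv_total
            props.append(shared / denom)
        result.per_size.append(
            SizeSummary(
                size=size,
                proportions=np.asarray(props, dtype=float),
                discovered_counts=discovered_counts,
                n_zero_discovery=n_zero,
            )
        )
    return result


@dataclass
class CurveComparison:
    rows: list[dict]

    @property
    def all_positive(self) -> bool:
        return all(r["median_diff"] > 0 for r in self.rows)

    @property
    def any_band_overlap(self) -> bool:
        return any(r["bands_overlap"] for r in self.rows)


def compare_curves(result_a: RarefactionResult, result_b: RarefactionResult) -> CurveComparison:
    """Per-size median difference (a − b) and [5th, 95th] band overlap."""
    if result_a.design.subgroup_sizes != result_b.design.subgroup_sizes:
        raise ValueError("rarefaction designs use different subgroup sizes")
    rows = []
    for sa, sb in zip(result_a.per_size, result_b.per_size):
        lo_a, hi_a = sa.percentile(5), sa.percentile(95)
        lo_b, hi_b = sb.percentile(5), sb.percentile(95)
        rows.append(
            {
                "size": sa.size,
                "median_a": sa.median,
                "median_b": sb.median,
                "median_diff": sa.median - sb.median,
                "bands_overlap": (lo_a <= hi_b) and (lo_b <= hi_a),
            }
        )
    return CurveComparison(rows)


def plot_curves(results: dict[str, RarefactionResult], path: str) -> None:
    """Median sharing-proportion curves with 5–95% ribbons per cohort."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, res in results.items():
        sizes = [s.size for s in res.per_size]
        med = [s.median for s in res.per_size]
        lo = [s.percentile(5) for s in res.per_size]
        hi = [s.percentile(95) for s in res.per_size]
        ax.plot(sizes, med, marker="o", label=label)
        ax.fill_between(sizes, lo, hi, alpha=0.2)
    ax.set_xscale("log")
    ax.set_xlabel("subgroup size (individuals)")
    ax.set_ylabel("proportion of discovered PVs shared with ancient cohort")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
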