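"""End-to-end orchestration: inputs -> per-stage results -> report bundle.

``run_all`` wires the modules in pipeline order (catalog, presence calling,
sharing, rarefaction, cross-species projection, selection bootstrap,
founder analysis), writes one JSON report plus per-stage TSVs, and stamps
every output with the configuration hash and seed.  Stages never mutate
each other's inputs; each consumes files or in-memory results only.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import catalog as cat
from . import founder as fnd
from . import phylo as phy
from . import presence as prs
from . import rarefaction as rar
from . import selection as sel
from . import sharing as shr

logger = logging.getLogger("paleopv")

REPORT_SCHEMA_VERSION = 1


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Paths to all pipeline inputs plus module parameters."""

    catalog: str
    carriers_ancient: str
    carriers_african: str
    carriers_nonafrican: str
    outdir: str
    pileups: str | None = None
    species: str | None = None
    founders: str | None = None
    selection: str | None = None
    seed: int = 0
    catalog_format: str = "tsv"
    bin_width: float = 1000.0
    rarefaction_sizes: list[int] = field(default_factory=list)
    rarefaction_reps: int = 200
    founder_age_threshold: float = 4000.0
    caller: prs.CallerConfig = field(default_factory=prs.CallerConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        caller = prs.CallerConfig(**raw.pop("caller", {}))
        try:
            return cls(caller=caller, **raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def validate(self) -> None:
        required = {
            "catalog": self.catalog,
            "carriers_ancient": self.carriers_ancient,
            "carriers_african": self.carriers_african,
            "carriers_nonafrican": self.carriers_nonafrican,
        }
        optional = {
            "pileups": self.pileups,
            "species": self.species,
            "founders": self.founders,
            "selection": self.selection,
        }
        for name, p in required.items():
            if not p or not Path(p).exists():
                raise ConfigError(f"input {name!r} missing: {p}")
        for name, p in optional.items():
            if p is not None and not Path(p).exists():
                raise ConfigError(f"input {name!r} missing: {p}")

    def digest(self) -> str:
        payload = {k: v for k, v in asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def run_all(config: RunConfig) -> dict:
    """Execute every stage and write the report bundle; returns the report."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.digest(), "seed": config.seed,
             "schema_version": REPORT_SCHEMA_VERSION}
    report: dict = {"stamp": stamp, "stages": {}}

    def stage(name):
        def deco(fn):
            try:
                logger.info("stage %s: start", name)
                result = fn()
                report["stages"][name] = result
                logger.info("stage %s: done", name)
            except Exception as exc:  # noqa: BLE001 - re-raised with context
                raise StageError(name, exc) from exc
        return deco

    state: dict = {}

    @stage("catalog")
    def _catalog():
        records = cat.read_catalog(config.catalog, format=config.catalog_format)
        state["catalog"] = records
        state["gene_of"] = {r.pv_id: r.gene for r in records}
        counts = cat.count_by_gene_and_pathway(records)
        return {
            "n_records": len(records),
            "n_genes": len(counts.per_gene),
            "total_nonredundant": counts.total_nonredundant,
        }

    @stage("presence")
    def _presence():
        if config.pileups is None:
            return {"skipped": True}
        sites = prs.read_pileup(config.pileups)
        calls = prs.call_all(state["catalog"], sites, config.caller)
        prs.write_calls(calls, out / "presence_calls.tsv")
        tally = {"present": 0, "absent": 0, "uncallable": 0}
        for c in calls:
            tally[c.call] += 1
        state["presence_calls"] = calls
        return {"n_sites": len(sites), **tally}

    @stage("sharing")
    def _sharing():
        ancient = cat.read_carriers(config.carriers_ancient)
        african = cat.read_carriers(config.carriers_african)
        nonafrican = cat.read_carriers(config.carriers_nonafrican)
        state.update(ancient=ancient, african=african, nonafrican=nonafrican)
        ancient_pvs = set().union(*(i.pv_ids for i in ancient)) if ancient else set()
        african_pvs = set().union(*(i.pv_ids for i in african)) if african else set()
        nonafrican_pvs = (
            set().union(*(i.pv_ids for i in nonafrican)) if nonafrican else set()
        )
        state["ancient_pvs"] = ancient_pvs
        venn = shr.venn_partition(ancient_pvs, african_pvs, nonafrican_pvs)
        profile = shr.temporal_profile(
            ancient, gene_of=state["gene_of"], bin_width=config.bin_width
        )
        catalog_ids = {r.pv_id for r in state["catalog"]}
        anc_counts = cat.count_by_gene_and_pathway(
            state["catalog"], restrict_to=ancient_pvs & catalog_ids
        )
        mod_counts = cat.count_by_gene_and_pathway(
            state["catalog"],
            restrict_to=(african_pvs | nonafrican_pvs) & catalog_ids,
        )
        loads = (
            shr.load_comparison(anc_counts, mod_counts)
            if anc_counts.total_nonredundant and mod_counts.total_nonredundant
            else []
        )
        shared_pct = (
            shr.sharing_percentage(
                len(ancient_pvs & catalog_ids), len(catalog_ids), 1
            )
            if catalog_ids
            else None
        )
        return {
            "venn": venn.to_dict(),
            "ancient_shared_percent_of_catalog": shared_pct,
            "temporal": {
                "oldest": profile.oldest,
                "youngest": profile.youngest,
                "n_undated": profile.n_undated,
                "bins": profile.bins,
            },
            "load_top_discordant": [
                {"gene": r.gene, "ancient_share": r.ancient_share,
                 "modern_share": r.modern_share, "discordance": r.discordance}
                for r in loads[:10]
            ],
        }

    @stage("rarefaction")
    def _rarefaction():
        african, nonafrican = state["african"], state["nonafrican"]
        smaller = min(len(african), len(nonafrican))
        sizes = config.rarefaction_sizes or [
            int(s) for s in rar.RarefactionDesign.default_for(
                smaller, n_sizes=8, smallest=max(10, smaller // 10)
            ).subgroup_sizes
        ]
        design = rar.RarefactionDesign(
            tuple(sizes), n_reps=config.rarefaction_reps, seed=config.seed
        )
        res_naf = rar.rarefy(nonafrican, state["ancient_pvs"], design)
        res_afr = rar.rarefy(african, state["ancient_pvs"], design)
        comparison = rar.compare_curves(res_naf, res_afr)
        with open(out / "rarefaction.tsv", "w") as fh:
            fh.write("cohort\tsize\tmedian\tp5\tp95\tmean_discovered\n")
            for label, res in (("nonafrican", res_naf), ("african", res_afr)):
                for row in res.summary_rows():
                    fh.write(
                        f"{label}\t{row['size']}\t{row['median']:.6f}\t"
                        f"{row['p5']:.6f}\t{row['p95']:.6f}\t{row['mean_discovered']:.2f}\n"
                    )
        return {
            "sizes": sizes,
            "nonafrican": res_naf.summary_rows(),
            "african": res_afr.summary_rows(),
            "separation": comparison.rows,
            "all_sizes_nonafrican_above": comparison.all_positive,
        }

    @stage("phylo")
    def _phylo():
        if config.species is None:
            return {"skipped": True}
        table = phy.read_species_table(config.species)
        matrix = phy.project_and_match(state["catalog"], table)
        summary = phy.clade_summary(matrix)
        closest = table.clade_order[-1]
        return {
            "summary": summary.to_dict(),
            "within_closest_clade": phy.within_clade_report(matrix, closest),
        }

    @stage("selection")
    def _selection():
        if config.selection is None:
            return {"skipped": True}
        table = sel.read_selection_table(config.selection)
        result = sel.bootstrap_group_test(
            table, "positive", "negative", n_boot=10_000, seed=config.seed
        )
        return {
            "mean_positive": result.mean_a,
            "mean_negative": result.mean_b,
            "observed_diff": result.observed_diff,
            "p_value": result.p_value,
        }

    @stage("founder")
    def _founder():
        if config.founders is None:
            return {"skipped": True}
        records = fnd.read_founder_table(config.founders)
        oldest, age = fnd.oldest_founder(records)
        within, exceeding = fnd.filter_by_age(records, config.founder_age_threshold)
        return {
            "n_records": len(records),
            "oldest": {"label": oldest.label, "age_bp": age},
            "n_within_threshold": len(within),
            "n_exceeding_threshold": len(exceeding),
            "exceeding": [r.label for r in exceeding],
        }

    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=1, default=str))
    logger.info("report written to %s", report_path)
    return report
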