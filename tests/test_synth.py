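import filecmp
import math

import numpy as np
import pytest

from paleopv.presence import CallerConfig, call_presence, filter_observations
from paleopv.synth import (
    SimulationConfig,
    simulate_catalog,
    simulate_cohorts,
    simulate_reads,
    simulate_run,
    simulate_species_table,
)

SMALL = SimulationConfig(seed=5, n_pvs=60, n_ancient=50, n_african=40, n_nonafrican=80)


def test_empty_catalog_config_yields_valid_empty_files(tmp_path):
    cfg = SimulationConfig(seed=1, n_pvs=0, n_ancient=5, n_african=5, n_nonafrican=5)
    paths = simulate_run(cfg, tmp_path / "run")
    from paleopv.catalog import read_carriers, read_catalog

    assert read_catalog(paths["catalog"]) == []
    for key in ("carriers_ancient", "carriers_african", "carriers_nonafrican"):
        inds = read_carriers(paths[key])
        assert all(not i.carried for i in inds)


def test_same_seed_twice_is_byte_identical(tmp_path):
    p1 = simulate_run(SMALL, tmp_path / "a")
    p2 = simulate_run(SMALL, tmp_path / "b")
    for key in p1:
        assert filecmp.cmp(p1[key], p2[key], shallow=False), key


def test_different_seed_changes_outputs(tmp_path):
    p1 = simulate_run(SMALL, tmp_path / "a")
    p2 = simulate_run(SimulationConfig(**{**SMALL.__dict__, "seed": 6}), tmp_path / "b")
    assert not filecmp.cmp(p1["carriers_ancient"], p2["carriers_ancient"], shallow=False)


def test_carriage_rate_within_three_standard_errors():
    cfg = SimulationConfig(seed=2, n_pvs=100, n_ancient=0, n_african=0,
                           n_nonafrican=10_000, mean_pvs_per_individual=0.8)
    catalog, truth = simulate_catalog(cfg)
    cohorts = simulate_cohorts(cfg, catalog, truth)
    naf = cohorts["modern_nonafrican"]
    # carried draws are Poisson(0.8) slots before dedup; compare slot mean via
    # counts of distinct PVs <= slots; use the planted mean with dedup slack
    mean_carried = np.mean([len(i.carried) for i in naf])
    lam = cfg.mean_pvs_per_individual
    se = math.sqrt(lam / len(naf))
    # dedup can only lower the count, and with 100 PVs the collision loss is small
    assert lam - 3 * se - 0.01 < mean_carried <= lam + 3 * se


def test_ancient_carriers_only_draw_from_ancient_present_truth():
    catalog, truth = simulate_catalog(SMALL)
    cohorts = simulate_cohorts(SMALL, catalog, truth)
    for ind in cohorts["ancient"]:
        assert set(ind.carried) <= truth.ancient_present


def test_heterozygous_dominates_zygosity():
    cfg = SimulationConfig(seed=3, n_pvs=100, n_ancient=0, n_african=0,
                           n_nonafrican=5000, mean_pvs_per_individual=1.0)
    catalog, truth = simulate_catalog(cfg)
    naf = simulate_cohorts(cfg, catalog, truth)["modern_nonafrican"]
    zygs = [z for i in naf for z in i.carried.values()]
    het_frac = sum(z == "het" for z in zygs) / len(zygs)
    assert abs(het_frac - 0.98) < 3 * math.sqrt(0.98 * 0.02 / len(zygs)) + 0.005


def test_propensity_recovery_within_three_standard_errors():
    cfg = SimulationConfig(seed=4, n_pvs=200, n_ancient=100, n_african=10_000,
                           n_nonafrican=10_000)
    catalog, truth = simulate_catalog(cfg)
    cohorts = simulate_cohorts(cfg, catalog, truth)
    for name, p in (("modern_african", 0.17), ("modern_nonafrican", 0.5)):
        flags = [
            pv in truth.ancient_present
            for i in cohorts[name]
            for pv in i.carried
        ]
        n = len(flags)
        observed = sum(flags) / n
        assert abs(observed - p) < 3 * math.sqrt(p * (1 - p) / n) + 0.01


def test_date_distribution_structure():
    cfg = SimulationConfig(seed=7, n_pvs=50, n_ancient=5000, n_african=0, n_nonafrican=0)
    catalog, truth = simulate_catalog(cfg)
    ancient = simulate_cohorts(cfg, catalog, truth)["ancient"]
    dates = [i.date_bp for i in ancient]
    undated = sum(d is None for d in dates) / len(dates)
    assert abs(undated - cfg.undated_frac) < 0.02
    dated = [d for d in dates if d is not None]
    in_bulk = sum(1000 <= d <= 5000 for d in dated) / len(dated)
    assert in_bulk > 0.85
    assert max(dated) > 5000  # the old tail exists
    assert max(dated) <= cfg.date_tail_max


class TestSimulateReads:
    def _pv(self, ref="C", alt="T"):
        from conftest import make_pv

        return make_pv("PVX", ref=ref, alt=alt, pos=5000)

    def test_no_damage_homref_yields_no_alt(self):
        cfg = SimulationConfig(seed=1, deamination_rate=0.0, seq_error_rate=0.0)
        rng = np.random.default_rng(0)
        for _ in range(20):
            site = simulate_reads(cfg, self._pv(), "ref/ref", rng=rng)
            assert all(o.base == "C" for o in site.observations)

    def test_heavy_damage_on_homref_ct_site_is_damage_consistent(self):
        from paleopv.presence import is_damage_consistent

        cfg = SimulationConfig(seed=1, deamination_rate=0.5,
                               deamination_decay=0.0, seq_error_rate=0.0)
        rng = np.random.default_rng(1)
        pv = self._pv()
        alt_obs = []
        for _ in range(30):
            site = simulate_reads(cfg, pv, "ref/ref", rng=rng)
            alt_obs += [o for o in site.observations if o.base == "T"]
        assert alt_obs  # damage does create alt-looking reads
        assert all(is_damage_consistent(pv, o) for o in alt_obs)
        assert all(o.strand == "+" for o in alt_obs)

    def test_het_alt_fraction_near_half(self):
        cfg = SimulationConfig(seed=1, deamination_rate=0.0, seq_error_rate=0.0,
                               duplicate_rate=0.0, depth_min=30, depth_mean_extra=0.0)
        rng = np.random.default_rng(2)
        pv = self._pv(ref="A", alt="G")
        fracs = []
        for _ in range(1000):
            site = simulate_reads(cfg, pv, "het", rng=rng)
            alt = sum(o.base == "G" for o in site.observations)
            fracs.append(alt / len(site.observations))
        se = math.sqrt(0.25 / (30 * 1000))
        assert abs(np.mean(fracs) - 0.5) < 3 * se

    def test_duplicates_share_fragment_and_collapse(self):
        cfg = SimulationConfig(seed=1, duplicate_rate=1.0)
        site = simulate_reads(cfg, self._pv(), "hom", rng=np.random.default_rng(3))
        keys = [o.frag_key for o in site.observations]
        assert len(keys) == 2 * len(set(keys))  # every read emitted twice
        filtered = filter_observations(site, CallerConfig(terminal_trim=0,
                                                          min_base_qual=0,
                                                          min_map_qual=0))
        assert len(filtered.observations) == len(set(keys))


def test_species_table_sharing_decays_toward_primate():
    cfg = SimulationConfig(seed=9, n_pvs=400)
    catalog, _ = simulate_catalog(cfg)
    table = simulate_species_table(cfg, catalog)
    hits_per_clade = {c: 0 for c in cfg.clade_order}
    for (pv_id, sp), allele in table.alleles.items():
        rec = next(r for r in catalog if r.pv_id == pv_id)
        if allele == rec.alt_allele:
            hits_per_clade[table.species_clade[sp]] += 1
    counts = [hits_per_clade[c] for c in cfg.clade_order]
    assert counts[0] == max(counts)
    assert counts[0] > 10 * max(1, counts[-1])  # strong distal concentration
    # monotone decay in expectation: distal half clearly above proximal half
    assert sum(counts[:4]) > 5 * max(1, sum(counts[4:]))


def test_planted_genotypes_recoverable_by_caller():
    cfg = SimulationConfig(seed=11)
    catalog, truth = simulate_catalog(cfg)
    rng = np.random.default_rng(12)
    snvs = [r for r in catalog if r.is_snv][:60]
    correct = 0
    total = 0
    expected = {"ref/ref": ("absent", "na"), "het": ("present", "het"),
                "hom": ("present", "hom")}
    for i, pv in enumerate(snvs):
        genotype = ("ref/ref", "het", "hom")[i % 3]
        site = simulate_reads(cfg, pv, genotype, rng=rng)
        call = call_presence(pv, site)
        total += 1
        if (call.call, call.zygosity) == expected[genotype]:
            correct += 1
    assert correct / total >= 0.9
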