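import pytest

from paleopv.catalog import CountTable, Individual
from paleopv.sharing import (
    load_comparison,
    sharing_percentage,
    temporal_profile,
    venn_partition,
)


class TestSharingPercentage:
    def test_published_ancient_sharing_ratio(self):
        # 1266 of 1781 catalogued PVs found in the ancient cohort
        assert sharing_percentage(1266, 1781, 0) == 71

    def test_extremes(self):
        assert sharing_percentage(0, 7, 2) == 0
        assert sharing_percentage(9, 9, 3) == 100

    def test_half_up_rounding(self):
        assert sharing_percentage(1, 8, 0) == 13  # 12.5 rounds up
        assert sharing_percentage(5, 1000, 1) == 0.5

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            sharing_percentage(0, 0, 1)


class TestVennPartition:
    def test_small_enumerable_case(self):
        part = venn_partition({"a", "b", "c"}, {"a"}, {"a", "b"})
        assert part.both == {"a"}
        assert part.only_nonafrican == {"b"}
        assert part.only_african == set()
        assert part.neither == {"c"}
        assert part.fractions == (0.5, 0.5, 0.0)

    def test_disjoint_sets_flagged(self):
        part = venn_partition({"x", "y"}, {"p"}, {"q"})
        assert part.neither == {"x", "y"}
        assert part.fractions is None

    def test_fractions_sum_to_one(self):
        part = venn_partition(set("abcdefgh"), set("abc"), set("bcdef"))
        assert abs(sum(part.fractions) - 1.0) < 1e-9
        assert sum(part.fractions_over_all) == pytest.approx(part.n_shared / 8)

    def test_matches_per_element_membership_oracle(self, rng):
        ids = [f"id{i}" for i in range(100)]
        anc = {i for i in ids if rng.random() < 0.5}
        afr = {i for i in ids if rng.random() < 0.3}
        naf = {i for i in ids if rng.random() < 0.6}
        part = venn_partition(anc, afr, naf)
        for pv in anc:
            expected = (
                "both" if pv in afr and pv in naf
                else "only_african" if pv in afr
                else "only_nonafrican" if pv in naf
                else "neither"
            )
            assert pv in getattr(part, expected)
        assert part.n_shared + len(part.neither) == len(anc)

    def test_idempotent_under_relabeling(self, rng):
        ids = [f"id{i}" for i in range(60)]
        anc = set(ids[:40]); afr = set(ids[10:30]); naf = set(ids[20:50])
        relabel = {i: f"R{i}" for i in ids}
        p1 = venn_partition(anc, afr, naf)
        p2 = venn_partition({relabel[i] for i in anc}, {relabel[i] for i in afr},
                            {relabel[i] for i in naf})
        assert {relabel[i] for i in p1.both} == p2.both
        assert p1.fractions == p2.fractions


class TestLoadComparison:
    def _table(self, per_gene):
        return CountTable(per_gene=per_gene, per_pathway={},
                          total_nonredundant=sum(per_gene.values()))

    def test_identical_tables_have_zero_discordance(self):
        t = self._table({"g1": 3, "g2": 5})
        assert all(r.discordance == 0 for r in load_comparison(t, t))

    def test_simple_arithmetic(self):
        anc = self._table({"g1": 2, "g2": 0})
        mod = self._table({"g1": 1, "g2": 1})
        rows = {r.gene: r for r in load_comparison(anc, mod)}
        assert rows["g1"].discordance == pytest.approx(0.5)
        assert rows["g2"].discordance == pytest.approx(-0.5)

    def test_missing_gene_gets_zero_share(self):
        anc = self._table({"g1": 4})
        mod = self._table({"g2": 4})
        rows = {r.gene: r for r in load_comparison(anc, mod)}
        assert rows["g2"].ancient_share == 0 and rows["g1"].modern_share == 0

    def test_matches_independent_recomputation(self, rng):
        genes = [f"g{i}" for i in range(12)]
        anc = self._table({g: int(rng.integers(0, 9)) + 1 for g in genes[:8]})
        mod = self._table({g: int(rng.integers(0, 9)) + 1 for g in genes[4:]})
        rows = load_comparison(anc, mod)
        for r in rows:
            assert r.ancient_share == pytest.approx(
                anc.per_gene.get(r.gene, 0) / anc.total_nonredundant
            )
            assert r.modern_share == pytest.approx(
                mod.per_gene.get(r.gene, 0) / mod.total_nonredundant
            )
        discs = [abs(r.discordance) for r in rows]
        assert discs == sorted(discs, reverse=True)


def _carrier(ind_id, date, carried, cohort="ancient"):
    return Individual(ind_id, cohort, date, "region",
                      {pv: "het" for pv in carried})


class TestTemporalProfile:
    def test_oldest_and_youngest_published_dates(self):
        inds = [
            _carrier("russia", 37470, ["BRCA1_c181"]),
            _carrier("vanuatu", 190, ["MSH2_c1204"]),
            _carrier("mid", 3000, ["TP53_x"]),
        ]
        prof = temporal_profile(inds)
        assert prof.oldest == ("BRCA1_c181", 37470)
        assert prof.youngest == ("MSH2_c1204", 190)

    def test_no_dated_carriers(self):
        prof = temporal_profile([_carrier("u1", None, ["a"]), _carrier("u2", None, ["b", "c"])])
        assert prof.bins == [] and prof.oldest is None
        assert prof.n_undated == 3  # carrier-occurrence units

    def test_binning_matches_manual_histogram(self, rng):
        inds = [
            _carrier(f"i{k}", float(rng.integers(0, 12000)),
                     [f"pv{j}" for j in range(rng.integers(1, 4))])
            for k in range(50)
        ]
        prof = temporal_profile(inds, bin_width=1000)
        # oracle: manual half-open binning, descending BP
        manual = {}
        for ind in inds:
            b = int(ind.date_bp // 1000)
            manual[b] = manual.get(b, 0) + len(ind.carried)
        for start, end, count in prof.bins:
            assert count == manual.get(int(end // 1000), 0)
        assert sum(c for _, _, c in prof.bins) + prof.n_undated == sum(
            len(i.carried) for i in inds
        )
        starts = [b[0] for b in prof.bins]
        assert starts == sorted(starts, reverse=True)

    def test_first_occurrence_is_oldest_carrier_per_gene(self):
        gene_of = {"pv1": "BRCA1", "pv2": "BRCA1", "pv3": "MLH1"}
        inds = [
            _carrier("a", 5000, ["pv1"]),
            _carrier("b", 8000, ["pv2"]),
            _carrier("c", 300, ["pv3"]),
        ]
        prof = temporal_profile(inds, gene_of=gene_of)
        assert prof.first_occurrence == {"BRCA1": 8000, "MLH1": 300}

    def test_individual_counting_mode(self):
        inds = [_carrier("a", 1500, ["x", "y", "z"])]
        prof = temporal_profile(inds, counting_mode="individual")
        assert sum(c for _, _, c in prof.bins) == 1
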