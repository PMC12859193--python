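import numpy as np
import pytest

from paleopv.presence import (
    CallerConfig,
    call_presence,
    filter_observations,
    is_damage_consistent,
    pileup_from_alignments,
    read_pileup,
    write_pileup,
)

from conftest import make_obs, make_pv, make_site

CFG = CallerConfig()


class TestFilter:
    def test_duplicates_collapse_to_best_quality(self):
        site = make_site([
            make_obs(bq=30, read_id="r1", frag=(10, 70, "+")),
            make_obs(bq=38, read_id="r2", frag=(10, 70, "+")),
            make_obs(bq=25, read_id="r3", frag=(10, 70, "+")),
        ])
        out = filter_observations(site, CFG)
        assert len(out.observations) == 1
        assert out.observations[0].base_qual == 38

    def test_terminal_bases_trimmed(self):
        site = make_site([make_obs(d5=1, d3=40)])
        assert filter_observations(site, CFG).observations == []
        site = make_site([make_obs(d5=40, d3=1)])
        assert filter_observations(site, CFG).observations == []
        site = make_site([make_obs(d5=2, d3=2)])
        assert len(filter_observations(site, CFG).observations) == 1

    def test_quality_thresholds(self):
        assert filter_observations(make_site([make_obs(bq=19)]), CFG).observations == []
        assert filter_observations(make_site([make_obs(mq=29)]), CFG).observations == []

    def test_matches_brute_force_reimplementation(self, rng):
        obs = [
            make_obs(
                base="ACGT"[rng.integers(4)],
                bq=int(rng.integers(0, 42)),
                mq=int(rng.integers(0, 61)),
                d5=int(rng.integers(0, 30)),
                d3=int(rng.integers(0, 30)),
                strand="+-"[rng.integers(2)],
                frag=(int(rng.integers(0, 20)), int(rng.integers(50, 60)), None),
                read_id=f"r{i}",
            )
            for i in range(200)
        ]
        got = filter_observations(make_site(obs), CFG).observations

        # oracle: survivors by explicit predicate, then per-key argmax scan
        surv = [
            o for o in obs
            if o.dist_from_5p >= 2 and o.dist_from_3p >= 2
            and o.base_qual >= 20 and o.map_qual >= 30
        ]
        expected = {}
        for o in surv:
            cur = expected.get(o.frag_key)
            if cur is None or o.base_qual > cur.base_qual:
                expected[o.frag_key] = cur if cur and o.base_qual <= cur.base_qual else o
        assert sorted(o.read_id for o in got) == sorted(
            o.read_id for o in expected.values()
        )


class TestDamageConsistency:
    @pytest.mark.parametrize(
        "ref,alt,strand,expected",
        [
            ("C", "T", "+", True),
            ("C", "T", "-", False),
            ("G", "A", "-", True),
            ("G", "A", "+", False),
            ("A", "G", "+", False),
            ("A", "G", "-", False),
            ("T", "C", "+", False),
        ],
    )
    def test_deamination_classes(self, ref, alt, strand, expected):
        pv = make_pv(ref=ref, alt=alt)
        obs = make_obs(base=alt, strand=strand)
        assert is_damage_consistent(pv, obs) is expected

    def test_indel_never_damage_consistent(self):
        pv = make_pv(ref="CT", alt="C")
        assert not is_damage_consistent(pv, make_obs(base="C", strand="+"))


class TestCallPresence:
    def test_no_observations_uncallable(self):
        call = call_presence(make_pv(), make_site([]))
        assert call.call == "uncallable" and call.zygosity == "na"

    def test_het_call_from_balanced_support(self):
        pv = make_pv(ref="A", alt="G")
        obs = [make_obs(base="G", strand=s, frag=(i, i + 60, None), read_id=f"a{i}")
               for i, s in enumerate("++-")]
        obs += [make_obs(base="A", frag=(100 + i, 160 + i, "+"), read_id=f"r{i}")
                for i in range(2)]
        call = call_presence(pv, make_site(obs))
        assert (call.call, call.zygosity) == ("present", "het")
        assert (call.n_alt_support, call.n_ref_support) == (3, 2)
        assert not call.damage_flagged

    def test_hom_call(self):
        pv = make_pv(ref="A", alt="G")
        obs = [make_obs(base="G", strand="+-"[i % 2], frag=(i, i + 60, None))
               for i in range(4)]
        call = call_presence(pv, make_site(obs))
        assert (call.call, call.zygosity) == ("present", "hom")

    def test_single_damage_consistent_alt_is_not_present(self):
        # C>T with one forward-strand alt read: could be pure deamination
        pv = make_pv(ref="C", alt="T")
        obs = [make_obs(base="T", strand="+", frag=(0, 60, None))]
        obs += [make_obs(base="C", strand="+", frag=(i + 1, i + 61, None)) for i in range(3)]
        call = call_presence(pv, make_site(obs))
        assert call.call == "uncallable"
        assert call.damage_flagged

    def test_double_strand_alt_overrides_damage_penalty(self):
        pv = make_pv(ref="C", alt="T")
        obs = [
            make_obs(base="T", strand="+", frag=(0, 60, None)),
            make_obs(base="T", strand="-", frag=(5, 65, None)),
        ]
        call = call_presence(pv, make_site(obs))
        assert call.call == "present"
        assert not call.damage_flagged

    def test_absent_requires_depth(self):
        pv = make_pv(ref="A", alt="G")
        call = call_presence(pv, make_site([make_obs(base="A", frag=(0, 60, "+"))]))
        assert call.call == "absent"
        cfg = CallerConfig(min_depth=3)
        call = call_presence(pv, make_site([make_obs(base="A", frag=(0, 60, "+"))]), cfg)
        assert call.call == "uncallable"

    def test_other_bases_excluded_from_supports(self):
        pv = make_pv(ref="A", alt="G")
        obs = [make_obs(base="T", frag=(i, i + 60, "+"), read_id=f"t{i}") for i in range(3)]
        obs.append(make_obs(base="A", frag=(90, 150, "+")))
        call = call_presence(pv, make_site(obs))
        assert (call.n_alt_support, call.n_ref_support, call.n_other) == (0, 1, 3)
        assert call.call == "absent"

    def test_call_invariant_to_observation_order_and_read_ids(self, rng):
        pv = make_pv(ref="C", alt="T")
        obs = [
            make_obs(
                base="CT"[rng.integers(2)],
                bq=int(rng.integers(15, 42)),
                strand="+-"[rng.integers(2)],
                frag=(int(rng.integers(0, 10)), int(rng.integers(55, 65)), None),
                read_id=f"r{i}",
            )
            for i in range(20)
        ]
        ref_call = call_presence(pv, make_site(obs))
        perm = [obs[i] for i in rng.permutation(len(obs))]
        relabeled = [
            make_obs(o.base, o.base_qual, o.map_qual, o.dist_from_5p,
                     o.dist_from_3p, o.strand,
                     (o.frag_key[0], o.frag_key[1], o.frag_key[2]), f"x{i}")
            for i, o in enumerate(perm)
        ]
        other = call_presence(pv, make_site(relabeled))
        assert (ref_call.call, ref_call.zygosity, ref_call.n_alt_support,
                ref_call.n_ref_support) == (
            other.call, other.zygosity, other.n_alt_support, other.n_ref_support)

    def test_raising_thresholds_never_turns_absent_into_present(self, rng):
        # monotonicity: stricter QC can only remove support
        pv = make_pv(ref="G", alt="A")
        for _ in range(30):
            obs = [
                make_obs(
                    base="GAC"[rng.integers(3)],
                    bq=int(rng.integers(0, 42)),
                    mq=int(rng.integers(0, 61)),
                    d5=int(rng.integers(0, 10)),
                    d3=int(rng.integers(0, 10)),
                    strand="+-"[rng.integers(2)],
                    frag=(int(rng.integers(0, 5)), 60, None),
                    read_id=f"r{rng.integers(1e6)}",
                )
                for _ in range(int(rng.integers(1, 15)))
            ]
            base_call = call_presence(pv, make_site(obs), CallerConfig())
            strict = CallerConfig(min_base_qual=30, min_map_qual=50, terminal_trim=4)
            strict_call = call_presence(pv, make_site(obs), strict)
            if base_call.call == "absent":
                assert strict_call.call != "present"


def test_pileup_tsv_round_trip(tmp_path, rng):
    sites = [
        make_site(
            [make_obs(read_id=f"r{i}", frag=(i, i + 60, "+")) for i in range(3)],
            ind_id="A", pv_id="PV1",
        ),
        make_site([make_obs(base="G", strand="-", frag=(7, 67, "-"))],
                  ind_id="B", pv_id="PV2"),
    ]
    path = tmp_path / "pileup.tsv"
    write_pileup(sites, path)
    back = read_pileup(path)
    assert {(s.ind_id, s.pv_id) for s in back} == {("A", "PV1"), ("B", "PV2")}
    assert back[0].observations == sites[0].observations


def test_sam_extraction_matches_planted_bases(tmp_path):
    """Reads written as SAM text yield the planted base, strand and distances."""
    pv = make_pv(pv_id="PVS", ref="C", alt="T", pos=1005)
    sam = tmp_path / "t.sam"
    # two forward reads (one alt), one reverse ref read spanning pos 1005
    sam.write_text(
        "@HD\tVN:1.6\tSO:coordinate\n"
        "@SQ\tSN:17\tLN:2000\n"
        "r1\t0\t17\t1001\t60\t10M\t*\t0\t0\tAAAATAAAAA\t" + "I" * 10 + "\n"
        "r2\t0\t17\t1003\t60\t10M\t*\t0\t0\tAACAAAAAAA\t" + "I" * 10 + "\n"
        "r3\t16\t17\t998\t60\t10M\t*\t0\t0\tAAAAAAACAA\t" + "I" * 10 + "\n"
    )
    sites = pileup_from_alignments(sam, "IND", [pv])
    assert len(sites) == 1
    by_read = {o.read_id: o for o in sites[0].observations}
    assert by_read["r1"].base == "T" and by_read["r1"].strand == "+"
    assert by_read["r1"].dist_from_5p == 4
    assert by_read["r2"].base == "C" and by_read["r2"].dist_from_5p == 2
    assert by_read["r3"].strand == "-"
    # reverse read: sequenced 5' end is the right-hand edge
    assert by_read["r3"].dist_from_5p == 2 and by_read["r3"].dist_from_3p == 7
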