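import numpy as np
import pytest

from paleopv.catalog import PVRecord
from paleopv.presence import PileupSite, ReadObservation


def make_pv(pv_id="PV1", gene="BRCA1", ref="C", alt="T", pos=100,
            pathways=("HR",), classification="Pathogenic", protein=""):
    return PVRecord(
        pv_id=pv_id, gene=gene, cdna=f"c.1{ref}>{alt}", protein=protein,
        chrom="17", pos=pos, ref_allele=ref, alt_allele=alt,
        pathways=frozenset(pathways), classification=classification,
    )


def make_obs(base="T", bq=35, mq=60, d5=10, d3=10, strand="+",
             frag=(50, 150, None), read_id="r1"):
    key = (frag[0], frag[1], strand if frag[2] is None else frag[2])
    return ReadObservation(
        read_id=read_id, base=base, base_qual=bq, map_qual=mq,
        dist_from_5p=d5, dist_from_3p=d3, strand=strand, frag_key=key,
    )


def make_site(observations, ind_id="IND1", pv_id="PV1"):
    return PileupSite(ind_id=ind_id, pv_id=pv_id, observations=list(observations))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_catalog(rng):
    """50 random SNV records across 8 genes, genes in 1-2 pathways."""
    from paleopv.synth import DEFAULT_PATHWAYS

    genes = [f"G{i}" for i in range(8)]
    gene_pw = {
        g: frozenset(
            rng.choice(DEFAULT_PATHWAYS, size=rng.integers(1, 3), replace=False)
        )
        for g in genes
    }
    records = []
    bases = "ACGT"
    for i in range(50):
        ref = bases[rng.integers(4)]
        alt = [b for b in bases if b != ref][rng.integers(3)]
        g = genes[rng.integers(8)]
        records.append(
            PVRecord(
                pv_id=f"PV{i:03d}", gene=g, cdna=f"c.{i}{ref}>{alt}", protein="",
                chrom="1", pos=i + 1, ref_allele=ref, alt_allele=alt,
                pathways=gene_pw[g], classification="Pathogenic",
            )
        )
    return records
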