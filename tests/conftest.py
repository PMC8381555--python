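import numpy as np
import pytest

from dofinemap.datamodel import CandidateSnp, EqtlInstance, FounderExpression, StrainPanel


@pytest.fixture(scope="session")
def panel() -> StrainPanel:
    return StrainPanel()


def make_snp(snp_id="snp1", pos=100_000, genotypes=(0, 0, 0, 1, 0, 0, 1, 1),
             effect=1.5, pvalue=0.01, atac=None, footprint=0.0,
             dist_promoter=50_000.0, dist_marker=20_000.0, chrom="1"):
    rngv = np.arange(8, dtype=float) if atac is None else np.asarray(atac, float)
    return CandidateSnp(
        snp_id=snp_id, chrom=chrom, pos=pos, peak_id=f"peak_{snp_id}",
        atac_signal=rngv, effect=effect, effect_pvalue=pvalue,
        genotypes=np.array(genotypes), footprint_flag=footprint,
        dist_to_promoter=dist_promoter, dist_to_marker=dist_marker,
    )


def make_instance(gene_id="g1", effects=None, candidates=None, marker_pos=10_000_000,
                  promoter_pos=10_050_000):
    if effects is None:
        effects = np.array([0.1, 0.9, 0.5, 0.2, 0.8, 0.3, 0.6, 0.4])
    if candidates is None:
        candidates = [make_snp()]
    return EqtlInstance(
        gene_id=gene_id, gene_chrom="1", gene_promoter_pos=promoter_pos,
        marker_chrom="1", marker_pos=marker_pos,
        allelic_effects=np.asarray(effects, float), candidates=candidates,
    )


def make_expression(gene_id="g1", values=None):
    if values is None:
        values = np.array([1.0, 3.0, 2.0, 4.0, 1.5, 2.5, 3.5, 0.5])
    return FounderExpression(gene_id=gene_id, expression=np.asarray(values, float))


@pytest.fixture
def snp_factory():
    return make_snp


@pytest.fixture
def instance_factory():
    return make_instance


@pytest.fixture
def expression_factory():
    return make_expression
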