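import pytest

from multihit import ModelParams, SimulationSpec, default_genome_target_count, sample_cohort

MAF_TEXT = """\
#version gdc-1.0.0
Tumor_Sample_Barcode\tChromosome\tStart_Position\tReference_Allele\tTumor_Seq_Allele2\tVariant_Classification\tVariant_Type
TCGA-AA-0001-01A\t1\t100\tA\tT\tMissense_Mutation\tSNP
TCGA-AA-0001-01A\t1\t250\tC\tG\tSilent\tSNP
TCGA-AA-0001-01A\t2\t300\tG\tA\tNonsense_Mutation\tSNP
TCGA-AA-0001-01A\t3\t400\tT\tC\tMissense_Mutation\tSNP
TCGA-AA-0001-01A\tX\t500\tA\tG\tMissense_Mutation\tSNP
TCGA-BB-0002-01A\t1\t100\tA\tT\tMissense_Mutation\tSNP
TCGA-BB-0002-01A\t5\t900\tC\tA\tFrame_Shift_Del\tDEL
"""


@pytest.fixture(scope="session")
def default_G():
    return default_genome_target_count()


@pytest.fixture
def maf_path(tmp_path):
    path = tmp_path / "fixture.maf"
    path.write_text(MAF_TEXT)
    return path


@pytest.fixture(scope="session")
def brca_like_cohort(default_G):
    """Seeded synthetic cohort from a 3-hit model at breast-carcinoma scale."""
    spec = SimulationSpec(
        components=(ModelParams(G=default_G, h=3, k=9e14),),
        n_samples=500,
        seed=11,
    )
    return sample_cohort(spec)
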