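import pytest

from oncocohort.formats_io import ChromTable
from oncocohort.simulate import CohortDesign, generate_cohort


@pytest.fixture(scope="session")
def small_chroms() -> ChromTable:
    return ChromTable((("chr1", 100), ("chr2", 60), ("chr3", 40), ("chr4", 30)))


@pytest.fixture(scope="session")
def default_truth():
    """One 50-patient synthetic cohort shared by read-only tests."""
    return generate_cohort(CohortDesign(seed=7))


MAF_HEADER = (
    "Hugo_Symbol\tChromosome\tStart_Position\tEnd_Position\tReference_Allele"
    "\tTumor_Seq_Allele2\tVariant_Classification\tVariant_Type"
    "\tTumor_Sample_Barcode"
)


def maf_text(rows: list[tuple]) -> str:
    lines = [MAF_HEADER]
    for r in rows:
        lines.append("\t".join(str(x) for x in r))
    return "\n".join(lines) + "\n"


@pytest.fixture(scope="session")
def tiny_maf_text() -> str:
    return maf_text(
        [
            ("TP53", "chr1", 100, 100, "A", "T", "Missense_Mutation", "SNP", "S1"),
            ("KMT2D", "chr1", 200, 200, "C", "G", "Silent", "SNP", "S1"),
            ("KMT2D", "chr1", 220, 220, "G", "A", "Nonsense_Mutation", "SNP", "S1"),
            ("B2M", "chr2", 50, 50, "T", "C", "Missense_Mutation", "SNP", "S2"),
        ]
    )
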