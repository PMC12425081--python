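import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from sigspect import gen_catalog, gen_cohort, gen_genome  # noqa: E402

MAF_HEADER = (
    "Chromosome\tStart_Position\tReference_Allele\tTumor_Seq_Allele2\t"
    "Variant_Type\tTumor_Sample_Barcode"
)


def maf_text(rows: list[str], comments: list[str] | None = None) -> str:
    lines = list(comments or [])
    lines.append(MAF_HEADER)
    lines.extend(rows)
    return "\n".join(lines) + "\n"


@pytest.fixture(scope="session")
def toy_genome():
    return gen_genome(20_000, seed=11)


@pytest.fixture(scope="session")
def toy_catalog():
    return gen_catalog(4, concentration=0.3, seed=7)


@pytest.fixture(scope="session")
def toy_cohort(toy_genome, toy_catalog):
    return gen_cohort(
        toy_genome, toy_catalog, n_samples=5, mutations_per_sample=300, seed=3
    )
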