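import pytest

from twohit.model import AnnotatedVariant, Individual, Pedigree, VariantTable
from twohit.pipeline import analyze_cohort
from twohit.simulate import CohortConfig, simulate_cohort, simulate_phase_blocks


@pytest.fixture(scope="session")
def default_cohort():
    return simulate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def default_blocks(default_cohort):
    return simulate_phase_blocks(default_cohort)


@pytest.fixture(scope="session")
def default_report(default_cohort, default_blocks):
    _, tumor_blocks = default_blocks
    c = default_cohort
    return analyze_cohort(
        c.germline, c.pedigree, c.somatic, c.segments, c.gene_models,
        tumor_blocks,
    )


@pytest.fixture
def sibship_pedigree():
    """Four affected and four unaffected siblings plus founders."""
    inds = [
        Individual("II_1", "0", "0", 1, "unknown"),
        Individual("II_2", "0", "0", 2, "unknown"),
    ]
    for i in range(1, 9):
        inds.append(
            Individual(
                f"III_{i}", "II_1", "II_2", 1 + i % 2,
                "affected" if i <= 4 else "unaffected",
            )
        )
    return Pedigree(inds)


def make_table(rows, sample_ids):
    """Build a VariantTable from (pos, kwargs) pairs on chr1."""
    records = []
    for i, (pos, kw) in enumerate(rows):
        kw = dict(kw)
        kw.setdefault("ref", "A")
        kw.setdefault("alt", "TG" if kw.pop("indel", False) else "T")
        records.append(AnnotatedVariant(chrom="chr1", pos=pos, **kw))
    return VariantTable(records=records, sample_ids=list(sample_ids))
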