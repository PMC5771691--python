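import pytest

from braintraj.records import SummaryCell


@pytest.fixture
def make_cell():
    """Factory for summary cells with sensible defaults."""

    def _make(
        mean,
        sem,
        n,
        genotype="WT",
        age=22.0,
        region="cortex",
        kind="thickness",
    ):
        return SummaryCell(
            genotype=genotype,
            age_months=age,
            region=region,
            measure_kind=kind,
            mean=mean,
            sem=sem,
            n=n,
        )

    return _make
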