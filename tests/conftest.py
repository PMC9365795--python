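import pytest

from th1select.elispot import Cytokine, EpitopeAssay
from th1select.funnel import FunnelConfig, GeneRecord


@pytest.fixture
def five_gene_table():
    """Five genes of which exactly two survive every funnel stage.

    PASS1/PASS2 satisfy all filters; HIGHMISS fails the high-stratum DE rule,
    NOPIN lacks PIN evidence, NOTUMOR is absent from the tumor line.
    """
    return [
        GeneRecord("PASS1", 2.0, 0.01, 2.2, 0.01, True, True),
        GeneRecord("PASS2", 1.8, 0.001, 1.6, 0.02, True, True),
        GeneRecord("HIGHMISS", 1.5, 0.01, 0.2, 0.01, True, True),
        GeneRecord("NOPIN", 2.5, 0.01, 2.5, 0.01, False, True),
        GeneRecord("NOTUMOR", 2.5, 0.01, 2.5, 0.01, True, False),
    ]


@pytest.fixture
def strict_config():
    return FunnelConfig(require_pin=True, require_tumor_expression=True)


@pytest.fixture
def strong_assay():
    """Clearly positive IFN-γ assay: ~30 spots over a ~10-spot background."""
    return EpitopeAssay(
        donor_id="D01",
        epitope_id="PSMA-p466",
        cytokine=Cytokine.IFNG,
        experimental_wells=(30, 32, 28, 30),
        control_wells=(10, 12, 8, 10),
    )


def make_assay(exp, ctl, donor="D01", epitope="E1", cytokine=Cytokine.IFNG):
    return EpitopeAssay(
        donor_id=donor, epitope_id=epitope, cytokine=cytokine,
        experimental_wells=tuple(exp), control_wells=tuple(ctl),
    )
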