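import pytest

from barcodiag.records import Alignment, SeqRecord
from barcodiag.simulate import krai_krue_demo


@pytest.fixture(scope="session")
def demo():
    """The packaged synthetic three-species assay demo.

    Returns (panel, alignment, truth, primer_panel).
    """
    return krai_krue_demo()


def make_alignment(rows: dict[str, str], species: dict[str, str] | None = None) -> Alignment:
    """Build an alignment from {id: residues}; species defaults to the id."""
    species = species or {}
    return Alignment(
        SeqRecord(rid, seq, species=species.get(rid, rid)) for rid, seq in rows.items()
    )
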