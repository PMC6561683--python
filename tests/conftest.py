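import numpy as np
import pytest

from kferqscan.io import ProteinRecord


@pytest.fixture
def record_factory():
    def make(accession, sequence, status="Swiss-Prot", **kw):
        defaults = dict(
            entry_name=f"{accession}_TEST",
            status=status,
            protein_names="test protein",
            gene_name=accession,
            organism="Test organism",
        )
        defaults.update(kw)
        return ProteinRecord(accession=accession, sequence=sequence, **defaults)

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def four_motif_seq():
    """A sequence with a known motif inventory and inert (G) spacers: windows
    crossing a spacer always contain G, which belongs to no residue category,
    so exactly the four planted pentapeptides match.

      KFERQ  canonical (Q right)
      QDIVR  canonical (Q left)
      KSLVQ  phospho-generated (Q right)
      RFEIK  acetyl-generated (K right; R first, so no second orientation)
    """
    return "GGGGG" + "KFERQ" + "GGGGG" + "QDIVR" + "GGGGG" + "KSLVQ" + "GGGGG" + "RFEIK" + "GGGGG"
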