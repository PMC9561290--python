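import numpy as np
import pytest

from mpratile.design import DesignParams, MetaUTR, tile_oligos
from mpratile.enrich import EnrichmentRecord


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def toy_genome():
    """Deterministic 3-kb chromosome as a plain mapping."""
    r = np.random.default_rng(7)
    seq = "".join(r.choice(list("ACGT"), size=3000))
    return {"chr1": seq}


@pytest.fixture
def default_params():
    return DesignParams()


@pytest.fixture
def small_pool(rng):
    """A tiled pool over one 600-nt synthetic UTR (no flanks, step 4)."""
    seq = "".join(rng.choice(list("ACGT"), size=600))
    meta = MetaUTR(gene_id="toy", sequence=seq, upstream_flank="", downstream_flank="")
    return tile_oligos(meta, DesignParams(flank_extension=0))


def make_records(log2fcs, fdrs, step=4, start_offset=0):
    """EnrichmentRecords with offsets attached, for window tests."""
    out = []
    for i, (lfc, fdr) in enumerate(zip(log2fcs, fdrs)):
        out.append(
            EnrichmentRecord(
                oligo_id=f"g|{i:04d}",
                log2fc=float(lfc),
                se=0.1,
                pvalue=float(fdr),
                fdr=float(fdr),
                mean_count=100.0,
                offset=start_offset + i * step,
            )
        )
    return out
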