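import numpy as np
import pytest

from ciascore.copy_number import CopyNumberProfile
from ciascore.genome_bins import build_bin_map, hg19_chrom_sizes
from ciascore.synthetic_data import toy_bin_map, with_synthetic_gc


@pytest.fixture(scope="session")
def toy_map():
    """10 chromosomes x 30 Mb = 300 bins with synthetic GC."""
    return toy_bin_map(seed=0)


@pytest.fixture(scope="session")
def hg19_map():
    """hg19 autosomes tiled at 1 Mb, synthetic GC attached."""
    bm = build_bin_map(chrom_sizes=hg19_chrom_sizes(autosomes_only=True),
                       genome_build="hg19")
    return with_synthetic_gc(bm, seed=0)


def make_cn(xi, sample_id="s", usable=None):
    xi = np.asarray(xi, dtype=float)
    if usable is None:
        usable = np.isfinite(xi) & (xi > 0)
    return CopyNumberProfile(sample_id, xi, usable)
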