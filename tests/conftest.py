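import numpy as np
import pytest

from mipfit import simulate as sim
from mipfit.probe_design import StrainVariant


@pytest.fixture(scope="session")
def toy_reference():
    """Two 6 kb contigs of random sequence (seeded; ~50% GC)."""
    rng = np.random.default_rng(1234)
    return {c: "".join(rng.choice(list("ACGT"), size=6000)) for c in ("I", "II")}


@pytest.fixture(scope="session")
def toy_panels():
    """Three 4-probe strain panels with synthetic arm/gap-fill sequences."""
    return sim.toy_panels(n_strains=3)


def make_variant(strain="s1", chrom="I", pos=100, ref="A", alt="T"):
    return StrainVariant(strain, chrom, pos, ref, alt)
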