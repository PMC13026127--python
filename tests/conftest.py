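import numpy as np
import pytest

from rotalib.clustering import RotamerCluster, RotamerSet
from rotalib.geometry import ChiSet, reconstruct_sidechain


def make_rotamer_set(aa: str, chis, threshold: float = 0.4,
                     counts=None) -> RotamerSet:
    """RotamerSet from explicit canonical chi vectors (ids in given order)."""
    clusters = []
    for i, chi in enumerate(chis):
        chi = tuple(float(c) for c in np.atleast_1d(chi))
        clusters.append(RotamerCluster(
            rotamer_id=i, canonical_chi=ChiSet(aa, chi),
            centroid_conformation=reconstruct_sidechain(aa, chi),
            member_count=0 if counts is None else int(counts[i]),
            mean_internal_rmsd=0.0))
    return RotamerSet(aa, clusters, threshold)


@pytest.fixture
def leu_field():
    from rotalib.synthetic import make_field
    return make_field("LEU", 3, seed=11)


@pytest.fixture
def leu_rotamer_set(leu_field):
    return make_rotamer_set("LEU", leu_field.rotamer_chis, threshold=0.40)
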