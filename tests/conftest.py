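import numpy as np
import pytest

from canopycarbon import synthetic as syn
from canopycarbon.matching_eval import FieldTree


@pytest.fixture(scope="session")
def separable_scene():
    """Non-overlapping stand with its point cloud (shared, read-only)."""
    sc = syn.separable_stand(seed=1)
    forest = syn.simulate_forest(sc)
    cloud = syn.simulate_point_cloud(forest, sc)
    return sc, forest, cloud


@pytest.fixture(scope="session")
def alpine_forest():
    sc = syn.alpine_default(seed=0)
    return sc, syn.simulate_forest(sc)


def as_field_trees(forest):
    return [FieldTree(id=int(r.id), x=float(r.x), y=float(r.y), species=r.species,
                      dbh_cm=float(r.dbh_cm), height_m=float(r.height_m),
                      agb_kg=float(r.agb_kg), carbon_kg=float(r.carbon_kg))
            for r in forest.itertuples()]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
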