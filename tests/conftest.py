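import pytest

from granule_sizer import AcquisitionModel, LengthLaw, PlateDesign
from granule_sizer.synthgen import FieldTruth, GranuleTruth


@pytest.fixture(scope="session")
def acq_small() -> AcquisitionModel:
    """Compact field for fast rendering tests."""
    return AcquisitionModel(field_shape=(128, 128))


@pytest.fixture(scope="session")
def default_law() -> LengthLaw:
    return LengthLaw.truncated_geometric()


@pytest.fixture(scope="session")
def tiny_design() -> PlateDesign:
    return PlateDesign(conditions=("Unstimulated",), wells_per_condition=2,
                       fields_per_well=2, cells_per_field=(4, 6),
                       granules_per_cell=(10, 20))


def make_field(granules, nuclei=(), sites=(), condition="c", well="w",
               field_id="f") -> FieldTruth:
    return FieldTruth(condition=condition, well=well, field_id=field_id,
                      granules=list(granules), nuclei=list(nuclei),
                      sites=list(sites))


def rod(x, y, n_quanta, orientation=0.0, **kw) -> GranuleTruth:
    return GranuleTruth(id=0, centroid=(x, y), orientation=orientation,
                        n_quanta=n_quanta, **kw)
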