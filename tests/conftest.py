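import numpy as np
import pytest

from wheatuniformity import FieldSimConfig, TraitRaster


@pytest.fixture
def cfg() -> FieldSimConfig:
    """Default study-geometry simulator configuration."""
    return FieldSimConfig(seed=0)


@pytest.fixture
def flat_raster() -> TraitRaster:
    """A fully valid constant LAI raster."""
    return TraitRaster(
        values=np.full((10, 12), 3.0),
        mask=np.ones((10, 12), bool),
        gsd_m=0.03,
        trait="LAI",
        plot_id="plot_000",
        stage="FS",
    )
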