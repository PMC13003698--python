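import numpy as np
import pandas as pd
import pytest

from petreltrack import pipeline as pl
from petreltrack import synthetic as syn


@pytest.fixture(scope="session")
def colony():
    return syn.EGG_ISLAND


@pytest.fixture(scope="session")
def bundle():
    """The default seeded two-season synthetic study."""
    return syn.generate_bundle(np.random.SeedSequence(1))


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full pipeline run on the default bundle; returns (out_dir, manifest)."""
    out = tmp_path_factory.mktemp("pipeline_out")
    manifest = pl.run_pipeline(pl.PipelineConfig(out_dir=str(out), seed=1))
    return out, manifest


def make_track(lons, lats, t0="2018-01-01T00:00Z", dt_h=2.0, **meta):
    """Small helper: build a Track from coordinate lists."""
    from petreltrack.geotrack import Track

    n = len(lons)
    ts = pd.date_range(t0, periods=n, freq=pd.Timedelta(hours=dt_h), tz="UTC")
    fixes = pd.DataFrame({"timestamp": ts, "lon": lons, "lat": lats})
    defaults = dict(bird_id="b1", deployment_id="d1", season="hot",
                    stage="incubation", year=2018)
    defaults.update(meta)
    return Track(fixes=fixes, **defaults)
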