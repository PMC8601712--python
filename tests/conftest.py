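import numpy as np
import pandas as pd
import pytest

from njflight.altimetry import AltitudeSeries
from njflight.segmentation import FlightEpisode

T0 = pd.Timestamp("2018-09-10T20:00:00Z")


def grid(n: int, start: pd.Timestamp = T0) -> pd.DatetimeIndex:
    return pd.date_range(start, periods=n, freq="5min")


def series(altitudes, start: pd.Timestamp = T0) -> AltitudeSeries:
    return AltitudeSeries(grid(len(altitudes), start), np.asarray(altitudes, float))


def activity_frame(scores, scale_max=10, start: pd.Timestamp = T0) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "timestamp": grid(len(scores), start),
            "score": list(scores),
            "scale_max": scale_max,
        }
    )


def episode(altitudes, duties=None, start: pd.Timestamp = T0, episode_id="ep0"):
    """A FlightEpisode built directly from altitude (and duty) samples."""
    alt = series(altitudes, start)
    duties = duties if duties is not None else [0.9] * len(altitudes)
    scores = [int(round(d * 10)) for d in duties]
    act = activity_frame(scores, 10, start)
    return FlightEpisode(
        bird_id="birdT",
        start=alt.timestamps[0],
        end=alt.timestamps[-1],
        core_hours=[],
        n_pre=0,
        n_post=0,
        altitude=alt,
        activity=act,
        episode_id=episode_id,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
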