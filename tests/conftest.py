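import numpy as np
import pandas as pd
import pytest

from apoclust import synthetic_tissue as st
from apoclust import track_io


def make_fates(records, movie_end_frame, frame_interval_min=10.0):
    """Hand-built fate table from (cell_id, last_frame, x, y) records;
    censoring inferred from the movie end."""
    df = pd.DataFrame(
        [
            dict(cell_id=cid, first_frame=0, last_frame=last,
                 censored=last == movie_end_frame, x0_um=float(x), y0_um=float(y))
            for cid, last, x, y in records
        ]
    ).set_index("cell_id")
    df.attrs["movie_end_frame"] = movie_end_frame
    df.attrs["frame_interval_min"] = frame_interval_min
    return df


@pytest.fixture(scope="session")
def small_random_movie():
    """Compact random-mode movie shared by read-only tests."""
    cfg = st.SynthConfig(
        seed=11,
        lattice=st.LatticeConfig(n_cols=10, n_rows=8),
        movie=st.MovieConfig(n_frames=60),
    )
    tracks, fates, truth = st.generate_movie(cfg)
    return cfg, tracks, fates, truth


@pytest.fixture()
def spot_file(tmp_path, small_random_movie):
    _, tracks, _, _ = small_random_movie
    path = tmp_path / "spots.csv"
    track_io.write_spot_table(tracks, path)
    return path
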