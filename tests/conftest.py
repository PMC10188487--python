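"""Shared fixtures: a rendered time-lapse scene with ground truth."""

import numpy as np
import pytest

from gastruquant.synthetic_data import (ImageRenderParams, TrackSimParams,
                                        render_timelapse,
                                        simulate_persistent_tracks)
from gastruquant.tracking import Trajectory


def make_scene(seed: int, n_tracks: int = 25, n_frames: int = 30,
               noise_sd: float = 0.2):
    """A rendered SNR-5 movie at the published calibration (0.189 µm/px,
    4 min/frame) with jittered-grid starts, plus its ground-truth table."""
    px = 0.189
    shape = (640, 640)
    field_um = shape[0] * px
    params = TrackSimParams(
        n_tracks=n_tracks, n_steps=n_frames - 1, speed_um_min=0.5,
        persistence_p=0.6, arena_um=(field_um - 20, field_um - 20),
        start_spacing_um=20.0, seed=seed)
    tracks = simulate_persistent_tracks(params)
    # shift into a 10 µm border margin so spots stay clear of the frame edge
    tracks = [Trajectory(t.track_id, t.frames, t.t_min, t.xy_um + 10.0)
              for t in tracks]
    render = ImageRenderParams(shape_px=shape, pixel_size_um=px,
                               blob_sigma_px=2.8, amplitude=1.0,
                               noise_sd=noise_sd, seed=seed + 1)
    stack, truth = render_timelapse(tracks, render)
    return stack, truth, render


@pytest.fixture(scope="session")
def snr5_scene():
    return make_scene(seed=0)
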