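import numpy as np
import pytest

from erkmech import (
    CellTrack,
    LagSpec,
    SyntheticSpec,
    default_ground_truth_rf,
    generate_linear_response_dataset,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture(scope="session")
def small_truth_rf():
    """Compact ground-truth response function for fast recovery tests."""
    return default_ground_truth_rf(L=8)


@pytest.fixture(scope="session")
def small_linear_dataset(small_truth_rf):
    """Noiseless synthetic linear-response dataset, small enough for
    exact-recovery assertions."""
    spec = SyntheticSpec(
        rf=small_truth_rf, n_cells=20, n_frames=120, noise_fraction=0.0, seed=7
    )
    return generate_linear_response_dataset(spec)


@pytest.fixture(scope="session")
def noisy_linear_dataset(small_truth_rf):
    """Synthetic dataset with 10% acceleration noise for statistical tests."""
    spec = SyntheticSpec(
        rf=small_truth_rf, n_cells=60, n_frames=200, noise_fraction=0.1, seed=11
    )
    return generate_linear_response_dataset(spec)


def make_sheet_tracks(
    n_side: int = 8,
    n_frames: int = 30,
    spacing: float = 6.0,
    erk_gradient: float = 0.02,
    drift: float = 0.1,
    jitter: float = 0.3,
    seed: int = 3,
) -> list[CellTrack]:
    """Regular grid of cells drifting in +x with a linear ERK field
    ERK = g * x; positions get small frozen per-cell jitter so quadratic
    fits are well conditioned."""
    rng = np.random.default_rng(seed)
    tracks = []
    frames = np.arange(n_frames)
    for i in range(n_side):
        for j in range(n_side):
            x0 = i * spacing + rng.normal(0, jitter)
            y0 = j * spacing + rng.normal(0, jitter)
            x = x0 + drift * frames
            y = np.full(n_frames, y0)
            erk = erk_gradient * x
            tracks.append(
                CellTrack(
                    cell_id=f"g{i:02d}_{j:02d}",
                    frames=frames,
                    pos=np.column_stack([x, y]),
                    erk=erk,
                )
            )
    return tracks
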