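from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from voitex import CTVolume, VOIMask

# the classical 4-level, 4x4 worked example: at d=1, 0 degrees the
# symmetric ordered-pair counts total 24
WORKED_IMAGE = np.array(
    [
        [0, 0, 1, 1],
        [0, 0, 1, 1],
        [0, 2, 2, 2],
        [2, 2, 3, 3],
    ]
)

WORKED_COUNTS_0DEG = np.array(
    [
        [4, 2, 1, 0],
        [2, 4, 0, 0],
        [1, 0, 6, 1],
        [0, 0, 1, 2],
    ]
)


@pytest.fixture
def worked_volume() -> tuple[CTVolume, VOIMask]:
    vox = WORKED_IMAGE.astype(float)[:, :, None]
    vol = CTVolume(voxels=vox, spacing=(1.0, 1.0, 1.0))
    mask = VOIMask(voxels=np.ones_like(vox, dtype=bool))
    return vol, mask


def make_volume(arr, spacing=(1.0, 1.0, 1.0)) -> CTVolume:
    return CTVolume(voxels=np.asarray(arr, dtype=float), spacing=spacing)


def full_mask(shape) -> VOIMask:
    return VOIMask(voxels=np.ones(shape, dtype=bool))


def random_volume_and_mask(rng, shape=(8, 8, 2), L=8):
    """Random quantized-looking volume with a random nonempty mask."""
    vox = rng.integers(0, L, size=shape).astype(float)
    mask = rng.random(shape) < 0.7
    if not mask.any():
        mask[tuple(s // 2 for s in shape)] = True
    return make_volume(vox), VOIMask(voxels=mask)


def discordant_distance_fixture(n: int = 45, seed: int = 7) -> pd.DataFrame:
    """55-column fixture: all distances rank-concordant within a parameter,
    except correlation q5 and difference_entropy q1, which are independently
    shuffled so they decorrelate from their siblings."""
    from voitex import PARAMETERS

    rng = np.random.default_rng(seed)
    base = {p: rng.normal(size=n) for p in PARAMETERS}
    cols = {"patient_id": [f"P{i:02d}" for i in range(n)],
            "group": (["BM"] * 5 + ["SW"] * 7 + ["SM"] * 30 + ["SP"] * 3)[:n]}
    for p in PARAMETERS:
        for d in range(1, 6):
            # strictly monotone transform per distance keeps ranks identical
            cols[f"{p}_q{d}"] = base[p] * (1.0 + 0.1 * d) + d
    cols["correlation_q5"] = rng.permutation(cols["correlation_q5"])
    cols["difference_entropy_q1"] = rng.permutation(cols["difference_entropy_q1"])
    return pd.DataFrame(cols)
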