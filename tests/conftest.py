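import numpy as np
import pytest

from thalamostate.io_formats import EpochSet, SpikeTrain


def brute_force_bursts(
    times: np.ndarray,
    isi_max_ms: float = 10.0,
    silence_min_ms: float = 50.0,
    min_spikes: int = 2,
) -> list[tuple[int, int]]:
    """Independent burst oracle: exhaustive scan over contiguous subsequences.

    Returns (i, j) index ranges (inclusive) of every subsequence that
    satisfies all burst criteria: length >= min_spikes, every internal ISI
    <= isi_max, maximal on both sides (cannot be extended while keeping ISIs
    short), and preceded by >= silence_min of quiet (or starting the train).
    """
    t = np.asarray(times, float)
    isi_max = isi_max_ms / 1000.0
    silence = silence_min_ms / 1000.0
    n = t.size
    out = []
    for i in range(n):
        for j in range(i + min_spikes - 1, n):
            isis = np.diff(t[i : j + 1])
            if np.any(isis > isi_max):
                break
            left_max = i == 0 or t[i] - t[i - 1] > isi_max
            right_max = j == n - 1 or t[j + 1] - t[j] > isi_max
            quiet = i == 0 or t[i] - t[i - 1] >= silence
            if left_max and right_max and quiet:
                out.append((i, j))
    return out


def random_train(rng: np.random.Generator, n_max: int = 200) -> SpikeTrain:
    """Random spike train mixing burst-like and tonic ISIs, with exact
    boundary values (10 ms and 50 ms) planted to exercise tie rules."""
    n = int(rng.integers(2, n_max + 1))
    kind = rng.integers(0, 4, size=n - 1)
    isis = np.where(
        kind == 0,
        rng.uniform(0.001, 0.010, n - 1),  # burst-like
        np.where(
            kind == 1,
            rng.uniform(0.010, 0.060, n - 1),  # intermediate
            rng.exponential(0.3, n - 1) + 0.011,  # tonic
        ),
    )
    exact = rng.random(n - 1)
    isis = np.where(exact < 0.05, 0.010, np.where(exact > 0.95, 0.050, isis))
    times = np.concatenate([[rng.uniform(0, 0.2)], isis]).cumsum()
    return SpikeTrain("rnd", times)


@pytest.fixture
def nrem_epochs_10min() -> EpochSet:
    return EpochSet(np.array([0.0]), np.array([600.0]), np.array(["NREM"], dtype=object))
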