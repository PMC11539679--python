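import pytest

from resuskit import ActivityProfile, encode_episode, fuse, table3_fixture
from resuskit.synthetic import generate_dataset, haydom_default_config


@pytest.fixture(scope="session")
def sus4_profile() -> ActivityProfile:
    """First four SUS activities: the profile of the 10-second worked example."""
    return ActivityProfile(
        name="SUS4",
        activities=("baby on table", "drying", "stimulation", "ventilation"),
        acronyms=("BOT", "Dry", "Stim", "Vent"),
    )


@pytest.fixture(scope="session")
def table3_episode():
    return table3_fixture()


@pytest.fixture(scope="session")
def table3_fused(table3_episode, sus4_profile):
    return fuse(encode_episode(table3_episode, sus4_profile, n_seconds=10))


@pytest.fixture(scope="session")
def small_haydom_dataset():
    """20 short synthetic Haydom-like episodes with labels and bookkeeping."""
    cfg = haydom_default_config(n_episodes=20, n_seconds=360, seed=7)
    episodes, labels, bookkeeping = generate_dataset(cfg)
    return cfg, episodes, labels, bookkeeping


def brute_force_active_set(records, profile, second):
    """Oracle: 1-based indices of activities overlapping second-bin `second`.

    A record [start, stop) overlaps bin n (1-based) iff start < n*1000 and
    stop > (n-1)*1000; computed directly from the raw intervals, independent
    of the encoding path.
    """
    lo, hi = (second - 1) * 1000, second * 1000
    return frozenset(
        profile.index(r.activity)
        for r in records
        if r.start_ms < hi and r.stop_ms > lo
    )


@pytest.fixture(scope="session")
def oracle_active_set():
    return brute_force_active_set
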