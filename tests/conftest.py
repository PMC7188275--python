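import numpy as np
import pytest

from tfopt import detection, evaluation, synth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_benchmark():
    """A 10-song corpus: enough structure for integration tests, fast."""
    return synth.make_benchmark(7, n_songs=10)


@pytest.fixture(scope="session")
def small_songs(small_benchmark):
    train = [detection.process_song(r, a) for r, a in small_benchmark.train]
    test = [detection.process_song(r, a) for r, a in small_benchmark.test]
    return train, test


@pytest.fixture(scope="session")
def small_fit(small_songs):
    """Templates fitted at two positions of the small corpus."""
    train, _ = small_songs
    return evaluation.fit_syllable(train, "A", 44100, positions=[3, 8])


@pytest.fixture(scope="session")
def full_benchmark_run():
    """The seeded 50-song hard-pair benchmark, fitted end to end.

    Session-scoped: several end-to-end assertions share this single run.
    """
    bench = synth.make_benchmark(1, n_songs=50)
    train = [detection.process_song(r, a) for r, a in bench.train]
    test = [detection.process_song(r, a) for r, a in bench.test]
    fit = evaluation.fit_syllable(train, bench.target_label, 44100)
    return bench, train, test, fit
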