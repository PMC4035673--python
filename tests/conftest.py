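import numpy as np
import pytest

from dtabias.effects import meta_effects
from dtabias.study_data import Corpus, MetaAnalysis, StudyTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_table(rng, study_id="s", n_lo=30, n_hi=300):
    """A random valid 2x2 table with at least one subject per group."""
    n1 = int(rng.integers(n_lo // 2, n_hi // 2))
    n2 = int(rng.integers(n_lo // 2, n_hi // 2))
    tp = int(rng.integers(1, n1))
    tn = int(rng.integers(1, n2))
    return StudyTable(study_id=study_id, tp=tp, fn=n1 - tp, tn=tn, fp=n2 - tn)


def random_meta(rng, meta_id="m", k=8, **kwargs):
    return MetaAnalysis(
        meta_id=meta_id,
        studies=tuple(random_table(rng, f"s{i}", **kwargs) for i in range(k)),
    )


def random_corpus(rng, n_metas=5, k_range=(3, 12)):
    return Corpus(
        metas=tuple(
            random_meta(rng, f"m{i}", k=int(rng.integers(*k_range)))
            for i in range(n_metas)
        ),
        provenance="randomized test corpus",
    )


def random_effects(rng, k=8, **kwargs):
    return meta_effects([random_table(rng, f"s{i}", **kwargs) for i in range(k)])


@pytest.fixture
def effects_factory(rng):
    return lambda k=8, **kw: random_effects(rng, k, **kw)


@pytest.fixture
def meta_factory(rng):
    return lambda k=8, meta_id="m", **kw: random_meta(rng, meta_id, k, **kw)


@pytest.fixture
def corpus_factory(rng):
    return lambda **kw: random_corpus(rng, **kw)
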