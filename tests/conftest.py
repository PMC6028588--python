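from __future__ import annotations

import warnings
from functools import lru_cache

import pytest

from csramod import ViennaEngine, build_ensemble
from csramod.energy import scan_sites
from csramod.fixtures import generate_fixture
from csramod.folding import FoldCache
from csramod.translation import regulate_record


@pytest.fixture(scope="session")
def engine():
    return ViennaEngine()


class _Analyzer:
    """Runs scan -> ensemble -> regulation once per (kind, seed) and caches."""

    def __init__(self, engine: ViennaEngine) -> None:
        self.engine = engine

    @lru_cache(maxsize=None)  # noqa: B019 - session-lifetime cache is intended
    def __call__(self, kind: str, seed: int = 0):
        fx = generate_fixture(kind, seed=seed)
        cache = FoldCache(self.engine)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sites = scan_sites(fx.record.sequence)
            ens = build_ensemble(fx.record.sequence, sites, cache, record_id=fx.record.id)
            call = regulate_record(fx.record, ens, cache) if ens.top_k else None
        return fx, sites, ens, call


@pytest.fixture(scope="session")
def analyze(engine):
    return _Analyzer(engine)
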