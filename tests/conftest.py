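import pytest

from grnswitch import grammar as G
from grnswitch import oracle as O

#: the eleven minimal bistable networks of the two-gene family
MBN_NAMES = ("kqw", "ckn", "bcdh", "ikno", "jmpsv", "bfjpv", "abejp",
             "jknptv", "jkmnps", "dhjknp", "aejknp")


@pytest.fixture(scope="session")
def family():
    """The canonical two-gene circuit family."""
    return G.enumerate_family(2)


@pytest.fixture(scope="session")
def certificates():
    """Session-wide cache of bistability certificates by circuit name."""
    cache: dict[str, O.BistabilityCertificate | None] = {}

    def get(name: str, budget: int = 2000, seed: int = 1):
        if name not in cache:
            cache[name] = O.is_bistable(G.circuit(name), budget=budget,
                                        rng_seed=seed)
        return cache[name]

    return get
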