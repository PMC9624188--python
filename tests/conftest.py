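import sys
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

from gramprod.paradigms import load_paradigm
from gramprod.token_io import Token, TokenSample

# oracles.py lives next to the tests, outside the installed package
sys.path.insert(0, str(Path(__file__).parent))

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def es_paradigm():
    return load_paradigm("es-pres-ind")


@pytest.fixture(scope="session")
def en_paradigm():
    return load_paradigm("en-prog")


def make_sample(records: list[str | tuple[str, str]], label: str = "s") -> TokenSample:
    """Build a TokenSample from 'lemma_marker' strings or (lemma, marker) pairs."""
    toks = []
    for r in records:
        lemma, marker = r.split("_") if isinstance(r, str) else r
        toks.append(Token(lemma, marker))
    return TokenSample(tuple(toks), label=label)


@pytest.fixture
def fig_example(es_paradigm):
    """A small two-sample fixture mimicking the worked filtering example:
    sample 2 contains a lemma ('bail') absent from sample 1."""
    s1 = make_sample(["com_o", "com_en", "salt_o", "salt_a", "quer_o"], label="child")
    s2 = make_sample(
        ["com_o", "com_en", "com_e", "salt_o", "bail_o", "bail_as",
         "com_emos", "salt_an", "quer_e", "quer_o"],
        label="adult",
    )
    return s1, s2
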