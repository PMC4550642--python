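import pytest

from minekit.fixtures import (
    DEMO_RULES,
    fixture_bundle,
    make_fixtures,
    synthetic_bundle,
)
from minekit.rules import ReactionRule


@pytest.fixture(scope="session")
def demo_rules() -> dict[str, ReactionRule]:
    rules = [
        ReactionRule(name, ec, transform, list(cr), list(cp), bool(bidir))
        for name, ec, transform, cr, cp, bidir in DEMO_RULES
    ]
    return {r.name: r for r in rules}


@pytest.fixture(scope="session")
def bundle():
    """Demo seeds expanded one generation with the demo rule set."""
    return fixture_bundle(generations=1)


@pytest.fixture(scope="session")
def big_bundle():
    """1,000-compound homologous-series bundle for search-scale checks."""
    return synthetic_bundle(1000)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("fixtures")
    make_fixtures(outdir)
    return outdir
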