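import json

import pytest

from atlaskit import FixtureManifest, generate_fixture_atlas, parse_atlas

#: Smallest valid atlas: a header, one root group, one structure.
MINIMAL_ATLAS = json.dumps({"@graph": [
    {"@id": "#header", "@type": ["Header"], "structureRoot": "#root"},
    {"@id": "#root", "@type": ["Group"], "members": ["#s1"]},
    {"@id": "#s1", "@type": ["Structure"], "name": "thing"},
]})


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """One shared synthetic atlas directory (seed-fixed, 6 structures)."""
    d = tmp_path_factory.mktemp("atlas") / "fx"
    generate_fixture_atlas(d, seed=42, grid_shape=(24, 24, 16),
                           n_structures=6, depth=3)
    return d


@pytest.fixture(scope="session")
def manifest(fixture_dir):
    return FixtureManifest.read(fixture_dir)


@pytest.fixture(scope="session")
def graph(fixture_dir):
    return parse_atlas((fixture_dir / "atlas.json").read_text(), strict=True)


@pytest.fixture(scope="session")
def nested_graph(fixture_dir):
    return parse_atlas((fixture_dir / "atlas_nested.json").read_text(),
                       strict=True)
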