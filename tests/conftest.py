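import pytest

from famground import fixtures, hierarchy, ontology_io


@pytest.fixture(scope="session")
def inpaper():
    return fixtures.build_inpaper_ontology()


@pytest.fixture(scope="session")
def graph(inpaper):
    return hierarchy.build_graph(inpaper)


@pytest.fixture()
def resource_dir(tmp_path, inpaper):
    """The example ontology written out as the five CSV resource files."""
    d = tmp_path / "resource"
    ontology_io.write_ontology(inpaper, d)
    return d
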