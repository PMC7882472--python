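import numpy as np
import pytest

from fragweb import assembly, community, pipeline, simulate


@pytest.fixture(scope="session")
def tiny_study():
    return simulate.tiny_fixture()


@pytest.fixture(scope="session")
def tiny_paths(tiny_study, tmp_path_factory):
    out = tmp_path_factory.mktemp("tiny")
    return tiny_study.write(out)


@pytest.fixture(scope="session")
def tiny_surveys(tiny_paths):
    return community.load_surveys(tiny_paths["covers"], tiny_paths["counts"])


@pytest.fixture(scope="session")
def tiny_diet(tiny_paths):
    return community.load_diet(tiny_paths["diet"])


@pytest.fixture(scope="session")
def tiny_communities(tiny_surveys, tiny_diet):
    return community.fragment_communities(tiny_surveys, tiny_diet)


@pytest.fixture(scope="session")
def tiny_webs(tiny_communities, tiny_diet):
    return assembly.build_webs(tiny_communities, tiny_diet)


@pytest.fixture(scope="session")
def synthetic_study():
    """One full default synthetic study (28 fragments), shared across tests."""
    return simulate.generate_study(seed=7)


@pytest.fixture(scope="session")
def synthetic_run(tmp_path_factory):
    """A complete pipeline run on synthetic data, shared across tests."""
    out = tmp_path_factory.mktemp("run")
    manifest = pipeline.run_all(out, config=pipeline.PipelineConfig(seed=7), synthetic=True)
    return out, manifest


def random_web(rng: np.random.Generator, max_rows: int = 6, max_cols: int = 6):
    """A random small quantitative web with no empty rows or columns."""
    r = int(rng.integers(1, max_rows + 1))
    c = int(rng.integers(1, max_cols + 1))
    while True:
        b = rng.random((r, c)) * (rng.random((r, c)) < 0.6)
        if b.sum() > 0 and (b.sum(axis=1) > 0).all() and (b.sum(axis=0) > 0).all():
            break
    return assembly.QuantitativeWeb(
        "rand", [f"p{i}" for i in range(r)], [f"c{j}" for j in range(c)], b
    )
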