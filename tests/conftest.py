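import pytest

from dolmn import build_community, classify_reactions, make_toy_model


@pytest.fixture(scope="session")
def toy():
    return make_toy_model()


@pytest.fixture(scope="session")
def toy_classification(toy):
    return classify_reactions(toy)


@pytest.fixture(scope="session")
def toy_k1(toy, toy_classification):
    return build_community(toy, toy_classification, 1)


@pytest.fixture(scope="session")
def toy_k2(toy, toy_classification):
    return build_community(toy, toy_classification, 2)


@pytest.fixture(scope="session")
def core():
    from dolmn import load_ecoli_core

    return load_ecoli_core()
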