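import hypothesis
import pytest

from haams import ChainSpec, EnumerationConstraints, reference_congener_list

hypothesis.settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=60
)
hypothesis.settings.load_profile("suite")


@pytest.fixture(scope="session")
def defaults() -> EnumerationConstraints:
    return EnumerationConstraints()


@pytest.fixture(scope="session")
def unit_res() -> EnumerationConstraints:
    return EnumerationConstraints(tolerance_da=0.5)


@pytest.fixture(scope="session")
def reference():
    return reference_congener_list()


@pytest.fixture(scope="session")
def all_chains(defaults):
    """The default bounded chain space: C4..C18, at most one double bond."""
    return list(defaults.iter_chains())


def pair_space(chains):
    """Brute-force congener space used as the enumeration oracle."""
    from haams import CongenerSpec

    out = set()
    for a in chains:
        for b in chains:
            if a.unsaturations + b.unsaturations <= 2:
                out.add(CongenerSpec(a, b))
    return sorted(out)


@pytest.fixture(scope="session")
def all_congeners(all_chains):
    return pair_space(all_chains)


@pytest.fixture()
def c13() -> ChainSpec:
    return ChainSpec(13, 0)


@pytest.fixture()
def c14_1() -> ChainSpec:
    return ChainSpec(14, 1)
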