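import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from hlapopgen import PopulationSample, make_individual
from hlapopgen.simulate import uyghur_like_fixture


@pytest.fixture(scope="session")
def uyghur_sample() -> PopulationSample:
    """Deterministic 104-individual sample with the published allele counts."""
    return uyghur_like_fixture()


def tiny_sample(genotypes, loci=("L",)):
    """Build a one-locus (or multi-locus) sample from a list of allele pairs."""
    inds = []
    for i, pairs in enumerate(genotypes):
        if isinstance(pairs[0], str):
            pairs = [pairs]
        inds.append(make_individual(f"S{i}", loci, pairs))
    return PopulationSample(loci=tuple(loci), individuals=inds)
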