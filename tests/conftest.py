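import numpy as np
import pytest

from dnscape.core import SampleSpec
from dnscape.coverage import FragmentSet
from dnscape.simulate import ScenarioConfig, build_scenario


def small_config(**overrides) -> ScenarioConfig:
    """A desk-scale scenario: one 200 kb chromosome per genome."""
    kwargs = dict(
        seed=11,
        n_chroms=1,
        chrom_length=200_000,
        with_sequence=False,
        n_genes=15,
        n_acrs=25,
        n_tes=40,
        n_ogs=60,
        fragments_per_sample=60_000,
    )
    kwargs.update(overrides)
    return ScenarioConfig(**kwargs)


@pytest.fixture(scope="session")
def small_scenario():
    return build_scenario(small_config())


@pytest.fixture(scope="session")
def seq_scenario():
    """Small scenario that carries nucleotide sequence (for GC tests)."""
    return build_scenario(small_config(seed=12, with_sequence=True, gc_content={"A": 0.3, "D": 0.4}))


def mk_fragset(intervals, length=1000, chrom="c1", **meta) -> FragmentSet:
    arr = np.asarray(intervals, dtype=np.int64).reshape(-1, 2)
    return FragmentSet({chrom: arr}, {chrom: length}, **meta)


def heavy_sample(n=60_000, genotype="A2", sub="A", rep=1) -> SampleSpec:
    return SampleSpec(genotype, sub, "heavy", rep, n)


def light_sample(n=60_000, genotype="A2", sub="A", rep=1) -> SampleSpec:
    return SampleSpec(genotype, sub, "light", rep, n)
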