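import dataclasses

import pytest

from nurfscape.config import TruthConfig


@pytest.fixture(scope="session")
def truth() -> TruthConfig:
    """Default ground-truth registry with a fixed seed."""
    return TruthConfig(seed=123)


def truth_with_promoters(seed: int, per_class: int) -> TruthConfig:
    base = TruthConfig(seed=seed)
    classes = tuple(
        dataclasses.replace(c, count=per_class) for c in base.genome.classes
    )
    return dataclasses.replace(base, genome=dataclasses.replace(base.genome, classes=classes))


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated genome cohort shared across genomics tests."""
    import nurfscape.simulate as sim

    truth = truth_with_promoters(seed=7, per_class=20)
    genome, annotation = sim.gen_genome(truth)
    return truth, genome, annotation
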