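import numpy as np
import pytest

from plasmidkit.simulate import (
    IsletSpec,
    MobSpec,
    PlasmidSpec,
    RepSpec,
    TASpec,
    generate_plasmid,
)


def random_seq(seed: int, length: int, gc: float = 0.5) -> str:
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


@pytest.fixture(scope="session")
def full_spec():
    """The default study plasmid: REP + MOB + TA + islet in 6 kb at GC 0.60."""
    def make(seed: int) -> PlasmidSpec:
        return PlasmidSpec(length=6000, background_gc=0.60, seed=seed,
                           rep=RepSpec(), mob=MobSpec(), ta=TASpec(),
                           islet=IsletSpec(length=2000, gc=0.40, n_orfs=1))
    return make


@pytest.fixture(scope="session")
def annotated_plasmid(full_spec):
    """Seed-6 plasmid with its truth record (cached for the session)."""
    return generate_plasmid(full_spec(6))
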