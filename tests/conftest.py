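import numpy as np
import pytest

import sramap as sm


@pytest.fixture(scope="session")
def default_bundle() -> sm.SyntheticBundle:
    """The default synthetic study bundle at a fixed seed."""
    return sm.generate_bundle(sm.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def design() -> sm.OrganDesign:
    return sm.OrganDesign()


def perfect_hairpin(
    arm: int = 40,
    loop: int = 6,
    flank5: int = 10,
    flank3: int = 10,
    rng: np.random.Generator | None = None,
) -> tuple[str, str]:
    """A perfect-stem hairpin (sequence, dot-bracket) built by hand.

    Independent of the package's generator: the arm is sampled directly
    and the 3' arm is its reverse complement.
    """
    rng = rng or np.random.default_rng(0)
    nt = np.array(list("ACGT"))
    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
    arm5 = "".join(rng.choice(nt, size=arm))
    loop_seq = "".join(rng.choice(nt, size=loop))
    f5 = "".join(rng.choice(nt, size=flank5))
    f3 = "".join(rng.choice(nt, size=flank3))
    arm3 = "".join(comp[b] for b in reversed(arm5))
    seq = f5 + arm5 + loop_seq + arm3 + f3
    struct = "." * flank5 + "(" * arm + "." * loop + ")" * arm + "." * flank3
    return seq, struct
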