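import numpy as np
import pytest

from refbias.io import PhasedVariant
from refbias.sim import BiasInjectionSpec, SimParams
from refbias.pipeline import run_simulation


def random_seq(n: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


@pytest.fixture(scope="session")
def tandem_repeat_fixture():
    """Reference with an ATTCx3 tract and a HET two-unit deletion.

    The deletion footprint (9 bp) exceeds one repeat unit, so a gap
    re-placed one unit to the right overlaps the footprint only
    partially -- the construction that defeats pileup-trusting
    assignment.
    """
    left = random_seq(500, 5)
    right = random_seq(500, 6)
    ref = {"chrS": left + "G" + "ATTC" * 3 + "T" + right}
    variant = PhasedVariant("chrS", 501, "G" + "ATTC" * 2, "G", (0, 1))
    return ref, variant


@pytest.fixture(scope="session")
def gap_shift_run(tandem_repeat_fixture):
    """Error-free diploid simulation over the tandem-repeat fixture with
    gaps re-placed to their rightmost equivalent positions."""
    ref, variant = tandem_repeat_fixture
    params = SimParams(coverage=30.0, error_rate=0.0, seeds=(1, 2))
    spec = BiasInjectionSpec(mode="gap_shift", sites=[variant], gap_policy="rightmost")
    return run_simulation(ref, [variant], params, injections=[spec])
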