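import numpy as np
import pytest

from whiskloop import synth


@pytest.fixture(scope="session")
def default_session():
    """Full default protocol (3 conditions x 30 sweeps x 2 cycles), one plain unit."""
    proto = synth.ProtocolConfig(seed=1)
    units = [synth.UnitSpec(unit_id="u0", base_rate=5.0)]
    return synth.generate_session(proto, units)


@pytest.fixture(scope="session")
def tagging_session():
    """50 units, half tagged with full suppression at 2 ms latency, base 2-10."""
    rng = np.random.default_rng(11)
    units = []
    for i in range(25):
        units.append(
            synth.UnitSpec(
                unit_id=f"t{i:02d}",
                base_rate=float(rng.uniform(2, 10)),
                opto_suppression=0.0,
                opto_latency_ms=2.0,
                is_tagged=True,
            )
        )
    for i in range(25):
        units.append(
            synth.UnitSpec(
                unit_id=f"n{i:02d}",
                base_rate=float(rng.uniform(2, 10)),
                opto_suppression=1.0,
                is_tagged=False,
            )
        )
    proto = synth.ProtocolConfig(seed=5)
    return synth.generate_session(proto, units, include_lfp=False)
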