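import numpy as np
import pytest

from multistable import Interval, ModelParams, ReversalSequence, SimProtocol


def seq_from_durations(durations, start_state="A", mixed=None,
                       final_complete=True):
    """One-block sequence with alternating A/B periods of given durations."""
    states = ["A", "B"] if start_state == "A" else ["B", "A"]
    intervals = []
    t = 0.0
    for j, d in enumerate(durations):
        complete = final_complete or j + 1 < len(durations)
        intervals.append(Interval(states[j % 2], t, float(d), complete))
        t += d
    return ReversalSequence([intervals])


@pytest.fixture(scope="session")
def operating_params():
    """A mid-regime parameter point with realistic reversal statistics."""
    return ModelParams(beta=1.75, phi_a=0.25, i0=0.5, sigma_n=0.15, tau_a=2.0)


@pytest.fixture(scope="session")
def operating_sequence(operating_params):
    """A long reversal sequence simulated at the operating point."""
    from multistable import simulate_reversals
    return simulate_reversals(operating_params,
                              SimProtocol(duration=2000.0, seed=11))


@pytest.fixture(scope="session")
def coupled_sequence():
    """History-coupled synthetic sequence with known ground truth."""
    from multistable import SynthConfig, history_coupled_sequence
    cfg = SynthConfig(n_blocks=20, block_length=400.0, mean_duration=2.0,
                      shape=4.0, coupling_b=2.0, coupling_tau=3.0, seed=5)
    return history_coupled_sequence(cfg)


@pytest.fixture(scope="session")
def renewal_long():
    """Large renewal sequence (~10^4 periods) for distribution recovery."""
    from multistable import SynthConfig, renewal_sequence
    cfg = SynthConfig(n_blocks=10, block_length=2100.0, mean_duration=2.0,
                      shape=4.0, seed=3)
    return renewal_sequence(cfg)
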