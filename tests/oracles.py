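"""Independent reference implementations used only by the test suite.

These deliberately share no code with the package: the Gillespie
sampler below is a continuous-time event-driven simulation of the same
binding/unbinding rates that the fixed-step engine discretises.
"""

import numpy as np


def gillespie_occupancy_samples(
    n_clutch: int,
    k_on: float,
    k_off: float,
    n_events: int,
    sample_dt: float,
    rng: np.random.Generator,
):
    """Sample the bound-clutch count of a force-free ensemble over time.

    Exact continuous-time simulation: each unbound clutch binds at
    k_on, each bound clutch unbinds at k_off, no force dependence.
    The state is recorded on a regular grid of spacing sample_dt while
    n_events reactions are played out (an initial burn-in of 10/k_off
    is discarded).  Returns an integer array of bound counts.
    """
    bound = 0
    t = 0.0
    burn_in = 10.0 / k_off
    samples = []
    next_sample = burn_in
    for _ in range(n_events):
        rate = (n_clutch - bound) * k_on + bound * k_off
        dt = rng.exponential(1.0 / rate)
        # record grid points passed during this waiting time
        while next_sample <= t + dt:
            samples.append(bound)
            next_sample += sample_dt
        t += dt
        if rng.random() < (n_clutch - bound) * k_on / rate:
            bound += 1
        else:
            bound -= 1
    return np.array(samples, dtype=int)
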