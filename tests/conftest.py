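import numpy as np
import pytest

import synaptoglu as sg


@pytest.fixture(scope="session")
def mini_recording():
    """60 s of synthetic spontaneous quantal events at literature scale.

    127 pA median amplitude, 0.145 ms decay, 7 Hz rate, 5 pA rms noise,
    40 kHz sampling; detection runs once per session and the events are
    shared across tests.
    """
    cfg = sg.SynthConfig(
        seed=1,
        pool=sg.PoolModel(quantal_amp=127e-12, quantal_tau=0.145e-3),
        noise_ephys=5e-12,
        mini_rate=7.0,
    )
    trace, truth = sg.simulate_minis(60.0, cfg, cfg.rng())
    events = sg.detect_minis(trace)
    return cfg, trace, truth, events


@pytest.fixture(scope="session")
def depressing_train_10hz():
    """Noiseless depressing 10-stimulus train at 10 Hz through both readouts."""
    protocol = sg.StimulusProtocol.regular(10, 10.0)
    pool = sg.PoolModel(n_rrp=100, p_r=0.3, refill_rate=0.0)
    released = sg.simulate_pool_train(protocol, pool, deterministic=True).released
    cfg = sg.SynthConfig(noise_ephys=0.0, noise_frames=0.0, pool=pool)
    epsc, _ = sg.render_epsc(released, protocol, cfg)
    fluo = sg.render_fluorescence(released, protocol, cfg)
    return protocol, pool, released, cfg, epsc, fluo


def match_events(truth_onsets, detected_peaks, tol=1.5e-3):
    """Greedy one-to-one matching of detected peaks to ground-truth onsets."""
    used = set()
    matched = 0
    detected = np.asarray(detected_peaks)
    for t in truth_onsets:
        if detected.size == 0:
            break
        d = np.abs(detected - t)
        j = int(np.argmin(d))
        if d[j] < tol and j not in used:
            used.add(j)
            matched += 1
    return matched
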