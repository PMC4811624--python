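import numpy as np
import pytest

import gawvot as gv


@pytest.fixture(scope="session")
def default_spec():
    return gv.SyntheticSpec(seed=42)


@pytest.fixture(scope="session")
def default_recording(default_spec):
    """Default synthetic onset GAW with its ground truth."""
    return gv.generate_gaw(default_spec)


@pytest.fixture(scope="session")
def default_report(default_recording):
    gaw, _ = default_recording
    return gv.analyze_gaw(gaw)


@pytest.fixture(scope="session")
def corpus_recordings():
    """Small seeded corpus with growth rates spread over a realistic range."""
    rng = np.random.default_rng(1234)
    recs = []
    for seed in range(20):
        a = float(rng.uniform(15.0, 60.0))
        f0 = float(rng.uniform(180.0, 240.0))
        spec = gv.SyntheticSpec(seed=seed, a_true=a, f0=f0)
        recs.append(gv.generate_gaw(spec))
    return recs


def m_peaks(a=25.0, r0=0.1, r_sat=1.0, t_max_ms=200.0, dt_ms=5.0, noise_sd=0.0, rng=None):
    """Peak series sampled exactly (or noisily) from the M envelope."""
    t = np.arange(0.0, t_max_ms + 0.5 * dt_ms, dt_ms)
    amps = gv.eval_M(t, a, r0, r_sat)
    if noise_sd > 0:
        amps = amps + noise_sd * rng.standard_normal(t.size)
    return [gv.Peak(i, float(ti), float(ai), True)
            for i, (ti, ai) in enumerate(zip(t, amps))]
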