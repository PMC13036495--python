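import numpy as np
import pytest

import filamech as fm


@pytest.fixture(scope="session")
def truth() -> fm.GroundTruth:
    """Default ground truth (saturating-concentration, wild-type values)."""
    return fm.GroundTruth()


@pytest.fixture(scope="session")
def bare_params() -> fm.WLCParams:
    return fm.WLCParams(lp=45.0, lc=896.0)


def make_ramp(lp: float, seed: int, noise_sd: float = 30.0,
              duration: float = 60.0, f_range=(0.1, 8.0)) -> fm.ForceExtensionCurve:
    """One synthetic force ramp as a force-extension curve."""
    cfg = fm.SimulationConfig(
        duration=duration, seed=seed,
        force_protocol=fm.ForceProtocol("ramp", start=f_range[0], stop=f_range[1]))
    tr = fm.simulate_force_ramp(cfg, fm.WLCParams(lp, 896.0), noise_sd=noise_sd)
    return fm.ForceExtensionCurve(tr.extension, tr.force)


def synthetic_trace(ext: np.ndarray, rate: float = 58.0,
                    force: float = 0.5, **meta) -> fm.TimeTrace:
    """Wrap a bare extension array into a TimeTrace."""
    n = ext.size
    time = np.arange(n) / rate
    return fm.TimeTrace(time, ext, np.full(n, force), np.zeros(n), dict(meta))
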