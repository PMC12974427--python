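import numpy as np
import pytest

from hesdyn import AnalysisConfig, Cohort, Trace
from hesdyn.report import _pooled
from hesdyn.simulate import calibrate_defaults


def make_trace(values, dt=0.25, cell_id="c1", replicate_id="R1",
               condition="proliferative", channel="hes1_endo",
               mitosis_times=(), sphase_times=(), release_time=None):
    values = np.asarray(values, dtype=float)
    return Trace(cell_id=cell_id, replicate_id=replicate_id, condition=condition,
                 channel=channel, times=np.arange(len(values)) * dt, values=values,
                 mitosis_times=np.array(mitosis_times, dtype=float),
                 sphase_times=np.array(sphase_times, dtype=float),
                 release_time=release_time)


def sinusoid_trace(period=24.0, duration=96.0, dt=0.25, amplitude=1.0,
                   offset=10.0, **kw):
    t = np.arange(0.0, duration + dt / 2, dt)
    tr = make_trace(offset + amplitude * np.sin(2 * np.pi * t / period), dt=dt, **kw)
    return tr


def as_cohort(traces, dt=0.25):
    return Cohort(list(traces), dt, max(tr.span for tr in traces))


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def defaults():
    return calibrate_defaults()


@pytest.fixture(scope="session")
def prolif_cohort(defaults):
    """Default proliferative cohort, one 90-cell replicate per seed 1-3."""
    return _pooled(defaults["proliferative"], 90, 96.0, 0.25, [1, 2, 3])


@pytest.fixture(scope="session")
def arrested_cohort(defaults):
    return _pooled(defaults["arrested"], 90, 96.0, 0.25, [1, 2, 3])


@pytest.fixture(scope="session")
def released_cohort(defaults):
    return _pooled(defaults["released"], 100, 96.0, 0.25, [1, 2, 3])
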