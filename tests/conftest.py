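import pytest

from organoflow import extract_roi_timeseries, run_chamber_simulation


@pytest.fixture(scope="session")
def chamber_run():
    """The default full-scale chamber simulation (112x100, t_end 4000 s).

    Shared across tests; ~15 s of compute, run once per session.
    """
    return run_chamber_simulation()


@pytest.fixture(scope="session")
def chamber_series(chamber_run):
    return extract_roi_timeseries(chamber_run.history, chamber_run.rois)
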