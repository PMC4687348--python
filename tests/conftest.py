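from datetime import datetime, timedelta, timezone

import pytest

from insulincalc import GlucoseMeasurement, MeasurementContext, PatientProfile

NOW = datetime(2024, 3, 2, 12, 0, tzinfo=timezone.utc)


@pytest.fixture
def baseline_profile() -> PatientProfile:
    """80 kg, middle-aged, eating, insulin-naive, human-insulin formulary."""
    return PatientProfile(weight=80.0, age=50.0)


def make_series(values, hours_ago=None, now=NOW):
    """Build a BG series; value i taken ``hours_ago[i]`` hours before NOW."""
    if hours_ago is None:
        hours_ago = [len(values) - i for i in range(len(values))]
    return [
        GlucoseMeasurement(
            timestamp=now - timedelta(hours=h),
            value=float(v),
            context=MeasurementContext.Q6H,
        )
        for v, h in zip(values, hours_ago)
    ]


@pytest.fixture
def series_factory():
    return make_series
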