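from datetime import datetime, timedelta

import pytest

from hivegate.logio import Detection, FieldOfView

BASE = datetime(2024, 6, 1, 8, 0, 0)


def make_det(t_seconds, x=100.0, tag_id=5059, y=160.0, theta=0.0, temp=None):
    """Detection at BASE + t_seconds, defaults inside the 800x320 FOV."""
    return Detection(
        tag_id=tag_id,
        timestamp=BASE + timedelta(seconds=t_seconds),
        x=float(x),
        y=float(y),
        theta=float(theta),
        cpu_temp=temp,
    )


@pytest.fixture
def fov():
    return FieldOfView()


@pytest.fixture
def base_time():
    return BASE
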