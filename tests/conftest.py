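import pytest
from hypothesis import settings

from ibsdt import CriticalTrialRecord

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_record(i: int, condition: str, **kwargs) -> CriticalTrialRecord:
    defaults = dict(
        subject_id=f"s{i:05d}",
        experiment_id=kwargs.pop("experiment_id", "exp5"),
        condition=condition,
    )
    return CriticalTrialRecord(**defaults, **kwargs)


@pytest.fixture
def toy_detection_records():
    """10 present (7 noticed) + 10 absent (1 'noticed') exp5-style records."""
    recs = []
    i = 0
    for noticed in ["yes"] * 7 + ["no"] * 3:
        recs.append(
            make_record(
                i,
                "present",
                stim_color="orange",
                stim_shape="circle",
                stim_side="left",
                attended_color="white",
                noticed=noticed,
                color_response="orange",
                shape_response="circle",
                side_response="left",
            )
        )
        i += 1
    for noticed in ["yes"] * 1 + ["no"] * 9:
        recs.append(
            make_record(
                i,
                "absent",
                attended_color="white",
                noticed=noticed,
                color_response="green",
                shape_response="triangle",
                side_response="right",
            )
        )
        i += 1
    return recs


@pytest.fixture
def exp1_reconstructed_records():
    """52 left-stimulus (38 'left' responses) + 55 right (25 'left') non-noticers.

    The unique decision matrix consistent with corrected rates of 72.64%
    and 45.54% and 68/107 correct overall.
    """
    recs = []
    i = 0
    for stim_side, n_total, n_left in (("left", 52, 38), ("right", 55, 25)):
        for j in range(n_total):
            recs.append(
                make_record(
                    i,
                    "present",
                    experiment_id="exp1",
                    stim_color="red",
                    stim_side=stim_side,
                    noticed="no",
                    side_response="left" if j < n_left else "right",
                )
            )
            i += 1
    return recs
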