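import numpy as np
import pytest

import gazelab as gl

#: Small but complete cohort: 2 genotypes, 2 frequencies, all three gaze
#: conditions, pre/post learning and two spike populations.  Short traces
#: keep the fixture fast while still spanning >= 2 stimulus cycles.
SMALL_CONFIG = {
    "stimulus": {"frequencies_hz": [1.0, 2.0], "peak_velocity_dps": 16.0,
                 "duration_s": 10.0, "sampling_rate_hz": 1000.0},
    "eye": {"noise_sd_dps": 2.0, "qp_rate_hz": 1.5, "ms_slope": 35.0,
            "ms_intercept_dps": 5.0, "qp_duration_s": 0.05},
    "groups": {
        "WT": {"n_animals": 3,
               "gain": {"VORd": {1.0: 0.70, 2.0: 0.80},
                        "OKR": {1.0: 0.35, 2.0: 0.20},
                        "VORl": {1.0: 0.90, 2.0: 0.90}},
               "phase": {"VORd": {1.0: 2.0, 2.0: 0.0},
                         "OKR": {1.0: -10.0, 2.0: -15.0},
                         "VORl": {1.0: 0.0, 2.0: 0.0}}},
        "SCA6": {"n_animals": 3,
                 "gain": {"VORd": {1.0: 0.53, 2.0: 0.576},
                          "OKR": {1.0: 0.33, 2.0: 0.19},
                          "VORl": {1.0: 0.75, 2.0: 0.75}},
                 "phase": {"VORd": {1.0: 2.0, 2.0: 0.0},
                           "OKR": {1.0: -10.0, 2.0: -15.0},
                           "VORl": {1.0: 0.0, 2.0: 0.0}}},
    },
    "learning": {
        "WT": {"n_animals": 2,
               "gain_pre": {1.0: 0.70, 2.0: 0.650},
               "gain_post": {1.0: 0.48, 2.0: 0.3497}},
        "SCA6": {"n_animals": 2,
                 "gain_pre": {1.0: 0.53, 2.0: 0.650},
                 "gain_post": {1.0: 0.48, 2.0: 0.5096}},
    },
    "spikes": {"duration_s": 60.0, "process": "gamma_renewal",
               "anesthetized": {"WT": {"n_cells": 3, "rate_sps": 30.49,
                                       "cv": 0.41},
                                "SCA6": {"n_cells": 3, "rate_sps": 38.83,
                                         "cv": 0.68}}},
    "stats": {"bonferroni_comparisons": 2, "alpha": 0.05},
}


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """(directory, ground-truth log) of a generated small cohort."""
    out = tmp_path_factory.mktemp("cohort")
    truth = gl.gen_cohort(SMALL_CONFIG, seed=11, out_dir=out)
    return out, truth


@pytest.fixture()
def stim_2hz():
    return gl.StimulusSpec(frequency=2.0, peak_velocity=16.0, duration=60.0,
                           sampling_rate=1000.0)


def make_recording(gain=0.8, phase=0.0, noise_sd=0.0, qp_rate=0.0, seed=0,
                   frequency=2.0, duration=20.0, condition="VORd",
                   following=False):
    """One synthetic recording plus its ground-truth log."""
    stim = gl.StimulusSpec(frequency=frequency, peak_velocity=16.0,
                           duration=duration, sampling_rate=1000.0)
    head = gl.gen_head_stimulus(stim)
    spec = gl.EyeModelSpec(gain=gain, phase=phase, noise_sd=noise_sd,
                           qp_rate=qp_rate)
    rec, truth = gl.gen_eye_response(head, stim, spec, seed=seed,
                                     metadata={"condition": condition},
                                     following=following)
    return rec, truth


def match_events(detected, injected, pre_slack=0.03, post_slack=0.05):
    """Match detected quick phases to injected ground truth.

    Returns (n_matched_injected, n_spurious): a detected event is matched
    if it lies within the injected pulse extended by the detector margins
    plus slack; otherwise it is spurious.
    """
    matched = set()
    spurious = 0
    for d in detected:
        hit = None
        for i, qp in enumerate(injected):
            if (qp["onset"] - pre_slack <= d.onset
                    and d.offset <= qp["onset"] + qp["width"] + post_slack):
                hit = i
                break
        if hit is None:
            spurious += 1
        else:
            matched.add(hit)
    return len(matched), spurious
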