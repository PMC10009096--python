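"""Shared fixtures: one medium synthetic session with known ground truth.

The session is simulated once per test run and shared (read-only) by the
place-field, theta and GLM tests.
"""

from __future__ import annotations

import pytest

from forageseq import behavior as bh
from forageseq import placefields as pf
from forageseq.core import resample_behavior
from forageseq.synthetic import CellGroundTruth, SimConfig, simulate_session

CELLS = [
    CellGroundTruth(
        "place", "P", field_center=(10.0, 5.0), field_width=9.0,
        peak_rate=10.0, baseline_rate=0.3, theta_depth=0.5,
    ),
    CellGroundTruth("flat", "none", peak_rate=0.0, baseline_rate=2.0, theta_depth=0.0),
    CellGroundTruth(
        "pds", "PDS", field_center=(-10.0, 0.0), field_width=10.0,
        peak_rate=10.0, baseline_rate=0.5, g_d=0.5, g_s=0.5, theta_depth=0.5,
    ),
    CellGroundTruth(
        "prec", "P", field_center=(0.0, 15.0), field_width=9.0,
        peak_rate=12.0, baseline_rate=0.2, theta_depth=0.6, precession_slope=-180.0,
    ),
]


@pytest.fixture(scope="session")
def sim_bundle():
    cfg = SimConfig(seed=7, n_trials=60, cells=CELLS)
    session, truth = simulate_session(cfg)
    frame = resample_behavior(session)
    trials = bh.segment_trials(session)
    spans = [t.span for t in trials]
    valid_bins = pf.visit_mask(frame, spans)
    return {
        "config": cfg,
        "session": session,
        "truth": truth,
        "frame": frame,
        "trials": trials,
        "spans": spans,
        "valid_bins": valid_bins,
    }
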