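"""Activation-time analysis: maps, APD/CV calibration, outcome labels.

The outcome taxonomy follows the four-way classification of
single-stimulus runs through a microfibrotic region:

* ``no_reentry`` — the wave crosses (or avoids) the region and dies out
  without re-exciting any tissue;
* ``non_sustained`` — re-activations occur but the slab is fully
  quiescent before the end of the monitored interval;
* ``activity`` — sustained re-excitation confined to the fibrotic region
  (microreentry acting inside the maze of broken links);
* ``reentry`` — ectopic beats leave the fibrotic region and sustain
  global re-excitation of the surrounding tissue (the region acts as an
  ectopic pacemaker).

"Sustained" means at least one activation event inside the final
assessment window (default the last 100 ms) of the run; "outside the
fibrotic region" means in-plane radius r > R0 + W from the cylinder axis.
These operational definitions are this package's convention (documented
in docs/methods.md); the qualitative taxonomy is standard.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .lattice import FibrosisSpec, LatticeGeometry, node_radius
from .model import FKParameters

__all__ = [
    "OutcomeLabel",
    "Calibration",
    "detect_activations",
    "measure_apd_cv",
    "classify_outcome",
    "pacing_cycle_length",
    "ectopic_cycle_length",
]

APD_THRESHOLD = 0.5  # fixed-voltage APD convention for the normalized AP
SUSTAIN_WINDOW = 100.0  # ms before t_end that defines "sustained"


class OutcomeLabel(str, enum.Enum):
    NO_REENTRY = "no_reentry"
    NON_SUSTAINED = "non_sustained"
    ACTIVITY = "activity"
    REENTRY = "reentry"


@dataclass(frozen=True)
class Calibration:
    """Single-pulse tissue calibration at one excitability level."""

    tau_d: float  # ms
    apd: float  # ms
    cv: float  # cm/s

    @property
    def wavelength(self) -> float:
        """WL = CV · APD in cm."""
        return self.cv * self.apd / 1000.0


def detect_activations(
    trace: np.ndarray,
    times: np.ndarray,
    threshold: float = 0.13,
    dead_time: float = 50.0,
) -> np.ndarray:
    """Upward threshold crossings of a sampled V trace, ≥ dead_time apart.

    Crossing times are linearly interpolated between samples. The first
    crossing is always accepted; later ones only after the dead time.
    """
    trace = np.asarray(trace, dtype=float)
    times = np.asarray(times, dtype=float)
    if trace.shape != times.shape:
        raise ValueError("trace and times must have equal length")
    idx = np.nonzero((trace[:-1] < threshold) & (trace[1:] >= threshold))[0]
    events = []
    t_last = -np.inf
    for i in idx:
        tc = times[i] + (times[i + 1] - times[i]) * (threshold - trace[i]) / (
            trace[i + 1] - trace[i]
        )
        if tc - t_last >= dead_time:
            events.append(tc)
            t_last = tc
    return np.asarray(events)


def _crossing_times(trace, times, threshold, direction):
    """All interpolated crossings, 'up' or 'down'."""
    if direction == "up":
        idx = np.nonzero((trace[:-1] < threshold) & (trace[1:] >= threshold))[0]
    else:
        idx = np.nonzero((trace[:-1] >= threshold) & (trace[1:] < threshold))[0]
    return np.array(
        [
            times[i]
            + (times[i + 1] - times[i]) * (threshold - trace[i]) / (trace[i + 1] - trace[i])
            for i in idx
        ]
    )


def measure_apd_cv(
    params: FKParameters,
    cable_cm: float = 8.0,
    dx: float = 0.01,
    dt: float = 0.0165,
    D: float = 1.0,
    probe_cm: Optional[tuple] = None,
    apd_node_cm: Optional[float] = None,
    t_end: float = 500.0,
) -> Calibration:
    """Measure APD and CV on a homogeneous 1D cable.

    A single stimulus at the left end launches one wave. CV comes from
    the activation-time difference between two interior probes (by
    default at 3/8 and 5/8 of the cable); APD is the duration the
    mid-cable potential stays above ``APD_THRESHOLD`` (0.5, i.e.
    mid-amplitude of the normalized action potential — the convention
    that reproduces the published remodeling table).
    """
    from .lattice import LatticeGeometry, uniform_link_field
    from .simulation import SimulationConfig, StimulusSpec, run_simulation

    if probe_cm is None:
        probe_cm = (0.375 * cable_cm, 0.625 * cable_cm)
    if apd_node_cm is None:
        apd_node_cm = 0.5 * cable_cm
    n = int(round(cable_cm / dx))
    geom = LatticeGeometry(nx=n, ny=1, n_layers=1, dx=dx)
    i1, i2 = (int(round(c / dx)) for c in probe_cm)
    im = int(round(apd_node_cm / dx))
    config = SimulationConfig(
        geom=geom,
        params=params,
        D=D,
        dt=dt,
        t_end=t_end,
        stimulus=StimulusSpec(corner=(0, 0), radius=0.2),
        # dense movie: the cable is small, and the APD needs the
        # repolarizing branch of the trace, not just activation events
        snapshot_every=0.25,
        probes=[(0, 0, i1), (0, 0, i2), (0, 0, im)],
        early_stop=True,
    )
    hist = run_simulation(config)
    a1 = hist.first_activation[0, 0, i1]
    a2 = hist.first_activation[0, 0, i2]
    if not (np.isfinite(a1) and np.isfinite(a2)) or a2 <= a1:
        raise RuntimeError(
            f"propagation failure on the calibration cable at tau_d = {params.tau_d} ms"
        )
    cv = (probe_cm[1] - probe_cm[0]) / (a2 - a1) * 1000.0  # cm/s

    trace = hist.snapshots[:, 0, 0, im].astype(float)
    times = hist.snapshot_times
    ups = _crossing_times(trace, times, APD_THRESHOLD, "up")
    downs = _crossing_times(trace, times, APD_THRESHOLD, "down")
    if len(ups) == 0 or len(downs) == 0:
        raise RuntimeError(
            f"no full action potential at the APD node for tau_d = {params.tau_d} ms"
        )
    up = ups[0]
    later = downs[downs > up]
    if len(later) == 0:
        raise RuntimeError("action potential did not repolarize within t_end")
    apd = later[0] - up
    return Calibration(tau_d=params.tau_d, apd=float(apd), cv=float(cv))


def classify_outcome(
    history,
    fibrosis: Optional[FibrosisSpec],
    sustain_window: float = SUSTAIN_WINDOW,
) -> OutcomeLabel:
    """Four-way outcome label for a completed single-stimulus run.

    reentry: ≥1 second activation outside the fibrotic region (r > R0+W)
    and activity persists into the final assessment window; activity:
    persists, but all re-activations stay inside; non_sustained:
    re-activations occurred but the slab went quiescent before t_end;
    no_reentry: otherwise (includes total propagation failure).
    """
    geom = history.config.geom
    count = history.activation_count
    any_reactivation = bool((count >= 2).any())
    last_t = history.last_activity_time
    sustained = (
        history.quiescent_at is None
        and np.isfinite(last_t)
        and last_t >= history.t_end - sustain_window
    )
    if fibrosis is None:
        outside = np.ones(geom.shape, dtype=bool)
    else:
        outside = node_radius(geom) > fibrosis.outer_radius
    second_outside = bool(np.isfinite(history.second_activation[outside]).any())

    if sustained and second_outside:
        return OutcomeLabel.REENTRY
    if sustained and any_reactivation:
        return OutcomeLabel.ACTIVITY
    if any_reactivation:
        return OutcomeLabel.NON_SUSTAINED
    return OutcomeLabel.NO_REENTRY


def pacing_cycle_length(activation_times: Sequence[float]) -> Optional[float]:
    """Median inter-activation interval (ms) at a probe; None if < 3 events."""
    t = np.sort(np.asarray(activation_times, dtype=float))
    if t.size < 3:
        return None
    return float(np.median(np.diff(t)))


def ectopic_cycle_length(history, min_count: int = 3) -> Optional[float]:
    """Pacing period (ms) of sustained re-excitation, from the activation maps.

    For every node that activated at least ``min_count`` times, the mean
    re-activation interval is (last − second) / (count − 2); the median
    over those nodes estimates the period of the ectopic source. Unlike
    a fixed probe this works even when the monitored window ends before
    the rhythm has reached distant tissue three times. None if no node
    re-activated often enough.
    """
    cnt = history.activation_count
    m = cnt >= max(min_count, 3)
    if not m.any():
        return None
    intervals = (history.last_activation[m] - history.second_activation[m]) / (cnt[m] - 2)
    return float(np.median(intervals))
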