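"""Period, amplitude and qualitative classification of simulated
oscillations.

A trajectory is classified as ``sustained`` (a limit cycle: the last ten
peak-to-peak amplitudes of the steady-state window agree to better than
1%), ``damped`` (oscillations initiate but their amplitude decays), or
``fixed_point`` (no meaningful oscillation at all).  The period is the
mean peak-to-peak interval and is reported only for sustained
oscillations; the amplitude is max - min of the observable over the
steady-state window, which for damped and fixed-point trajectories is
the asymptotic (terminal) value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .dde import Trajectory

__all__ = [
    "OscillationSummary",
    "find_peaks",
    "summarize",
    "percent_period_change",
    "IncomparableConditions",
]

#: Relative amplitude floor: oscillations smaller than this fraction of the
#: observable's full-run range (which is of the order of the production
#: rate kappa1 for Her1) are treated as no oscillation.
AMPLITUDE_FLOOR_REL = 1e-3

#: Relative spread of the last peak-to-peak amplitudes below which an
#: oscillation counts as steady.
STEADY_TOL = 0.01

#: Per-cycle amplitude ratio below which a declining oscillation counts as
#: damped rather than steady.
DAMPED_RATIO = 0.99


class IncomparableConditions(ValueError):
    """Raised when a period comparison involves a non-sustained condition."""


@dataclass(frozen=True)
class OscillationSummary:
    """Summary of one oscillation analysis.

    ``period`` is NaN unless the classification is ``sustained``;
    ``decay_rate`` is the per-cycle amplitude ratio (1.0 for a sustained
    oscillation, < 1 for a damped one, 0.0 for a fixed point).
    """

    period: float
    amplitude: float
    classification: str
    decay_rate: float
    n_cycles_used: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def find_peaks(times: np.ndarray, values: np.ndarray) -> list[tuple[float, float]]:
    """Local maxima of a uniformly sampled signal.

    Strict three-point maxima are refined to sub-grid accuracy with a
    parabola through the three samples; plateaus (runs of equal values
    above both neighbors) return the plateau midpoint.  A constant signal
    has no peaks.  Endpoints are never peaks.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size != values.size:
        raise ValueError("times and values must have equal length")
    if times.size < 3:
        raise ValueError("need at least 3 samples to find peaks")

    peaks: list[tuple[float, float]] = []
    n = values.size
    i = 1
    while i < n - 1:
        if values[i] > values[i - 1]:
            # scan over a possible plateau
            j = i
            while j < n - 1 and values[j + 1] == values[i]:
                j += 1
            if j < n - 1 and values[j + 1] < values[i]:
                if j == i:
                    # strict maximum: parabolic refinement
                    vm, v0, vp = values[i - 1], values[i], values[i + 1]
                    denom = vm - 2.0 * v0 + vp
                    offset = 0.5 * (vm - vp) / denom if denom != 0.0 else 0.0
                    step = times[i] - times[i - 1]
                    peaks.append(
                        (
                            float(times[i] + offset * step),
                            float(v0 - 0.25 * (vm - vp) * offset),
                        )
                    )
                else:
                    mid = 0.5 * (times[i] + times[j])
                    peaks.append((float(mid), float(values[i])))
                i = j + 1
                continue
            i = j + 1
            continue
        i += 1
    return peaks


def _extract_observable(traj: Trajectory, observable) -> np.ndarray:
    from . import clock

    if callable(observable):
        return np.asarray(observable(traj), dtype=float)
    if observable in traj.labels:
        return traj.component(observable)
    if isinstance(observable, str) and observable.startswith("total_"):
        factor = observable[len("total_"):]
        if factor in ("her1", "her7", "hes6"):
            return clock.total_protein_series(traj, factor)
    raise KeyError(
        f"unknown observable {observable!r}: expected a component label, "
        "'total_her1'/'total_her7'/'total_hes6', or a callable"
    )


def _cycle_amplitudes(
    peaks: list[tuple[float, float]], troughs: list[tuple[float, float]]
) -> list[float]:
    """Per-cycle amplitude: each peak minus the next trough."""
    amps = []
    ti = 0
    for tp, vp in peaks:
        while ti < len(troughs) and troughs[ti][0] <= tp:
            ti += 1
        if ti >= len(troughs):
            break
        amps.append(vp - troughs[ti][1])
    return amps


def summarize(
    traj: Trajectory,
    observable="total_her1",
    amplitude_floor: float | None = None,
) -> OscillationSummary:
    """Classify a trajectory and extract period and amplitude.

    The first half of the run is discarded as transient.  ``observable``
    selects the analyzed signal: a component label, a ``total_*`` protein
    selector (the headline observable is total Her1), or a callable on
    the trajectory.  ``amplitude_floor`` defaults to ``1e-3`` times the
    observable's full-run range.
    """
    v = _extract_observable(traj, observable)
    t = traj.times
    if t.size < 16:
        raise ValueError(
            "trajectory too short to analyze; extend t_end "
            "(need >= 20 putative cycles after transient)"
        )
    v_range = float(np.max(v) - np.min(v))
    eps = AMPLITUDE_FLOOR_REL * v_range if amplitude_floor is None else amplitude_floor

    half = t.size // 2
    tw, vw = t[half:], v[half:]

    peaks_all = find_peaks(t, v)
    troughs_all = [(tt, -vv) for tt, vv in find_peaks(t, -v)]
    peaks_w = [pk for pk in peaks_all if pk[0] >= tw[0]]
    troughs_w = [tr for tr in troughs_all if tr[0] >= tw[0]]
    amps_w = _cycle_amplitudes(peaks_w, troughs_w)
    amps_all = _cycle_amplitudes(peaks_all, troughs_all)

    def terminal_amplitude() -> float:
        tail = max(2, t.size // 20)  # final 5% of the run
        return float(np.max(v[-tail:]) - np.min(v[-tail:]))

    # -- steady, sustained oscillation?
    if len(amps_w) >= 10:
        last10 = np.array(amps_w[-10:])
        mean_amp = float(np.mean(last10))
        spread = float((np.max(last10) - np.min(last10)) / mean_amp) if mean_amp > 0 else np.inf
        if mean_amp > eps and spread < STEADY_TOL:
            intervals = np.diff([pk[0] for pk in peaks_w])
            used = intervals[-10:] if intervals.size > 10 else intervals
            period = float(np.mean(used))
            amplitude = float(np.max(vw) - np.min(vw))
            return OscillationSummary(
                period=period,
                amplitude=amplitude,
                classification="sustained",
                decay_rate=1.0,
                n_cycles_used=int(used.size),
            )

    # -- oscillations that initiated but decay (or already died out)
    meaningful = [a for a in amps_all if a > eps]
    if len(meaningful) >= 3:
        ratios = [b / a for a, b in zip(meaningful, meaningful[1:]) if a > 0]
        decay = float(np.median(ratios)) if ratios else 0.0
        if decay < DAMPED_RATIO or (amps_w and amps_w[-1] < eps) or not amps_w:
            return OscillationSummary(
                period=float("nan"),
                amplitude=terminal_amplitude(),
                classification="damped",
                decay_rate=min(decay, 1.0),
                n_cycles_used=len(meaningful),
            )
        # declining too slowly to call damped but not steady either:
        # conservatively report damped with the measured ratio
        return OscillationSummary(
            period=float("nan"),
            amplitude=terminal_amplitude(),
            classification="damped",
            decay_rate=min(decay, 1.0),
            n_cycles_used=len(meaningful),
        )

    return OscillationSummary(
        period=float("nan"),
        amplitude=terminal_amplitude(),
        classification="fixed_point",
        decay_rate=0.0,
        n_cycles_used=0,
    )


def transient_period(
    traj: Trajectory,
    observable="total_her1",
    amplitude_floor: float | None = None,
) -> float:
    """Period of the oscillatory mode regardless of whether it sustains.

    For a damped condition the decaying oscillation still has a
    well-defined cycle time; this measures the mean interval between
    successive peaks whose cycle amplitude exceeds the floor, skipping
    the first (startup) interval.  For a sustained oscillation it agrees
    with :func:`summarize` to within the steady-state tolerance.  Returns
    NaN when fewer than three meaningful peaks exist (a fixed point).
    """
    v = _extract_observable(traj, observable)
    t = traj.times
    v_range = float(np.max(v) - np.min(v))
    eps = AMPLITUDE_FLOOR_REL * v_range if amplitude_floor is None else amplitude_floor
    peaks = find_peaks(t, v)
    troughs = [(tt, -vv) for tt, vv in find_peaks(t, -v)]
    amps = _cycle_amplitudes(peaks, troughs)
    good = [pk[0] for pk, a in zip(peaks, amps) if a > eps]
    if len(good) < 3:
        return float("nan")
    intervals = np.diff(good)[1:]  # drop the startup interval
    return float(np.mean(intervals[-10:] if intervals.size > 10 else intervals))


def percent_period_change(
    p_a,
    p_b,
    t_end: float = 300.0,
    dt: float | None = None,
    observable="total_her1",
) -> float:
    """Signed percent period difference between two parameter sets,
    100*(period_a - period_b)/period_b, measured on total Her1 (by
    default) of fresh simulations.

    Raises :class:`IncomparableConditions` if either condition does not
    sustain oscillations.
    """
    from .clock import simulate

    summaries = {}
    for tag, p in (("a", p_a), ("b", p_b)):
        s = summarize(simulate(p, t_end=t_end, dt=dt), observable=observable)
        if s.classification != "sustained":
            raise IncomparableConditions(
                f"condition {tag} is {s.classification}, not sustained; "
                "periods are incomparable"
            )
        summaries[tag] = s
    return 100.0 * (summaries["a"].period - summaries["b"].period) / summaries["b"].period
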