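"""Fixed-step integration of delay differential equations with constant lags.

Implements the classical method of steps: the system is advanced with an
explicit fourth-order Runge-Kutta scheme on a uniform grid, and delayed
state lookups are served from the stored solution using cubic Hermite
interpolation between grid points (the history function covers arguments
at or before the initial time).

The integrator is deliberately fixed-step.  The oscillator models built on
top of it have smooth limit cycles and lags of order one, so a step of a
hundredth of the shortest lag resolves the dynamics comfortably, and a
fixed grid makes convergence checks (halving ``dt``) trivial to state and
test.  Adaptive stepping, state-dependent lags and distributed delays are
out of scope.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DDEProblem",
    "Trajectory",
    "IntegrationError",
    "integrate",
]

logger = logging.getLogger(__name__)

#: Required ratio between the smallest positive lag and the step size.
MIN_STEPS_PER_DELAY = 10


class IntegrationError(RuntimeError):
    """Raised when the state becomes non-finite during integration.

    Attributes
    ----------
    time:
        The time reached when the failure was detected.
    """

    def __init__(self, message: str, time: float):
        super().__init__(message)
        self.time = time


@dataclass
class DDEProblem:
    """A system of delay differential equations with constant lags.

    Parameters
    ----------
    rhs:
        Callable ``rhs(t, y, z)`` returning ``dy/dt`` where ``y`` is the
        current state vector and ``z`` is a list of delayed state vectors,
        one per entry of ``delays`` (in the same order).  A lag of exactly
        zero is served with the current state.
    delays:
        Non-negative constant lags, in the same (dimensionless) time unit
        as ``t_span``.
    history:
        Callable ``history(t)`` returning the state vector for any
        ``t <= t0``.
    t_span:
        ``(t0, t_end)`` with ``t_end > t0``.
    dim:
        State dimension.
    """

    rhs: Callable[[float, np.ndarray, list[np.ndarray]], np.ndarray]
    delays: Sequence[float]
    history: Callable[[float], np.ndarray]
    t_span: tuple[float, float]
    dim: int

    def __post_init__(self) -> None:
        if any(tau < 0 for tau in self.delays):
            raise ValueError(f"delays must be non-negative, got {list(self.delays)}")
        t0, t1 = self.t_span
        if not t1 > t0:
            raise ValueError(f"t_span must satisfy t_end > t0, got {self.t_span}")
        if self.dim < 1:
            raise ValueError("dim must be >= 1")


@dataclass
class Trajectory:
    """Solution of a DDE on a uniform time grid.

    ``states`` has shape ``(len(times), dim)``; ``labels`` names the
    columns.  ``meta`` records integration diagnostics such as the number
    of negative-concentration clamp events.
    """

    times: np.ndarray
    states: np.ndarray
    labels: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape != (self.times.size, len(self.labels)):
            raise ValueError(
                "states must have shape (len(times), len(labels)); got "
                f"{self.states.shape} for {self.times.size} times, "
                f"{len(self.labels)} labels"
            )
        if self.times.size >= 2:
            steps = np.diff(self.times)
            if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-8):
                raise ValueError("times must be strictly increasing with uniform step")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def component(self, label: str) -> np.ndarray:
        """Return the time series of one named component."""
        try:
            j = self.labels.index(label)
        except ValueError:
            raise KeyError(f"no component {label!r}; have {self.labels}") from None
        return self.states[:, j]

    def to_tsv(self, path) -> None:
        """Write the trajectory as TSV with a time column plus one column
        per component."""
        df = pd.DataFrame(self.states, columns=self.labels)
        df.insert(0, "time", self.times)
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path) -> "Trajectory":
        df = pd.read_csv(path, sep="\t")
        labels = [c for c in df.columns if c != "time"]
        return cls(df["time"].to_numpy(), df[labels].to_numpy(), labels)


def _hermite_weights(theta: float, dt: float) -> tuple[float, float, float, float]:
    """Cubic Hermite basis at fractional position ``theta`` in [0, 1],
    returning weights for (y_j, y_{j+1}, f_j, f_{j+1}); derivative weights
    carry the ``dt`` factor."""
    t2 = theta * theta
    t3 = t2 * theta
    h00 = 2.0 * t3 - 3.0 * t2 + 1.0
    h10 = t3 - 2.0 * t2 + theta
    h01 = -2.0 * t3 + 3.0 * t2
    h11 = t3 - t2
    return h00, h01, dt * h10, dt * h11


def integrate(
    problem: DDEProblem,
    dt: float,
    labels: Sequence[str] | None = None,
    clamp_negative: bool = False,
) -> Trajectory:
    """Integrate a :class:`DDEProblem` with fixed-step RK4 (method of steps).

    Delayed arguments are interpolated from the stored solution with cubic
    Hermite patches; on a uniform grid the fractional offsets are the same
    at every step, so the interpolation weights are precomputed once.
    Stage times falling inside the current step would require lags shorter
    than the step; these are excluded by requiring
    ``dt <= min(positive delays) / 10``.

    Parameters
    ----------
    problem:
        The DDE system to solve.
    dt:
        Positive step size.  Rejected if larger than one tenth of the
        smallest positive lag.
    labels:
        Component names for the returned :class:`Trajectory`; defaults to
        ``x0 .. x{dim-1}``.
    clamp_negative:
        If True, clamp state components at zero after each step (a guard
        for concentration variables); each event is counted in
        ``Trajectory.meta['clamp_events']`` and logged.

    Raises
    ------
    IntegrationError
        If the state becomes non-finite (overflow/NaN); the exception
        reports the time reached.
    ValueError
        For an invalid step size.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    positive = [tau for tau in problem.delays if tau > 0]
    if positive and dt > min(positive) / MIN_STEPS_PER_DELAY + 1e-12:
        raise ValueError(
            f"dt={dt} too large: must be <= min positive delay / "
            f"{MIN_STEPS_PER_DELAY} = {min(positive) / MIN_STEPS_PER_DELAY}"
        )

    t0, t_end = problem.t_span
    n_steps = int(math.ceil((t_end - t0) / dt - 1e-9))
    dim = problem.dim
    rhs = problem.rhs
    history = problem.history

    times = t0 + dt * np.arange(n_steps + 1)
    ys = np.empty((n_steps + 1, dim))
    fs = np.empty((n_steps + 1, dim))
    y0 = np.asarray(history(t0), dtype=float)
    if y0.shape != (dim,):
        raise ValueError(f"history(t0) must have shape ({dim},), got {y0.shape}")
    ys[0] = y0

    delays = list(problem.delays)
    n_delays = len(delays)
    # Precompute, for each RK stage offset and each positive lag, the integer
    # grid offset and Hermite weights of the delayed lookup (constant on a
    # uniform grid).
    stage_offsets = (0.0, 0.5, 1.0)
    lookup: list[list[tuple[int, float, float, float, float] | None]] = []
    for c in stage_offsets:
        row: list[tuple[int, float, float, float, float] | None] = []
        for tau in delays:
            if tau == 0:
                row.append(None)  # zero lag: use the stage state itself
                continue
            s_rel = c - tau / dt
            # snap to the grid when the lag is an integer number of steps
            if abs(s_rel - round(s_rel)) < 1e-9:
                s_rel = round(s_rel)
            j_off = int(math.floor(s_rel))
            theta = s_rel - j_off
            w0, w1, w2, w3 = _hermite_weights(theta, dt)
            row.append((j_off, w0, w1, w2, w3))
        lookup.append(row)

    def delayed_states(i: int, stage: int, stage_y: np.ndarray) -> list[np.ndarray]:
        out = []
        row = lookup[stage]
        c = stage_offsets[stage]
        for k in range(n_delays):
            entry = row[k]
            if entry is None:
                out.append(stage_y)
                continue
            j_off, w0, w1, w2, w3 = entry
            j = i + j_off
            if j < 0:
                # argument at or before t0: ask the history function
                out.append(np.asarray(history(t0 + (i + c) * dt - delays[k]), dtype=float))
            else:
                out.append(w0 * ys[j] + w1 * ys[j + 1] + w2 * fs[j] + w3 * fs[j + 1])
        return out

    # With only positive lags, the delayed states at a stage do not depend
    # on the stage state, so the two half-step stages share one lookup.
    lags_all_positive = all(tau > 0 for tau in delays)

    clamp_events = 0
    half = 0.5 * dt
    sixth = dt / 6.0
    for i in range(n_steps):
        t = times[i]
        y = ys[i]
        k1 = np.asarray(rhs(t, y, delayed_states(i, 0, y)))
        fs[i] = k1
        y2 = y + half * k1
        z_half = delayed_states(i, 1, y2)
        k2 = np.asarray(rhs(t + half, y2, z_half))
        y3 = y + half * k2
        if not lags_all_positive:
            z_half = delayed_states(i, 1, y3)
        k3 = np.asarray(rhs(t + half, y3, z_half))
        y4 = y + dt * k3
        k4 = np.asarray(rhs(t + dt, y4, delayed_states(i, 2, y4)))
        y_new = y + sixth * (k1 + 2.0 * (k2 + k3) + k4)
        if not np.all(np.isfinite(y_new)):
            raise IntegrationError(
                f"non-finite state at t={times[i + 1]:.6g} "
                f"(integration started at t0={t0:g})",
                time=float(times[i + 1]),
            )
        if clamp_negative and np.any(y_new < 0.0):
            clamp_events += int(np.sum(y_new < 0.0))
            np.maximum(y_new, 0.0, out=y_new)
        ys[i + 1] = y_new
    # derivative at the final node, so the last Hermite patch is complete
    fs[n_steps] = np.asarray(
        rhs(times[-1], ys[n_steps], delayed_states(n_steps, 0, ys[n_steps]))
    )

    if clamp_events:
        logger.warning("clamped %d negative state components to zero", clamp_events)

    if labels is None:
        labels = [f"x{j}" for j in range(dim)]
    return Trajectory(
        times,
        ys,
        list(labels),
        meta={"dt": dt, "clamp_events": clamp_events, "derivatives": fs},
    )
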