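"""Minimal three-variable model of the zebrafish segmentation clock.

The core pacemaker circuit couples three Hairy/Enhancer-of-split-related
bHLH repressors: Her1 and Her7, whose genes oscillate, and Hes6, which is
produced at a constant rate.  The proteins dimerize promiscuously, but of
the resulting dimer cloud only Her1:Her1 homodimers and Her7:Hes6
heterodimers bind DNA, where they repress the *her1* and *her7* promoters
with delays set by protein production.  Dimers that do not bind DNA still
matter: every dimer is degraded, so monomers sequestered into the cloud
acquire an extra, concentration-dependent loss channel.

Under the assumption that dimerization equilibrates much faster than
production and turnover, dimer levels are instantaneous products of
monomer levels and the circuit reduces to three delay differential
equations for the monomer concentrations h1, h6, h7 (dimensionless; time
in units of the monomer lifetime, dimers in units of the half-repression
threshold)::

    dh1/ds = kappa1 * H(h1(s-tau1)^2 + h6(s-tau1)*h7(s-tau1))
             - h1 - delta*h1*(h1 + h6 + h7)
    dh6/ds = kappa6 - h6 - delta*h6*(h1 + h6 + h7)
    dh7/ds = kappa7 * H(h1(s-tau7)^2 + h6(s-tau7)*h7(s-tau7))
             - h7 - delta*h7*(h1 + h6 + h7)

with the Hill repression function H(d) = 1 / (1 + d^n).  The linear -h
term is plain monomer turnover and the delta term is degradation of
monomers resident in dimers.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import yaml

from .dde import DDEProblem, Trajectory, integrate

__all__ = [
    "ClockParameters",
    "MonomerState",
    "GENOTYPES",
    "repression",
    "minimal_rhs",
    "simulate",
    "make_mutant",
    "total_protein",
    "total_protein_series",
    "effective_degradation",
]

#: Genotypes the model distinguishes.  Mutating a gene zeroes the matching
#: production rate; the hes6 heterozygote halves kappa6.
GENOTYPES = (
    "wildtype",
    "her1",
    "her7",
    "hes6",
    "her7;hes6",
    "her1;hes6",
    "her1;her7",
    "hes6_het",
)

_FACTORS = ("her1", "her7", "hes6")


@dataclass(frozen=True)
class ClockParameters:
    """Dimensionless parameters of the reduced clock model.

    Defaults are the wildtype reference set: production rates
    kappa1 = kappa7 = 10 and kappa6 = 90, production delays tau1 = 1.02
    and tau7 = 1.00 (the 2% difference reflects the longer *her1* gene),
    dimer-mediated degradation delta = 1 and Hill coefficient n = 2.

    ``homodimer_double_loss`` switches the dimer-mediated loss term from
    the symmetric form delta*h_i*(h1+h6+h7) to the variant with an extra
    factor on the self term, delta*h_i*(h1+h6+h7+h_i), which counts both
    monomers lost when a homodimer is degraded.  The default is the
    symmetric form; the variant changes no qualitative behavior.
    """

    kappa1: float = 10.0
    kappa7: float = 10.0
    kappa6: float = 90.0
    tau1: float = 1.02
    tau7: float = 1.00
    n: float = 2.0
    delta: float = 1.0
    homodimer_double_loss: bool = False

    def __post_init__(self) -> None:
        for name in ("kappa1", "kappa7", "kappa6", "tau1", "tau7", "delta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.n < 1:
            raise ValueError(f"Hill coefficient n must be >= 1, got {self.n}")

    def replace(self, **kwargs) -> "ClockParameters":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ClockParameters":
        """Read parameters from a ``key: value`` YAML file; absent keys
        keep their defaults, unknown keys are rejected."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown parameter(s) in {path}: {sorted(unknown)}")
        return cls(**data)


@dataclass(frozen=True)
class MonomerState:
    """Monomer concentrations at a single time point."""

    h1: float
    h6: float
    h7: float

    def __post_init__(self) -> None:
        if self.h1 < 0 or self.h6 < 0 or self.h7 < 0:
            raise ValueError(f"monomer concentrations must be >= 0, got {self}")

    def as_array(self) -> np.ndarray:
        return np.array([self.h1, self.h6, self.h7])


def repression(d11: float, d67: float, n: float) -> float:
    """Production fraction under Hill repression by the two DNA-binding
    dimers.

    The Her1 homodimer (``d11``) and Her7:Hes6 heterodimer (``d67``)
    levels enter a single Hill term additively, in units of the
    half-repression threshold (scaled to 1): a combined dimer level of 1
    halves production.  ``n`` is a phenomenological Hill coefficient for
    the effective cooperativity of multiple promoter binding sites.
    """
    if d11 < 0 or d67 < 0:
        raise ValueError(f"dimer levels must be >= 0, got d11={d11}, d67={d67}")
    return 1.0 / (1.0 + (d11 + d67) ** n)


def minimal_rhs(
    now: MonomerState,
    delayed_tau1: MonomerState,
    delayed_tau7: MonomerState,
    p: ClockParameters,
) -> tuple[float, float, float]:
    """Time derivatives (dh1/ds, dh6/ds, dh7/ds) of the reduced model.

    Equilibrium dimer levels are products of (delayed) monomer levels:
    d11 = h1^2, d67 = h6*h7.  Hes6 production is constant in time, so its
    equation carries neither a delay nor a repression term.
    """
    h1, h6, h7 = now.h1, now.h6, now.h7
    total = h1 + h6 + h7
    extra1 = h1 if p.homodimer_double_loss else 0.0
    extra6 = h6 if p.homodimer_double_loss else 0.0
    extra7 = h7 if p.homodimer_double_loss else 0.0
    z1, z7 = delayed_tau1, delayed_tau7
    dh1 = (
        p.kappa1 * repression(z1.h1 ** 2, z1.h6 * z1.h7, p.n)
        - h1
        - p.delta * h1 * (total + extra1)
    )
    dh6 = p.kappa6 - h6 - p.delta * h6 * (total + extra6)
    dh7 = (
        p.kappa7 * repression(z7.h1 ** 2, z7.h6 * z7.h7, p.n)
        - h7
        - p.delta * h7 * (total + extra7)
    )
    return dh1, dh6, dh7


def _make_rhs(p: ClockParameters):
    """Array-valued right-hand side for the integrator (same equations as
    :func:`minimal_rhs`, parameters bound to locals for speed, no per-call
    validation)."""
    kappa1, kappa6, kappa7 = p.kappa1, p.kappa6, p.kappa7
    n, delta = p.n, p.delta
    double_loss = p.homodimer_double_loss
    array = np.array

    def rhs(t, y, z):
        h1 = y[0]
        h6 = y[1]
        h7 = y[2]
        z1 = z[0]
        z7 = z[1]
        total = h1 + h6 + h7
        d_rep1 = z1[0] * z1[0] + z1[1] * z1[2]
        d_rep7 = z7[0] * z7[0] + z7[1] * z7[2]
        if double_loss:
            loss1 = h1 + delta * h1 * (total + h1)
            loss6 = h6 + delta * h6 * (total + h6)
            loss7 = h7 + delta * h7 * (total + h7)
        else:
            dtot = 1.0 + delta * total
            loss1 = h1 * dtot
            loss6 = h6 * dtot
            loss7 = h7 * dtot
        return array(
            [
                kappa1 / (1.0 + d_rep1 ** n) - loss1,
                kappa6 - loss6,
                kappa7 / (1.0 + d_rep7 ** n) - loss7,
            ]
        )

    return rhs


def default_dt(p: ClockParameters) -> float:
    """Default integration step: a hundredth of the shortest production
    delay (falling back to 0.01 if both delays are zero)."""
    taus = [tau for tau in (p.tau1, p.tau7) if tau > 0]
    return min(taus) / 100.0 if taus else 0.01


def simulate(
    p: ClockParameters,
    t_end: float = 300.0,
    dt: float | None = None,
) -> Trajectory:
    """Integrate the reduced model from constant zero history.

    The zero history means production bootstraps the dynamics; only the
    steady-state attractor is of interest, and the transient is discarded
    by the downstream oscillation analysis.  ``t_end`` should be long
    enough to contain at least ~20 cycles after the transient (the
    default 300 monomer lifetimes gives dozens).
    """
    if dt is None:
        dt = default_dt(p)
    zero = np.zeros(3)
    problem = DDEProblem(
        rhs=_make_rhs(p),
        delays=[p.tau1, p.tau7],
        history=lambda t: zero,
        t_span=(0.0, t_end),
        dim=3,
    )
    traj = integrate(problem, dt, labels=["h1", "h6", "h7"], clamp_negative=True)
    traj.meta["parameters"] = p.to_dict()
    return traj


def make_mutant(p: ClockParameters, genotype: str) -> ClockParameters:
    """Parameter set for a genotype: loss-of-function mutations zero the
    production rate of the affected gene(s); the hes6 heterozygote halves
    kappa6."""
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}; expected one of {GENOTYPES}")
    if genotype == "wildtype":
        return p
    if genotype == "hes6_het":
        return p.replace(kappa6=p.kappa6 / 2.0)
    updates = {}
    for gene in genotype.split(";"):
        updates[{"her1": "kappa1", "her7": "kappa7", "hes6": "kappa6"}[gene]] = 0.0
    return p.replace(**updates)


def total_protein(state: MonomerState, factor: str) -> float:
    """Total concentration of one factor: free monomer plus all monomers
    resident in equilibrium dimers (two per homodimer).

    For Her1: total = h1 + 2*h1^2 + h1*h6 + h1*h7, and analogously for
    the other factors.
    """
    if factor not in _FACTORS:
        raise ValueError(f"factor must be one of {_FACTORS}, got {factor!r}")
    h = {"her1": state.h1, "hes6": state.h6, "her7": state.h7}
    own = h[factor]
    others = [h[f] for f in _FACTORS if f != factor]
    return own + 2.0 * own ** 2 + own * others[0] + own * others[1]


def total_protein_series(traj: Trajectory, factor: str) -> np.ndarray:
    """Vectorized :func:`total_protein` over a simulated trajectory."""
    if factor not in _FACTORS:
        raise ValueError(f"factor must be one of {_FACTORS}, got {factor!r}")
    h1 = traj.component("h1")
    h6 = traj.component("h6")
    h7 = traj.component("h7")
    own = {"her1": h1, "hes6": h6, "her7": h7}[factor]
    return own + 2.0 * own ** 2 + own * (h1 + h6 + h7) - own * own


def effective_degradation(
    traj: Trajectory,
    p: ClockParameters,
    component: str = "her1",
) -> tuple[float, float]:
    """Mean effective degradation rate and half-life of a monomer.

    The instantaneous per-capita loss rate of each monomer in the reduced
    model is r(s) = 1 + delta*(h1 + h6 + h7) (plus the homodimer self
    term if that variant is active): one unit of plain turnover plus
    dimer-mediated degradation that scales with the total monomer pool.
    For a sustained oscillation the rate is averaged over an integer
    number of cycles of the steady-state window; a damped or fixed-point
    trajectory uses the terminal value.  Returns ``(mean rate,
    ln(2)/mean rate)``.
    """
    from .oscillation import find_peaks, summarize

    if component not in _FACTORS:
        raise ValueError(f"component must be one of {_FACTORS}, got {component!r}")
    h1 = traj.component("h1")
    h6 = traj.component("h6")
    h7 = traj.component("h7")
    own = {"her1": h1, "hes6": h6, "her7": h7}[component]
    rate = 1.0 + p.delta * (h1 + h6 + h7 + (own if p.homodimer_double_loss else 0.0))

    summary = summarize(traj, observable="total_" + component)
    if summary.classification == "sustained":
        # average between the first and last peak of the steady window
        half = traj.times.size // 2
        peaks = find_peaks(traj.times[half:], own[half:])
        t_first, t_last = peaks[0][0], peaks[-1][0]
        mask = (traj.times >= t_first) & (traj.times <= t_last)
        mean_rate = float(np.trapezoid(rate[mask], traj.times[mask]) / (t_last - t_first))
    else:
        mean_rate = float(rate[-1])
    return mean_rate, math.log(2.0) / mean_rate
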