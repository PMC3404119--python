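"""Scripted in-silico experiments on the clock model.

Each function runs a family of simulations of the reduced model and
tabulates oscillation summaries: production-rate sweeps of Hes6
(`kappa6_sweep`), the eight-genotype mutant panel (`mutant_panel`),
the Her1-delay scan (`delay_scan`), one-at-a-time parameter sensitivity
(`sensitivity`) and cycle-averaged monomer/dimer levels
(`dimer_levels`).  Results are pandas DataFrames ready for TSV export;
the command-line interface wraps these functions one to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clock import (
    ClockParameters,
    GENOTYPES,
    MonomerState,
    make_mutant,
    simulate,
    total_protein_series,
)
from .dde import IntegrationError
from .oscillation import summarize, transient_period

__all__ = [
    "SweepResult",
    "kappa6_sweep",
    "mutant_panel",
    "delay_scan",
    "sensitivity",
    "dimer_levels",
    "DEFAULT_KAPPA6_GRID",
    "SCENARIOS",
]

#: Default Hes6 production-rate grid: covers all named genotype markers
#: (0 and 90) with headroom.
DEFAULT_KAPPA6_GRID = tuple(float(x) for x in range(0, 151, 5))

#: The two sweep scenarios: Her7 production equal to Her1's (the
#: wildtype/hes6 line) and zero (the her7/her7;hes6 line).
SCENARIOS = ("kappa7_equal_kappa1", "kappa7_zero")

#: (scenario, kappa6) combinations naming genotypes on the sweep.
GENOTYPE_MARKERS = {
    ("kappa7_equal_kappa1", 90.0): "wildtype",
    ("kappa7_equal_kappa1", 0.0): "hes6",
    ("kappa7_zero", 90.0): "her7",
    ("kappa7_zero", 0.0): "her7;hes6",
}


@dataclass
class SweepResult:
    """Period and amplitude of total Her1 along a kappa6 grid, per
    scenario.  Non-sustained grid points carry their (asymptotic)
    amplitude with the period absent (NaN); ``transient_period`` records
    the decaying-mode cycle time where one exists."""

    kappa6_grid: np.ndarray
    table: pd.DataFrame  # columns: scenario, kappa6, classification,
    #                      period, transient_period, amplitude, genotype
    parameters: dict = field(default_factory=dict)

    def scenario(self, name: str) -> pd.DataFrame:
        return self.table[self.table["scenario"] == name].reset_index(drop=True)

    def marker(self, genotype: str) -> pd.Series:
        rows = self.table[self.table["genotype"] == genotype]
        if rows.empty:
            raise KeyError(f"no marker row for genotype {genotype!r}")
        return rows.iloc[0]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _observable_for(p: ClockParameters) -> str:
    """Headline observable: total Her1, except total Her7 when Her1
    production is absent (the her1-mutant sweep convention)."""
    return "total_her7" if p.kappa1 == 0 else "total_her1"


def _summarize_point(p: ClockParameters, t_end: float, dt: float | None, observable=None):
    traj = simulate(p, t_end=t_end, dt=dt)
    obs = observable or _observable_for(p)
    s = summarize(traj, observable=obs)
    tp = s.period if s.classification == "sustained" else transient_period(traj, observable=obs)
    return traj, s, tp


def kappa6_sweep(
    base: ClockParameters,
    grid=DEFAULT_KAPPA6_GRID,
    scenarios=SCENARIOS,
    t_end: float = 300.0,
    dt: float | None = None,
) -> SweepResult:
    """Sweep the Hes6 production rate for the kappa7 = kappa1 and
    kappa7 = 0 scenarios, summarizing total Her1 at each grid point.

    Integrator failures at individual grid points are recorded (row
    classification ``error``) and the sweep continues.
    """
    grid = np.asarray(sorted(float(g) for g in grid))
    rows = []
    for scen in scenarios:
        if scen not in SCENARIOS:
            raise ValueError(f"unknown scenario {scen!r}; expected one of {SCENARIOS}")
        kappa7 = base.kappa1 if scen == "kappa7_equal_kappa1" else 0.0
        for k6 in grid:
            p = base.replace(kappa6=float(k6), kappa7=kappa7)
            genotype = GENOTYPE_MARKERS.get((scen, float(k6)), "")
            try:
                _, s, tp = _summarize_point(p, t_end, dt, observable="total_her1")
            except IntegrationError as err:
                rows.append(
                    dict(scenario=scen, kappa6=k6, classification="error",
                         period=np.nan, transient_period=np.nan,
                         amplitude=np.nan, genotype=genotype, error=str(err))
                )
                continue
            rows.append(
                dict(scenario=scen, kappa6=k6, classification=s.classification,
                     period=s.period, transient_period=tp,
                     amplitude=s.amplitude, genotype=genotype, error="")
            )
    table = pd.DataFrame(rows)
    return SweepResult(
        kappa6_grid=grid,
        table=table,
        parameters={**base.to_dict(), "t_end": t_end, "dt": dt},
    )


def mutant_panel(
    base: ClockParameters,
    t_end: float = 300.0,
    dt: float | None = None,
    genotypes=GENOTYPES,
) -> pd.DataFrame:
    """Classification, period and amplitude for each genotype.

    The observable is total Her1 except in her1-mutant backgrounds,
    where total Her7 carries the oscillation.
    """
    rows = []
    for g in genotypes:
        p = make_mutant(base, g)
        obs = _observable_for(p)
        _, s, tp = _summarize_point(p, t_end, dt, observable=obs)
        rows.append(
            dict(genotype=g, observable=obs, classification=s.classification,
                 period=s.period, transient_period=tp, amplitude=s.amplitude,
                 decay_rate=s.decay_rate)
        )
    return pd.DataFrame(rows)


def delay_scan(
    base: ClockParameters,
    tau1_values=(1.00, 1.02, 1.04),
    grid=DEFAULT_KAPPA6_GRID,
    t_end: float = 300.0,
    dt: float | None = None,
) -> dict[float, SweepResult]:
    """Repeat the kappa6 sweep for several Her1 production delays,
    probing how the delay difference between *her1* and *her7* tunes the
    wildtype-vs-her7-mutant period gap."""
    return {
        float(tau1): kappa6_sweep(
            base.replace(tau1=float(tau1)), grid=grid, t_end=t_end, dt=dt
        )
        for tau1 in tau1_values
    }


#: One-at-a-time sensitivity default multipliers (symmetric around 1 on a
#: log scale; the perturbation set is this module's choice and is echoed
#: in the output).
DEFAULT_MULTIPLIERS = (0.5, 0.8, 0.9, 1.1, 1.25, 2.0)

SENSITIVITY_PARAMETERS = ("kappa1", "kappa7", "kappa6", "tau1", "tau7", "delta", "n")


def sensitivity(
    base: ClockParameters,
    multipliers=DEFAULT_MULTIPLIERS,
    parameters=SENSITIVITY_PARAMETERS,
    t_end: float = 300.0,
    dt: float | None = None,
) -> pd.DataFrame:
    """One-at-a-time parameter perturbation around a reference set.

    Each row multiplies one parameter by one factor and records the
    period and amplitude of total Her1, plus percent changes relative to
    the unperturbed reference (the multiplier-1.0 row).  Non-oscillatory
    cells are flagged by their classification, not fatal.
    """
    _, ref, _ = _summarize_point(base, t_end, dt, observable="total_her1")
    if ref.classification != "sustained":
        raise ValueError("reference parameter set does not sustain oscillations")
    rows = [
        dict(parameter="(reference)", multiplier=1.0, classification=ref.classification,
             period=ref.period, amplitude=ref.amplitude,
             period_pct_change=0.0, amplitude_pct_change=0.0)
    ]
    for name in parameters:
        for m in multipliers:
            p = base.replace(**{name: getattr(base, name) * float(m)})
            try:
                _, s, _ = _summarize_point(p, t_end, dt, observable="total_her1")
            except IntegrationError:
                rows.append(dict(parameter=name, multiplier=m, classification="error",
                                 period=np.nan, amplitude=np.nan,
                                 period_pct_change=np.nan, amplitude_pct_change=np.nan))
                continue
            ppc = (
                100.0 * (s.period - ref.period) / ref.period
                if s.classification == "sustained" else np.nan
            )
            apc = 100.0 * (s.amplitude - ref.amplitude) / ref.amplitude
            rows.append(dict(parameter=name, multiplier=m,
                             classification=s.classification,
                             period=s.period, amplitude=s.amplitude,
                             period_pct_change=ppc, amplitude_pct_change=apc))
    return pd.DataFrame(rows)


#: Combined DNA-binding dimer level at which production is halved (the
#: reduced model measures dimers in units of this threshold).
HALF_REPRESSION_THRESHOLD = 1.0


def dimer_levels(
    base: ClockParameters,
    genotypes=("wildtype", "her1", "her7", "hes6", "her7;hes6"),
    t_end: float = 300.0,
    dt: float | None = None,
) -> pd.DataFrame:
    """Cycle-averaged monomer and equilibrium-dimer levels per genotype.

    Averages are taken over the steady-state window (second half of the
    run); equilibrium dimers are instantaneous products of the monomer
    series, averaged over the window, so e.g. <d67> reflects the
    covariance of h6 and h7, not the product of their means.  The
    half-repression threshold (1 in reduced units) is included for
    comparison with the repressive dimer levels.
    """
    rows = []
    for g in genotypes:
        p = make_mutant(base, g)
        traj = simulate(p, t_end=t_end, dt=dt)
        half = traj.times.size // 2
        h1 = traj.component("h1")[half:]
        h6 = traj.component("h6")[half:]
        h7 = traj.component("h7")[half:]
        rows.append(
            dict(
                genotype=g,
                h1=h1.mean(), h6=h6.mean(), h7=h7.mean(),
                d11=(h1 * h1).mean(), d16=(h1 * h6).mean(),
                d17=(h1 * h7).mean(), d66=(h6 * h6).mean(),
                d67=(h6 * h7).mean(), d77=(h7 * h7).mean(),
                half_repression_threshold=HALF_REPRESSION_THRESHOLD,
            )
        )
    return pd.DataFrame(rows)
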