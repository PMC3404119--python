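"""Seeded generators for every input the analysis stages consume.

Each generator draws from a ``numpy`` Generator seeded explicitly, so the
same configuration reproduces byte-identical data, and each returns (or
writes) machine-readable ground truth alongside the data so consuming
modules can be tested closed-loop: titration series with known relative
affinities, somite-boundary tables with known genotype periods, and
promoter sequence with planted H-box 12-mers.

Noise models: fluorescence noise is multiplicative log-normal (signals
stay positive and the spread scales with the signal, as for chip
intensities); boundary-time noise is additive Gaussian; background DNA
is i.i.d. at a given GC content (no dinucleotide structure - sufficient
for recall/precision testing of the scanner).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .mitomi import BindingSeries, HBoxHit
from .timing import REQUIRED_COLUMNS

__all__ = [
    "GeneratorConfig",
    "gen_binding_series",
    "gen_boundary_table",
    "gen_promoter",
    "DEFAULT_BINDING_TRUTH",
    "DEFAULT_GENOTYPE_PERIODS",
    "WILDTYPE_PERIOD_MIN",
]

#: Default relative affinities (1/K_d, arbitrary units) for a binding
#: experiment: bHLH pairs 4-20x above a PPARg-like non-bHLH negative
#: control, with at most ~2-fold differences among the bHLH pairs.
DEFAULT_BINDING_TRUTH = {
    "Her7:Hes6": 1.00,
    "Her1:Her1": 0.90,
    "Her7:Her1": 0.55,
    "Her7:Her7": 0.50,
    "Hes6:Her1": 0.45,
    "MyoD:Her7": 0.40,
    "PPARg:Her7": 0.05,
}

#: Wildtype somitogenesis period at 28.5 degC, minutes per somite.
WILDTYPE_PERIOD_MIN = 25.0

#: Default genotype period factors relative to wildtype: hes6
#: heterozygotes segment 2% slower and homozygotes 6% slower.
DEFAULT_GENOTYPE_PERIODS = {
    "wildtype": 1.00,
    "hes6_het": 1.02,
    "hes6": 1.06,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Bundle of generator settings with the seed and ground truth,
    serializable next to the data it produced."""

    seed: int = 0
    noise_cv: float = 0.10
    n_points: int = 8
    timing_sd_min: float = 0.75
    n_embryos: int = 25
    somite_range: tuple[int, int] = (2, 17)
    binding_truth: dict = field(default_factory=lambda: dict(DEFAULT_BINDING_TRUTH))
    genotype_periods: dict = field(
        default_factory=lambda: dict(DEFAULT_GENOTYPE_PERIODS)
    )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def gen_binding_series(
    truth: dict[str, float] | None = None,
    n_points: int = 8,
    noise_cv: float = 0.10,
    seed: int = 0,
    background: float = 5.0,
    free_range: tuple[float, float] = (1.0, 100.0),
) -> list[BindingSeries]:
    """Titration series in the linear (sub-K_d) binding regime.

    ``truth`` maps probe id to relative affinity (proportional to
    1/K_d); free-signal values are log-spaced over ``free_range`` and
    bound = background + slope_true * free * exp(eps) with
    eps ~ Normal(0, noise_cv).  The same free grid is shared by all
    probes of the set, as on one chip.
    """
    if truth is None:
        truth = dict(DEFAULT_BINDING_TRUTH)
    if n_points < 3:
        raise ValueError("need at least 3 titration points")
    rng = np.random.default_rng(seed)
    free = np.geomspace(free_range[0], free_range[1], n_points)
    out = []
    for probe, slope in truth.items():
        eps = rng.normal(0.0, noise_cv, size=n_points) if noise_cv > 0 else 0.0
        bound = background + slope * free * np.exp(eps)
        out.append(
            BindingSeries(
                probe_id=probe,
                free_signal=tuple(free),
                bound_signal=tuple(np.maximum(bound, 0.0)),
                group="synthetic",
            )
        )
    return out


def gen_boundary_table(
    genotype_periods: dict[str, float] | None = None,
    n_embryos: int = 25,
    somite_range: tuple[int, int] = (2, 17),
    timing_sd: float = 0.75,
    seed: int = 0,
    base_period: float = WILDTYPE_PERIOD_MIN,
    batch: str = "exp1",
) -> pd.DataFrame:
    """Boundary-formation times linear in somite index with Gaussian
    timing noise.

    ``genotype_periods`` maps genotype to its period as a factor of
    ``base_period`` (minutes per somite).  Each embryo gets a jittered
    onset time; formation_time = onset + period*(index - first) +
    Normal(0, timing_sd).  Defaults follow the measured effect sizes
    (heterozygous hes6 2% slower, homozygous 6% slower than wildtype)
    with noise at 3% of the wildtype period.
    """
    if genotype_periods is None:
        genotype_periods = dict(DEFAULT_GENOTYPE_PERIODS)
    first, last = somite_range
    if last - first + 1 < 3:
        raise ValueError("somite_range must span at least 3 somites")
    rng = np.random.default_rng(seed)
    indices = np.arange(first, last + 1)
    rows = []
    for genotype, factor in genotype_periods.items():
        period = base_period * factor
        for e in range(n_embryos):
            embryo = f"{genotype}_{e:03d}"
            onset = rng.uniform(0.0, 2.0 * base_period)
            noise = rng.normal(0.0, timing_sd, size=indices.size)
            times = onset + period * (indices - first) + noise
            for i, t in zip(indices, times):
                rows.append(
                    dict(
                        embryo_id=embryo,
                        batch=batch,
                        genotype=genotype,
                        somite_index=int(i),
                        time_min=float(t),
                    )
                )
    return pd.DataFrame(rows, columns=["embryo_id", "batch", "genotype",
                                       "somite_index", "time_min"])


def _spurious_core_positions(seq: list[str]) -> list[tuple[int, str]]:
    """Positions of H-box cores on either strand of a mutable sequence."""
    from .mitomi import scan_hbox

    hits = scan_hbox("".join(seq))
    return [(h.start + 3, h.strand) for h in hits]


def gen_promoter(
    length: int = 5000,
    planted: list[tuple[int, str]] | None = None,
    gc: float = 0.4,
    seed: int = 0,
    contig: str = "synthetic_promoter",
    avoid_spurious: bool = True,
) -> tuple[SeqRecord, list[HBoxHit]]:
    """Random promoter-like DNA with planted H-box 12-mers.

    ``planted`` lists (position, twelve_mer) pairs: the 12-mer is
    spliced in with its core starting at position+3.  Planted motifs
    must be non-overlapping and in bounds.  With ``avoid_spurious``
    (default), background H-box cores arising by chance are destroyed
    by mutating their central G before planting, so the planted sites
    are the only hits - the single-H-box promoter scenario.  Returns
    the record and the truth as a list of hits (BED-ready).

    This is synthetic sequence: i.i.d. background at the given GC
    content, not a real genomic promoter.
    """
    from .mitomi import scan_hbox

    planted = planted or []
    rng = np.random.default_rng(seed)
    p_g = gc / 2.0
    p_a = (1.0 - gc) / 2.0
    seq = list(
        rng.choice(list("ACGT"), size=length, p=[p_a, p_g, p_g, p_a])
    )

    intervals = []
    for pos, mer in planted:
        if len(mer) != 12:
            raise ValueError(f"planted motif must be a 12-mer, got {mer!r}")
        if pos < 0 or pos + 12 > length:
            raise ValueError(f"planted motif at {pos} out of bounds for length {length}")
        intervals.append((pos, pos + 12))
    intervals.sort()
    for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
        if s2 < e1:
            raise ValueError("planted motifs overlap")

    if avoid_spurious:
        # destroy chance cores by flipping the fourth core base (a G
        # required by the consensus in either orientation); repeat since
        # a mutation can create a new core nearby
        for _ in range(10):
            spurious = _spurious_core_positions(seq)
            if not spurious:
                break
            for core_start, _strand in spurious:
                seq[core_start + 3] = "A"

    for pos, mer in planted:
        seq[pos : pos + 12] = list(mer.upper())

    record = SeqRecord(Seq("".join(seq)), id=contig, description="synthetic promoter")

    # ground truth comes from the planting plan itself, independent of the
    # scanner that will be tested against it
    from .mitomi import _is_hbox_core, _revcomp

    truth = []
    for pos, mer in planted:
        mer = mer.upper()
        core = mer[3:9]
        if _is_hbox_core(core):
            truth.append(HBoxHit(contig, pos, pos + 12, "+", mer, core))
        elif _is_hbox_core(_revcomp(mer)[3:9]):
            truth.append(
                HBoxHit(contig, pos, pos + 12, "-", _revcomp(mer), _revcomp(mer)[3:9])
            )
    return record, truth
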