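"""Relative binding affinities from titration series, and H-box motif
scanning.

In a MITOMI-style equilibrium binding assay operated below the
dissociation constant, the amount of bound material at any free
concentration is approximately proportional to 1/K_d, so the slope of an
ordinary least-squares line of bound signal on free signal is a relative
affinity.  Slopes are compared within an experiment after normalizing
the strongest interaction to one.

The Hes/Her consensus binding site (the H-box) is the hexamer CACGNG;
the in-vivo-relevant subset is CACG[T/C]G.  :func:`scan_hbox` reports
every H-box core on either strand of a DNA sequence as a 12-mer with
3-nt flanks, BED-style.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from scipy import stats

__all__ = [
    "BindingSeries",
    "RelativeAffinity",
    "HBoxHit",
    "fit_relative_affinity",
    "normalize_set",
    "compare_slopes",
    "rank_library",
    "scan_hbox",
    "read_binding_tsv",
    "write_affinity_tsv",
    "write_bed",
    "ALL_CACNNN",
]

_BASES = "ACGT"

#: The 64 permutations of CACNNN probed to define the consensus.
ALL_CACNNN = tuple("CAC" + "".join(tail) for tail in itertools.product(_BASES, repeat=3))


@dataclass(frozen=True)
class BindingSeries:
    """One titration: matched free-signal / bound-signal fluorescence
    pairs for a single probe (a protein pair or a DNA 12-mer)."""

    probe_id: str
    free_signal: tuple[float, ...]
    bound_signal: tuple[float, ...]
    group: str = ""

    def __post_init__(self) -> None:
        if len(self.free_signal) != len(self.bound_signal):
            raise ValueError(
                f"{self.probe_id}: free and bound signals differ in length "
                f"({len(self.free_signal)} vs {len(self.bound_signal)})"
            )
        if len(self.free_signal) < 3:
            raise ValueError(f"{self.probe_id}: need >= 3 titration points")
        if any(x < 0 for x in self.free_signal + self.bound_signal):
            raise ValueError(f"{self.probe_id}: signals must be >= 0")


@dataclass(frozen=True)
class RelativeAffinity:
    """Fitted slope of a binding series with its standard error, fit
    quality, and (once :func:`normalize_set` has run) the slope divided
    by the strongest slope of its set."""

    probe_id: str
    slope: float
    stderr: float
    r_squared: float
    normalized: float = float("nan")
    group: str = ""


def fit_relative_affinity(
    series: BindingSeries, max_free: float | None = None
) -> RelativeAffinity:
    """OLS fit of bound on free signal; the slope is the relative
    affinity.

    The fit includes an intercept, because constant background
    fluorescence is real in chip assays and does not affect the slope.
    The series is assumed to lie in the linear (sub-K_d) regime;
    ``max_free`` optionally drops saturating points above a free-signal
    cutoff.
    """
    free = np.asarray(series.free_signal, dtype=float)
    bound = np.asarray(series.bound_signal, dtype=float)
    if max_free is not None:
        keep = free <= max_free
        if keep.sum() < 3:
            raise ValueError(
                f"{series.probe_id}: fewer than 3 points below max_free={max_free}"
            )
        free, bound = free[keep], bound[keep]
    if np.ptp(free) == 0:
        raise ValueError(f"{series.probe_id}: free signal has zero variance")
    res = stats.linregress(free, bound)
    return RelativeAffinity(
        probe_id=series.probe_id,
        slope=float(res.slope),
        stderr=float(res.stderr),
        r_squared=float(res.rvalue**2),
        group=series.group,
    )


def normalize_set(affinities: Sequence[RelativeAffinity]) -> list[RelativeAffinity]:
    """Fill ``normalized`` = slope / max slope across the set.

    Negative fitted slopes (a noise artifact for non-binders) are clamped
    to zero before normalization.  An empty or all-zero set is rejected.
    """
    import warnings

    if not affinities:
        raise ValueError("cannot normalize an empty affinity set")
    clamped = []
    for aff in affinities:
        if aff.slope < 0:
            warnings.warn(
                f"{aff.probe_id}: negative fitted slope {aff.slope:.3g} clamped to 0"
            )
            aff = replace(aff, slope=0.0)
        clamped.append(aff)
    top = max(a.slope for a in clamped)
    if top <= 0:
        raise ValueError("all slopes are zero; nothing to normalize against")
    return [replace(a, normalized=a.slope / top) for a in clamped]


def compare_slopes(a: RelativeAffinity, b: RelativeAffinity) -> float:
    """Two-sided z-test for a slope difference: |slope_a - slope_b| /
    sqrt(se_a^2 + se_b^2) against the standard normal."""
    if not (a.stderr > 0 and b.stderr > 0):
        raise ValueError("both affinities need a positive standard error")
    z = (a.slope - b.slope) / np.hypot(a.stderr, b.stderr)
    return float(2.0 * stats.norm.sf(abs(z)))


def _is_hbox_core(core: str) -> bool:
    # CACGNG: fixed bases at 1-4 and 6; position 5 free (N allowed when
    # stating the consensus itself)
    return (
        len(core) == 6
        and core[0] == "C"
        and core[1] == "A"
        and core[2] == "C"
        and core[3] == "G"
        and core[4] in _BASES + "N"
        and core[5] == "G"
    )


def _collapse_n(core: str) -> str:
    """Family pattern of a CACNNN 6-mer with the central variable base
    (position 5, 1-based) collapsed to N."""
    return core[:4] + "N" + core[5]


def rank_library(
    affinities: Sequence[RelativeAffinity],
) -> tuple[pd.DataFrame, str | None, str]:
    """Rank a complete CACNNN library and extract the consensus core.

    ``affinities`` must contain one entry per 64 CACNNN permutation
    (probe ids are the 6-mers); missing permutations are an error.
    Returns ``(table, best_family, best_single)`` where the table is
    sorted by normalized affinity, ``best_family`` is the top pattern
    after collapsing the variable position 5 (e.g. ``CACGNG``) or None
    when no family separates from the rest (flagged), and
    ``best_single`` is the strongest individual 6-mer.
    """
    have = {a.probe_id for a in affinities}
    missing = sorted(set(ALL_CACNNN) - have)
    if missing:
        raise ValueError(f"library incomplete: missing {len(missing)} permutations, "
                         f"e.g. {missing[:5]}")
    norm = normalize_set(list(affinities))
    table = pd.DataFrame(
        dict(
            probe_id=[a.probe_id for a in norm],
            slope=[a.slope for a in norm],
            stderr=[a.stderr for a in norm],
            normalized=[a.normalized for a in norm],
            family=[_collapse_n(a.probe_id) for a in norm],
        )
    ).sort_values("normalized", ascending=False, ignore_index=True)
    family_means = table.groupby("family")["normalized"].mean().sort_values(ascending=False)
    best_single = table.iloc[0]["probe_id"]
    # A consensus exists only if the top family separates from the next.
    if len(family_means) >= 2 and family_means.iloc[0] - family_means.iloc[1] < 0.05:
        return table, None, best_single
    return table, family_means.index[0], best_single


@dataclass(frozen=True)
class HBoxHit:
    """One H-box occurrence: a 12-mer (3-nt flanks around the CACGNG
    core) in 0-based half-open coordinates on the + or - strand.
    Coordinates may extend past the sequence ends when the core lies
    within 3 nt of an edge; the missing flank bases are padded with N."""

    contig: str
    start: int
    end: int
    strand: str
    twelve_mer: str
    core: str

    def __post_init__(self) -> None:
        if self.end - self.start != 12:
            raise ValueError("an H-box hit spans exactly 12 bases")
        if not _is_hbox_core(self.core):
            raise ValueError(f"not an H-box core: {self.core}")


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def scan_hbox(sequence, contig: str = "seq", strict: bool = False) -> list[HBoxHit]:
    """Find every H-box core (CACGNG; CACG[T/C]G with ``strict``) on both
    strands of a DNA sequence.

    ``sequence`` is a string over {A,C,G,T,N} or a Biopython SeqRecord
    (whose id becomes the contig).  Each hit is reported as the 12-mer
    made of the core and 3-nt flanks, in the hit's strand orientation;
    flanks running past the sequence ends are padded with N.  The
    palindromic core CACGTG matches both strands at the same position;
    such duplicates are collapsed to a single + strand hit.  An N in the
    sequence never matches a fixed core position.
    """
    if hasattr(sequence, "seq"):
        contig = sequence.id
        sequence = str(sequence.seq)
    seq = sequence.upper()
    if len(seq) < 12:
        raise ValueError("sequence must be at least 12 bases long")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")

    # position 5 is unconstrained in the permissive consensus, so even an
    # ambiguous N matches there; strict mode must confirm T or C
    allowed = "TC" if strict else _BASES + "N"

    def core_at(p: int, strand: str) -> str | None:
        s = seq[p : p + 6]
        if strand == "-":
            s = _revcomp(s)
        if _is_hbox_core(s) and s[4] in allowed:
            return s
        return None

    def padded_12mer(p: int) -> str:
        lo, hi = p - 3, p + 9
        left = "N" * max(0, -lo)
        right = "N" * max(0, hi - len(seq))
        return left + seq[max(lo, 0) : min(hi, len(seq))] + right

    hits: list[HBoxHit] = []
    for p in range(len(seq) - 5):
        fwd = core_at(p, "+")
        if fwd is not None:
            hits.append(
                HBoxHit(contig, p - 3, p + 9, "+", padded_12mer(p), fwd)
            )
        rev = core_at(p, "-")
        if rev is not None:
            if fwd is not None and _revcomp(fwd) == fwd:
                continue  # palindromic core: already reported on +
            hits.append(
                HBoxHit(contig, p - 3, p + 9, "-", _revcomp(padded_12mer(p)), rev)
            )
    return hits


# -- file format helpers -------------------------------------------------

def read_binding_tsv(path) -> list[BindingSeries]:
    """Read binding series from TSV with columns probe_id, free, bound
    (and optionally group): one row per titration point."""
    df = pd.read_csv(path, sep="\t")
    required = {"probe_id", "free", "bound"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: binding TSV needs columns {sorted(required)}")
    out = []
    for probe, sub in df.groupby("probe_id", sort=False):
        group = str(sub["group"].iloc[0]) if "group" in sub.columns else ""
        out.append(
            BindingSeries(
                probe_id=str(probe),
                free_signal=tuple(sub["free"].astype(float)),
                bound_signal=tuple(sub["bound"].astype(float)),
                group=group,
            )
        )
    return out


def write_affinity_tsv(affinities: Iterable[RelativeAffinity], path) -> None:
    pd.DataFrame([vars(a) for a in affinities]).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def write_bed(hits: Iterable[HBoxHit], path, scores: dict[str, float] | None = None) -> None:
    """Write hits as BED6: contig, start, end, twelve_mer, score, strand.
    The score is the known normalized affinity of the 12-mer times 1000
    when provided, else 0."""
    with open(path, "w") as fh:
        for h in hits:
            score = int(round(1000 * scores.get(h.twelve_mer, 0.0))) if scores else 0
            fh.write(
                f"{h.contig}\t{h.start}\t{h.end}\t{h.twelve_mer}\t{score}\t{h.strand}\n"
            )


def read_fasta(path) -> list:
    """All records of a FASTA file (Biopython SeqRecords)."""
    return list(SeqIO.parse(str(path), "fasta"))
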