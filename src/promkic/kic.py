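"""Kappa index of coincidence and C+G content — the two pattern coordinates.

The Kappa index of coincidence (Kappa IC) is a cryptanalytic
letter-coincidence statistic adapted here to a single DNA sequence: the
sequence is compared against every one of its own shifted suffixes, and
the percentage of coinciding positions is averaged over all shifts.
For a sequence A of length L:

    KIC(A) = round( mean_{u=1..L-1} 100 * |{i : A[i] = A[i+u]}| / (L - u), 2 )

Homopolymers score 100; a sequence with no position equal at any shift
scores 0; i.i.d. equiprobable DNA scores ~25 (match probability 1/4).
The statistic is sensitive to simple sequence repeats, short tandem
repeats and homopolymer tracts, which is what makes it useful as a
promoter-pattern coordinate.

The companion x-coordinate is the sliding-window C+G percentage CG_SW,
by default rescaled relative to the whole segment's C+G percentage
CG_TOT:

    CG_TOT = 100 * (C+G)_TOT / (A+T+C+G)_TOT
    CG_SW  = CG_TOT * (C+G)_SW / (A+T+C+G)_SW      (relative mode)

so that relative CG_SW never exceeds CG_TOT.  Ambiguous bases (N) never
count as a coincidence and enter neither the C+G nor the A+T tallies,
but do occupy window positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqio import PromoterSequence, SlidingWindowConfig

_N_CODE = ord("N")


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def kappa_ic(seq: str) -> float:
    """Kappa index of coincidence of one sequence, as a percentage.

    Averages, over every shift u = 1..L-1, the percentage of positions
    at which the sequence coincides with its own suffix starting at u,
    and rounds the result to two decimals.  N matches nothing,
    including another N.

    >>> kappa_ic("AAAA")
    100.0
    >>> kappa_ic("ACGT")
    0.0
    """
    a = _encode(seq)
    L = a.size
    if L < 2:
        raise ValueError("kappa_ic requires a sequence of length >= 2")
    not_n = a != _N_CODE
    total = 0.0
    for u in range(1, L):
        eq = (a[: L - u] == a[u:]) & not_n[: L - u]
        total += 100.0 * eq.sum() / (L - u)
    return float(np.round(total / (L - 1), 2))


@dataclass(frozen=True)
class SequenceComposition:
    """Base counts and the whole-sequence C+G percentage (CG_TOT)."""

    count_a: int
    count_t: int
    count_c: int
    count_g: int
    count_n: int
    length: int
    cg_total: float

    @property
    def acgt(self) -> int:
        return self.count_a + self.count_t + self.count_c + self.count_g


def cg_total(seq: str | PromoterSequence) -> SequenceComposition:
    """Whole-sequence composition; CG_TOT = 100 * (C+G) / (A+T+C+G)."""
    s = seq.sequence if isinstance(seq, PromoterSequence) else seq
    if not s:
        raise ValueError("cannot compute composition of an empty sequence")
    counts = {b: s.count(b) for b in "ATCGN"}
    acgt = counts["A"] + counts["T"] + counts["C"] + counts["G"]
    if acgt == 0:
        raise ValueError("composition undefined: sequence contains only N")
    cg = 100.0 * (counts["C"] + counts["G"]) / acgt
    return SequenceComposition(
        count_a=counts["A"],
        count_t=counts["T"],
        count_c=counts["C"],
        count_g=counts["G"],
        count_n=counts["N"],
        length=len(s),
        cg_total=cg,
    )


def cg_window(window: str, cg_tot: float, relative: bool = True) -> float:
    """Sliding-window C+G value CG_SW.

    Relative mode rescales the window's C+G share by CG_TOT; absolute
    mode is the plain window percentage.  A window of only N yields 0.
    """
    if not window:
        raise ValueError("window must be non-empty")
    if not 0.0 <= cg_tot <= 100.0:
        raise ValueError("cg_tot must lie in [0, 100]")
    cg = window.count("C") + window.count("G")
    acgt = len(window) - window.count("N")
    if acgt == 0:
        return 0.0
    scale = cg_tot if relative else 100.0
    return scale * cg / acgt


@dataclass(frozen=True)
class WindowMeasurement:
    """One (CG_SW, Kappa IC) point from one sliding window."""

    window_start: int
    cg_value: float
    kic_value: float


def profile(
    seq: PromoterSequence | str, cfg: SlidingWindowConfig | None = None
) -> list[WindowMeasurement]:
    """All (CG_SW, Kappa IC) measurements of a sequence, 5'->3'.

    Equivalent to calling :func:`kappa_ic` and :func:`cg_window` on
    every window, but computed with shared shift comparisons across
    overlapping windows so that whole promoter collections profile
    quickly.
    """
    cfg = cfg or SlidingWindowConfig()
    s = seq.sequence if isinstance(seq, PromoterSequence) else seq
    n = cfg.n_windows(len(s))
    w, step = cfg.window_size, cfg.step
    a = _encode(s)
    not_n = a != _N_CODE

    starts = np.arange(n) * step

    # KIC: for each shift u, eq_u[j] = (a[j] == a[j+u], j not N); the
    # match count of the window at s is a width-(w-u) sliding sum of eq_u.
    kic = np.zeros(n)
    for u in range(1, w):
        eq = ((a[: a.size - u] == a[u:]) & not_n[: a.size - u]).astype(np.int64)
        csum = np.concatenate(([0], np.cumsum(eq)))
        matches = csum[starts + (w - u)] - csum[starts]
        kic += 100.0 * matches / (w - u)
    kic = np.round(kic / (w - 1), 2)

    is_cg = (a == ord("C")) | (a == ord("G"))
    is_n = ~not_n
    cg_csum = np.concatenate(([0], np.cumsum(is_cg.astype(np.int64))))
    n_csum = np.concatenate(([0], np.cumsum(is_n.astype(np.int64))))
    cg_counts = cg_csum[starts + w] - cg_csum[starts]
    acgt_counts = w - (n_csum[starts + w] - n_csum[starts])

    comp = cg_total(s)
    scale = comp.cg_total if cfg.relative_cg else 100.0
    with np.errstate(invalid="ignore"):
        cg_vals = np.where(
            acgt_counts > 0, scale * cg_counts / np.maximum(acgt_counts, 1), 0.0
        )

    return [
        WindowMeasurement(int(st), float(cv), float(kv))
        for st, cv, kv in zip(starts, cg_vals, kic)
    ]
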