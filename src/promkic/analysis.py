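"""Aggregate analyses over promoter pattern collections.

Density maps bin pattern centers of weight over the (CG%, Kappa IC)
plane — one dot per promoter — and their pairwise overlap quantifies
how much two groups (species, tissues) occupy the same region of
pattern space.  Proportion tables, expected-vs-observed comparisons and
pairwise class correlations support tissue-specificity analyses, and a
small IUPAC scanner decides TATA-containing vs TATA-less promoters.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_values

from .seqio import DEFAULT_TSS_OFFSET, PromoterSequence


@dataclass(frozen=True)
class DensityMap:
    """Counts of pattern centers over a [0,100]^2 grid of square bins.

    Bins are half-open [lo, hi); a center sitting exactly on an edge
    belongs to the higher bin, and 100.0 falls in the last bin.
    """

    grid: np.ndarray
    bin_size: float
    group: str

    @property
    def total(self) -> int:
        return int(self.grid.sum())


def density_map(
    centers: list[tuple[float, float]], bin_size: float = 1.0, group: str = ""
) -> DensityMap:
    if not centers:
        raise ValueError("density_map needs at least one center")
    arr = np.asarray(centers, dtype=float)
    if ((arr < 0) | (arr > 100)).any():
        raise ValueError("centers must lie within [0, 100]^2")
    n_bins = int(np.ceil(100.0 / bin_size))
    idx = np.floor(arr / bin_size).astype(int)
    idx = np.minimum(idx, n_bins - 1)  # 100.0 goes in the top bin
    grid = np.zeros((n_bins, n_bins), dtype=np.int64)
    np.add.at(grid, (idx[:, 0], idx[:, 1]), 1)
    return DensityMap(grid=grid, bin_size=bin_size, group=group)


def overlap(a: DensityMap, b: DensityMap) -> float:
    """Shared mass of two normalized density maps: sum of bin-wise minima.

    Equals 1 - total-variation distance between the normalized maps;
    1 iff the normalized maps coincide, 0 iff their supports are
    disjoint.  Symmetric.
    """
    if a.grid.shape != b.grid.shape or a.bin_size != b.bin_size:
        raise ValueError("density maps use different binnings")
    pa = a.grid / a.grid.sum()
    pb = b.grid / b.grid.sum()
    return float(np.minimum(pa, pb).sum())


def class_proportions(
    labels: dict[str, str], groups: dict[str, str] | None = None
) -> pd.DataFrame:
    """Per-group class percentages; rows sum to 100.

    ``labels`` maps sequence id -> class label, ``groups`` maps id ->
    group name (species or tissue); ids without a group are pooled
    under "ungrouped".  The transposed view (per-class distribution
    over groups) is just ``table.T`` renormalized; see
    :func:`group_distribution_per_class`.
    """
    groups = groups or {}
    rows = [
        {"group": groups.get(sid, "ungrouped"), "label": lab}
        for sid, lab in labels.items()
    ]
    df = pd.DataFrame(rows)
    counts = df.groupby(["group", "label"]).size().unstack(fill_value=0)
    return counts.div(counts.sum(axis=1), axis=0) * 100.0


def group_distribution_per_class(
    labels: dict[str, str], groups: dict[str, str] | None = None
) -> pd.DataFrame:
    """Transposed view: for each class, its percentage split over groups."""
    groups = groups or {}
    rows = [
        {"group": groups.get(sid, "ungrouped"), "label": lab}
        for sid, lab in labels.items()
    ]
    df = pd.DataFrame(rows)
    counts = df.groupby(["label", "group"]).size().unstack(fill_value=0)
    return counts.div(counts.sum(axis=1), axis=0) * 100.0


def expected_observed(
    reference_freqs: dict[str, float], subset_labels: list[str]
) -> pd.DataFrame:
    """Expected vs observed class percentages with observed/expected ratios.

    ``reference_freqs`` are the class shares (percent, summing to 100)
    in the reference promoter population; the observed shares come from
    the subset.  A class missing from the subset gets ratio 0 and is
    flagged ``absent``; ratios far from 1 suggest enrichment or
    silencing of the class's genes in the subset.
    """
    if not subset_labels:
        raise ValueError("subset is empty")
    total_ref = sum(reference_freqs.values())
    if not np.isclose(total_ref, 100.0, atol=0.5):
        raise ValueError(f"reference frequencies sum to {total_ref}, not 100")
    n = len(subset_labels)
    obs = {
        lab: 100.0 * subset_labels.count(lab) / n for lab in reference_freqs
    }
    rows = []
    for lab, exp in reference_freqs.items():
        o = obs[lab]
        ratio = o / exp if exp > 0 else np.nan
        rows.append(
            {
                "class": lab,
                "expected_pct": exp,
                "observed_pct": o,
                "ratio": ratio,
                "absent": o == 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("class")


def pairwise_relation(
    table: pd.DataFrame,
    class_a: str,
    class_b: str,
    threshold: float = 0.5,
) -> tuple[float, str]:
    """Pearson correlation of two class columns across groups, with a tag.

    Tags "complementary" (r <= -threshold: the classes trade off across
    groups), "proportional" (r >= threshold), else "none".  A
    zero-variance column makes the correlation undefined (nan, tag
    "undefined").
    """
    if len(table) < 3:
        raise ValueError("need at least 3 groups to correlate")
    a = table[class_a].to_numpy(dtype=float)
    b = table[class_b].to_numpy(dtype=float)
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan"), "undefined"
    r = float(np.corrcoef(a, b)[0, 1])
    if r <= -threshold:
        return r, "complementary"
    if r >= threshold:
        return r, "proportional"
    return r, "none"


def save_density_image(dmap: DensityMap, path) -> None:
    """Write a density map as a grayscale image (denser bins darker).

    Rows are flipped so high Kappa IC sits at the top, matching how
    pattern distributions are drawn.
    """
    from PIL import Image

    grid = dmap.grid.T[::-1].astype(float)  # rows = KIC (top high), cols = CG
    peak = grid.max() if grid.max() > 0 else 1.0
    img = (255 * (1.0 - grid / peak)).astype(np.uint8)
    Image.fromarray(img, mode="L").save(str(path))


@dataclass(frozen=True)
class TataScanResult:
    sequence_id: str
    hits: tuple[tuple[int, str], ...]  # (0-based absolute position, word)
    tata_containing: bool


def _iupac_regex(motif: str) -> re.Pattern[str]:
    parts = []
    for c in motif.upper():
        if c not in ambiguous_dna_values:
            raise ValueError(f"{c!r} is not an IUPAC nucleotide code")
        opts = ambiguous_dna_values[c]
        parts.append(c if len(opts) == 1 else f"[{opts}]")
    return re.compile("".join(parts))


def scan_tata(
    seq: PromoterSequence,
    motif: str = "TATAWAW",
    region: tuple[int, int] = (-40, -19),
) -> TataScanResult:
    """Scan for an IUPAC consensus in a TSS-relative region (forward strand).

    ``region`` is an inclusive interval of TSS-relative coordinates; a
    hit must lie entirely inside it.  Default TATAWAW in -40..-19
    covers the canonical core-promoter TATA-box placement.
    """
    tss = seq.tss_offset if seq.tss_offset is not None else DEFAULT_TSS_OFFSET
    lo = tss + region[0]
    hi = tss + region[1]
    if lo < 0 or hi >= len(seq.sequence):
        raise ValueError(
            f"region {region} relative to TSS at {tss} falls outside the "
            f"{len(seq.sequence)} nt sequence"
        )
    pat = _iupac_regex(motif)
    hits = []
    # the full match must end at or before the region's right edge
    segment = seq.sequence[lo : hi + 1]
    for i in range(len(segment) - len(motif) + 1):
        if pat.fullmatch(segment, i, i + len(motif)):
            hits.append((lo + i, segment[i : i + len(motif)]))
    return TataScanResult(
        sequence_id=seq.id,
        hits=tuple(hits),
        tata_containing=bool(hits),
    )
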