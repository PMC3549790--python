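"""Class-conditional synthetic promoter generator and mutation simulator.

Real promoter collections fall into ten pattern archetypes that differ
in base composition and in how simple sequence repeats — above all
homopolymer tracts — are laid out: AT- or CG-dominated backgrounds
studded with short (3-8 nt) tracts, long (>=30 nt) spike tracts near
the TSS, tandem blocks of mixed short tracts, abrupt local depletions
of one base pair, or alternating C+G composition levels.  Each
:class:`ClassRecipe` realizes one archetype as a seeded generative
model over 600 nt segments (TSS at offset 500, the -499..+100
convention), so that every downstream stage — profiling, pattern
building, classification, aggregation — can run on data whose class
labels are known by construction.

The quantitative defaults (background A+T fractions, tract counts,
3-8 nt short / 30-60 nt long tract lengths, 30-60 nt depletion blocks
within +/-200 nt of the TSS) are this package's concrete instantiation
of the qualitative class architectures; docs/methods.md tabulates them.

A uniform substitution mutator supports robustness experiments: at low
per-site rates the pattern of a promoter barely moves, while different
classes stay far apart.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import groupby

import numpy as np

from .seqio import PromoterSequence

_BASES = "ACGT"


@dataclass(frozen=True)
class DepletionBlock:
    """A contiguous block overwritten with tandem short tracts.

    ``bases`` is the tract alphabet ("AT" writes a CG-depleted block).
    The block is placed so it lies within ``offset_range`` relative to
    the TSS.
    """

    bases: str
    length_range: tuple[int, int] = (30, 60)
    offset_range: tuple[int, int] = (-200, 200)


@dataclass(frozen=True)
class ClassRecipe:
    """Generative parameters for one promoter class.

    ``short_tracts`` is a tuple of (count, alphabet) groups; each tract
    picks one base from its alphabet and a length from
    ``short_tract_len``.  ``tandem_tracts`` short tracts are laid down
    back-to-back as one central block.  ``composition_blocks`` replaces
    the homogeneous background with alternating (at_fraction, length)
    blocks.
    """

    label: str
    length: int = 600
    tss_offset: int = 500
    at_fraction: float = 0.5
    short_tracts: tuple[tuple[int, str], ...] = ()
    short_tract_len: tuple[int, int] = (3, 8)
    n_long_tracts: int = 0
    long_tract_bases: str = ""
    long_tract_len: tuple[int, int] = (30, 60)
    long_tract_offset: tuple[int, int] = (-200, 200)
    tandem_tracts: int = 0
    tandem_bases: str = _BASES
    tandem_tract_len: tuple[int, int] | None = None  # defaults to short_tract_len
    composition_blocks: tuple[tuple[float, int], ...] = ()
    depletion_blocks: tuple[DepletionBlock, ...] = ()


_RECIPES: dict[str, ClassRecipe] = {
    # AT-rich background, many short poly(dA)/poly(dT) tracts
    "AT_based": ClassRecipe(
        label="AT_based", at_fraction=0.65, short_tracts=((20, "AT"),)
    ),
    # CG-rich background, many short poly(dC)/poly(dG) tracts
    "CG_based": ClassRecipe(
        label="CG_based", at_fraction=0.35, short_tracts=((20, "CG"),)
    ),
    # evenly interspersed background (A,T,C,G ~ 25%) + a central tandem
    # block of mixed short tracts; no scattered tracts, so the cloud
    # stays round and centrally disposed
    "ATCG_compact": ClassRecipe(
        label="ATCG_compact",
        at_fraction=0.5,
        tandem_tracts=6,
    ),
    # balanced composition, equally distributed scattered short AT and
    # CG tracts, no tandem block
    "ATCG_balanced": ClassRecipe(
        label="ATCG_balanced",
        at_fraction=0.5,
        short_tracts=((12, "AT"), (12, "CG")),
        short_tract_len=(5, 12),
    ),
    # balanced + a heavy extra load of tandem short tracts of all four
    # bases: pronounced central part, higher-than-average Kappa IC
    "ATCG_middle": ClassRecipe(
        label="ATCG_middle",
        at_fraction=0.5,
        short_tracts=((2, "AT"), (2, "CG")),
        tandem_tracts=28,
        tandem_tract_len=(8, 16),
    ),
    # two alternating C+G composition levels, no tract blocks
    "ATCG_less": ClassRecipe(
        label="ATCG_less",
        composition_blocks=((0.65, 60), (0.35, 60)),
    ),
    # many short CG tracts, few AT tracts, one CG-depleted block near TSS
    "AT_less": ClassRecipe(
        label="AT_less",
        at_fraction=0.45,
        short_tracts=((16, "CG"), (4, "AT")),
        depletion_blocks=(DepletionBlock(bases="AT"),),
    ),
    # mirror of AT_less
    "CG_less": ClassRecipe(
        label="CG_less",
        at_fraction=0.55,
        short_tracts=((16, "AT"), (4, "CG")),
        depletion_blocks=(DepletionBlock(bases="CG"),),
    ),
    # >=30 nt poly(dA) or poly(dT) spike near the TSS
    "AT_spike": ClassRecipe(
        label="AT_spike",
        at_fraction=0.55,
        short_tracts=((6, "AT"),),
        n_long_tracts=1,
        long_tract_bases="AT",
    ),
    # mirror of AT_spike
    "CG_spike": ClassRecipe(
        label="CG_spike",
        at_fraction=0.45,
        short_tracts=((6, "CG"),),
        n_long_tracts=1,
        long_tract_bases="CG",
    ),
}


def default_recipe(label: str) -> ClassRecipe:
    """The documented default recipe for one of the ten class labels."""
    try:
        return _RECIPES[label]
    except KeyError:
        raise ValueError(
            f"unknown class label {label!r}; expected one of "
            f"{', '.join(_RECIPES)}"
        ) from None


def _background(recipe: ClassRecipe, rng: np.random.Generator) -> np.ndarray:
    def block(at: float, n: int) -> np.ndarray:
        p = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])  # A C G T
        return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n, p=p)

    if not recipe.composition_blocks:
        return block(recipe.at_fraction, recipe.length)
    parts = []
    total = 0
    i = 0
    while total < recipe.length:
        at, n = recipe.composition_blocks[i % len(recipe.composition_blocks)]
        parts.append(block(at, min(n, recipe.length - total)))
        total += n
        i += 1
    return np.concatenate(parts)[: recipe.length]


def _tandem_run(
    bases: str, n_tracts: int, lens: tuple[int, int], rng: np.random.Generator
) -> np.ndarray:
    # balanced multiset of tract bases, shuffled: tracts come "in any
    # order" but the block's composition stays near its target
    picks = list(bases) * (n_tracts // len(bases) + 1)
    order = rng.permutation(n_tracts)
    tracts = []
    for k in order:
        b = picks[int(k)]
        tracts.append(
            np.full(int(rng.integers(lens[0], lens[1] + 1)), ord(b), np.uint8)
        )
    return np.concatenate(tracts)


def _place(
    occupied: list[tuple[int, int]],
    length: int,
    lo: int,
    hi: int,
    rng: np.random.Generator,
    attempts: int = 1000,
) -> int:
    """A start in [lo, hi] whose [start, start+length) avoids occupied spans."""
    if hi < lo:
        raise ValueError("element does not fit in the sequence: recipe infeasible")
    for _ in range(attempts):
        start = int(rng.integers(lo, hi + 1))
        if all(start + length <= s or start >= e for s, e in occupied):
            occupied.append((start, start + length))
            return start
    raise ValueError(
        "could not place a structural element without overlap: "
        "tract budget too large for the sequence length"
    )


def generate(recipe: ClassRecipe, seed: int = 0) -> PromoterSequence:
    """Draw one promoter sequence from a class recipe, deterministically."""
    rng = np.random.default_rng(seed)
    arr = _background(recipe, rng)
    L = recipe.length
    tss = recipe.tss_offset
    occupied: list[tuple[int, int]] = []

    for blk in recipe.depletion_blocks:
        run = _tandem_run(
            blk.bases,
            max(1, blk.length_range[1] // recipe.short_tract_len[0]),
            recipe.short_tract_len,
            rng,
        )[: int(rng.integers(blk.length_range[0], blk.length_range[1] + 1))]
        lo = max(0, tss + blk.offset_range[0])
        hi = min(L - run.size, tss + blk.offset_range[1] - run.size)
        start = _place(occupied, run.size, lo, hi, rng)
        arr[start : start + run.size] = run

    for _ in range(recipe.n_long_tracts):
        n = int(rng.integers(recipe.long_tract_len[0], recipe.long_tract_len[1] + 1))
        b = recipe.long_tract_bases[rng.integers(len(recipe.long_tract_bases))]
        lo = max(0, tss + recipe.long_tract_offset[0])
        hi = min(L - n, tss + recipe.long_tract_offset[1] - n)
        start = _place(occupied, n, lo, hi, rng)
        arr[start : start + n] = ord(b)

    if recipe.tandem_tracts:
        run = _tandem_run(
            recipe.tandem_bases,
            recipe.tandem_tracts,
            recipe.tandem_tract_len or recipe.short_tract_len,
            rng,
        )
        # central block: keep it within the middle two thirds
        lo, hi = L // 6, L - L // 6 - run.size
        start = _place(occupied, run.size, lo, hi, rng)
        arr[start : start + run.size] = run

    for count, alphabet in recipe.short_tracts:
        for _ in range(count):
            n = int(
                rng.integers(recipe.short_tract_len[0], recipe.short_tract_len[1] + 1)
            )
            b = alphabet[rng.integers(len(alphabet))]
            start = _place(occupied, n, 0, L - n, rng)
            arr[start : start + n] = ord(b)

    return PromoterSequence(
        id=f"{recipe.label}_s{seed}",
        sequence=arr.tobytes().decode("ascii"),
        tss_offset=tss,
    )


def make_fixture_set(
    n_per_class: int, seed: int = 0
) -> list[tuple[PromoterSequence, str]]:
    """A balanced labeled collection: n_per_class sequences per class.

    Per-sequence seeds are derived from the master seed so different
    masters give disjoint, reproducible sets.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(10 * n_per_class) % (2**31)
    out = []
    k = 0
    for label in _RECIPES:
        recipe = default_recipe(label)
        for j in range(n_per_class):
            s = generate(recipe, seed=int(child_seeds[k]))
            out.append(
                (
                    PromoterSequence(
                        id=f"{label}_{seed}_{j:03d}",
                        sequence=s.sequence,
                        tss_offset=s.tss_offset,
                    ),
                    label,
                )
            )
            k += 1
    return out


@dataclass(frozen=True)
class MutationSpec:
    """Uniform per-site substitution; replacements never keep the base."""

    rate: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError("mutation rate must lie in [0, 1]")


def mutate(seq: PromoterSequence, spec: MutationSpec) -> PromoterSequence:
    """Substitute each site independently with probability ``spec.rate``."""
    rng = np.random.default_rng(spec.seed)
    arr = np.frombuffer(seq.sequence.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < spec.rate
    for i in np.flatnonzero(hit):
        current = chr(arr[i])
        choices = [b for b in _BASES if b != current]
        arr[i] = ord(choices[rng.integers(len(choices))])
    return PromoterSequence(
        id=f"{seq.id}_mut",
        sequence=arr.tobytes().decode("ascii"),
        species=seq.species,
        tissue=seq.tissue,
        tss_offset=seq.tss_offset,
    )


# ---------------------------------------------------------------------------
# structural audit: an independent scanner over the generated sequence,
# deliberately not reusing the generator's bookkeeping


def _runs(seq: str) -> list[tuple[str, int]]:
    return [(b, len(list(g))) for b, g in groupby(seq)]


def max_run_length(seq: str, bases: str) -> int:
    """Longest homopolymer run of any single base drawn from ``bases``."""
    return max((n for b, n in _runs(seq) if b in bases), default=0)


def expected_at_fraction(recipe: ClassRecipe) -> float:
    """Analytic overall A+T fraction implied by a recipe."""

    def at_share(alphabet: str) -> float:
        return sum(1 for b in alphabet if b in "AT") / len(alphabet)

    mean_short = sum(recipe.short_tract_len) / 2
    mean_long = sum(recipe.long_tract_len) / 2
    covered = 0.0
    at_mass = 0.0
    for count, alphabet in recipe.short_tracts:
        span = count * mean_short
        covered += span
        at_mass += span * at_share(alphabet)
    span = recipe.n_long_tracts * mean_long
    covered += span
    at_mass += span * at_share(recipe.long_tract_bases or "AT") if span else 0.0
    mean_tandem = sum(recipe.tandem_tract_len or recipe.short_tract_len) / 2
    span = recipe.tandem_tracts * mean_tandem
    covered += span
    at_mass += span * at_share(recipe.tandem_bases)
    for blk in recipe.depletion_blocks:
        span = sum(blk.length_range) / 2
        covered += span
        at_mass += span * at_share(blk.bases)
    if recipe.composition_blocks:
        bg_at = float(np.mean([at for at, _ in recipe.composition_blocks]))
    else:
        bg_at = recipe.at_fraction
    at_mass += (recipe.length - covered) * bg_at
    return at_mass / recipe.length


def audit_sequence(seq: PromoterSequence, recipe: ClassRecipe) -> list[str]:
    """Check a generated sequence against its recipe's structural claims.

    Returns a list of human-readable failures (empty = pass).
    """
    failures: list[str] = []
    s = seq.sequence
    if len(s) != recipe.length:
        failures.append(f"length {len(s)} != {recipe.length}")

    if recipe.n_long_tracts:
        need = recipe.long_tract_len[0]
        got = max_run_length(s, recipe.long_tract_bases)
        if got < need:
            failures.append(
                f"longest {recipe.long_tract_bases} run {got} < {need}"
            )

    for blk in recipe.depletion_blocks:
        lo = max(0, recipe.tss_offset + blk.offset_range[0])
        hi = min(len(s), recipe.tss_offset + blk.offset_range[1])
        region = s[lo:hi]
        wlen = blk.length_range[0]
        found = any(
            sum(1 for c in region[i : i + wlen] if c in blk.bases) / wlen >= 0.9
            for i in range(max(0, len(region) - wlen + 1))
        )
        if not found:
            failures.append(
                f"no {wlen} nt {blk.bases}-dominated block within "
                f"{blk.offset_range} of the TSS"
            )

    at_obs = sum(1 for c in s if c in "AT") / len(s)
    at_exp = expected_at_fraction(recipe)
    if abs(at_obs - at_exp) > 0.05:
        failures.append(
            f"A+T fraction {at_obs:.3f} deviates from expected {at_exp:.3f} "
            "by more than 5 points"
        )
    return failures
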