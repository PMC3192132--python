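"""Enrichment statistics: Fisher's exact test, the A->G composition shift,
and the random-position permutation test for duplication-polymorphism overlap.

`fisher_exact` is computed with exact integer arithmetic over the
hypergeometric support (two-sided by probability ordering), so it agrees with
full enumeration bit-for-bit at desk scale.
"""

from __future__ import annotations

import dataclasses
import math
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np

from .io import Interval
from .paralog import ParalogHit


@dataclasses.dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("at least one count must be positive")


def fisher_exact(table: ContingencyTable2x2, sidedness: str = "two-sided") -> float:
    """Exact hypergeometric p-value for a 2x2 table.

    Two-sided p sums the probabilities of all tables with the observed margins
    whose probability does not exceed the observed table's (probability
    ordering).  Degenerate margins give p = 1.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    weights = {x: math.comb(r1, x) * math.comb(r2, c1 - x) for x in range(lo, hi + 1)}
    total = sum(weights.values())
    obs = weights[a]
    if sidedness == "greater":
        tail = sum(w for x, w in weights.items() if x >= a)
    elif sidedness == "less":
        tail = sum(w for x, w in weights.items() if x <= a)
    elif sidedness == "two-sided":
        tail = sum(w for w in weights.values() if w <= obs)
    else:
        raise ValueError(f"unknown sidedness {sidedness!r}")
    return float(Fraction(tail, total))


@dataclasses.dataclass(frozen=True)
class AgShiftResult:
    n_sites: int
    n_explained: int
    frac_ag_all: float
    frac_ag_retained: float
    table: ContingencyTable2x2 | None
    p_value: float


def ag_shift_test(
    substitutions: Mapping[str, str],
    explained: Mapping[str, bool],
) -> AgShiftResult:
    """A->G fraction among all sites vs sites retained after removing explained
    ones, with a Fisher test on (explained vs retained) x (A->G vs other).

    ``substitutions`` maps site_id to "X>Y" on the transcript strand.
    """
    sids = list(substitutions)
    is_ag = {s: substitutions[s] == "A>G" for s in sids}
    n = len(sids)
    n_ag = sum(is_ag.values())
    retained = [s for s in sids if not explained.get(s, False)]
    removed = [s for s in sids if explained.get(s, False)]
    if n == 0 or n_ag == 0:
        return AgShiftResult(n, len(removed), 0.0, 0.0, None, 1.0)
    ag_retained = sum(is_ag[s] for s in retained)
    ag_removed = n_ag - ag_retained
    table = ContingencyTable2x2(
        a=ag_removed, b=len(removed) - ag_removed,
        c=ag_retained, d=len(retained) - ag_retained,
    )
    return AgShiftResult(
        n_sites=n,
        n_explained=len(removed),
        frac_ag_all=n_ag / n,
        frac_ag_retained=ag_retained / len(retained) if retained else 0.0,
        table=table,
        p_value=fisher_exact(table),
    )


@dataclasses.dataclass(frozen=True)
class PermutationResult:
    observed: int
    null_counts: tuple[int, ...]
    fold: float | None  # None when the null mean is 0 or intervals are empty
    p_value: float      # (1 + #{null >= observed}) / (1 + replicates)
    replicates: int
    seed: int


def cnv_permutation(
    positions_by_site: Mapping[str, Sequence[tuple[str, int]]],
    intervals: Sequence[Interval],
    genome_sizes: Mapping[str, int],
    replicates: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Overlap of sites (or any of their paralog positions) with duplication
    intervals, against a null that redraws every position uniformly over the
    genome (length-weighted across sequences).

    Each site counts once however many of its positions overlap.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    chroms = sorted(genome_sizes)
    sizes = np.array([genome_sizes[c] for c in chroms], dtype=np.int64)
    offsets = np.concatenate(([0], np.cumsum(sizes)))
    total_len = int(offsets[-1])
    chrom_index = {c: i for i, c in enumerate(chroms)}

    # merged intervals in concatenated coordinates
    pairs = sorted(
        (offsets[chrom_index[iv.chrom]] + iv.start, offsets[chrom_index[iv.chrom]] + iv.end)
        for iv in intervals
        if iv.chrom in chrom_index
    )
    merged: list[list[int]] = []
    for s, e in pairs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    starts = np.array([m[0] for m in merged], dtype=np.int64)
    ends = np.array([m[1] for m in merged], dtype=np.int64)

    def member(flat_pos: np.ndarray) -> np.ndarray:
        if len(starts) == 0:
            return np.zeros(flat_pos.shape, dtype=bool)
        i = np.searchsorted(starts, flat_pos, side="right") - 1
        return (i >= 0) & (flat_pos < ends[np.clip(i, 0, None)])

    site_ids = sorted(positions_by_site)
    flat: list[int] = []
    group_start = [0]
    for sid in site_ids:
        for chrom, pos0 in positions_by_site[sid]:
            if chrom not in chrom_index:
                raise ValueError(f"position on unknown sequence {chrom!r}")
            flat.append(int(offsets[chrom_index[chrom]]) + pos0)
        group_start.append(len(flat))
    flat_arr = np.array(flat, dtype=np.int64)
    boundaries = np.array(group_start[:-1], dtype=np.int64)

    def count_sites(hits: np.ndarray) -> int:
        if len(hits) == 0:
            return 0
        return int(np.maximum.reduceat(hits.astype(np.uint8), boundaries).sum())

    observed = count_sites(member(flat_arr))

    null_counts = np.empty(replicates, dtype=np.int64)
    for r in range(replicates):
        draws = rng.integers(0, total_len, size=len(flat_arr))
        null_counts[r] = count_sites(member(draws))

    mean_null = float(null_counts.mean()) if len(flat_arr) else 0.0
    fold = observed / mean_null if (len(starts) and mean_null > 0) else None
    p = (1 + int(np.sum(null_counts >= observed))) / (1 + replicates)
    return PermutationResult(
        observed=observed,
        null_counts=tuple(int(x) for x in null_counts),
        fold=fold,
        p_value=p,
        replicates=replicates,
        seed=seed,
    )


def site_paralog_positions(
    sites: Sequence,
    hits: Sequence[ParalogHit],
    exclude: Sequence[str] = (),
) -> dict[str, list[tuple[str, int]]]:
    """Site position plus every paralog-hit RDD-column position, per site."""
    skip = set(exclude)
    out: dict[str, list[tuple[str, int]]] = {}
    for s in sites:
        if s.site_id in skip:
            continue
        out[s.site_id] = [(s.chrom, s.pos - 1)]
    for h in hits:
        if h.site_id in out and h.rdd_column_pos is not None:
            out[h.site_id].append((h.chrom, h.rdd_column_pos))
    return out
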