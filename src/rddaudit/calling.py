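"""RDD calling from RNA pileups: the three published thresholds.

A site is called in an individual when
  1) at least ``min_reads`` RNA reads cover the site,
  2) at least 90% of those reads show nucleotide A or B,
  3) at least 10% of the A/B reads show B.

All thresholds are inclusive and evaluated with exact rational arithmetic so
boundary cases (10% of 10 reads) are never lost to floating point.
"""

from __future__ import annotations

import dataclasses
from fractions import Fraction
from typing import Iterable, Mapping

from .align import SitePileup
from .io import RddSite


@dataclasses.dataclass(frozen=True)
class CallThresholds:
    min_reads: int = 10
    min_ab_fraction: Fraction = Fraction(9, 10)
    min_b_fraction: Fraction = Fraction(1, 10)


DEFAULT_THRESHOLDS = CallThresholds()


@dataclasses.dataclass(frozen=True, slots=True)
class RddCall:
    site_id: str
    individual: str
    total: int
    n_A: int
    n_B: int
    called: bool


def call_rdd(
    pile: SitePileup,
    site: RddSite,
    thresholds: CallThresholds = DEFAULT_THRESHOLDS,
) -> RddCall:
    """Apply the three criteria to one RNA pileup."""
    if pile.source != "RNA":
        raise ValueError(f"call_rdd expects an RNA pileup, got {pile.source!r}")
    n_a, n_b, _n_other = pile.abo(site.ref_nt, site.rdd_nt)
    total = pile.total
    called = (
        total >= thresholds.min_reads
        and Fraction(n_a + n_b, total) >= thresholds.min_ab_fraction
        and n_a + n_b > 0
        and Fraction(n_b, n_a + n_b) >= thresholds.min_b_fraction
    )
    return RddCall(pile.site_id, pile.individual, total, n_a, n_b, called)


def call_cohort(
    pileups: Mapping[tuple[str, str], SitePileup],
    sites: Iterable[RddSite],
    individuals: Iterable[str],
    thresholds: CallThresholds = DEFAULT_THRESHOLDS,
) -> tuple[list[RddCall], dict[str, int], dict[str, set[str]]]:
    """Calls for every (site, individual), the per-individual event counts, and
    per-site carrier sets.

    Pairs absent from ``pileups`` are treated as zero-coverage (never called).
    """
    site_list = list(sites)
    calls: list[RddCall] = []
    per_individual: dict[str, int] = {ind: 0 for ind in individuals}
    carriers: dict[str, set[str]] = {s.site_id: set() for s in site_list}
    for site in site_list:
        for ind in per_individual:
            pile = pileups.get((site.site_id, ind))
            if pile is None:
                pile = SitePileup(site.site_id, ind, "RNA")
            call = call_rdd(pile, site, thresholds)
            calls.append(call)
            if call.called:
                per_individual[ind] += 1
                carriers[site.site_id].add(ind)
    return calls, per_individual, carriers


def write_calls_tsv(calls: Iterable[RddCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("site_id\tindividual\ttotal\tn_A\tn_B\tcalled\n")
        for c in calls:
            fh.write(f"{c.site_id}\t{c.individual}\t{c.total}\t{c.n_A}\t{c.n_B}\t{int(c.called)}\n")


def write_individual_summary_tsv(per_individual: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        fh.write("individual\tn_events\n")
        for ind in sorted(per_individual):
            fh.write(f"{ind}\t{per_individual[ind]}\n")
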