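"""Per-individual genomic-read evidence for candidate RDD sites.

Lenient criterion: at least one genomic read shows nucleotide B.
Stringent criterion: at least 90% of reads show A or B, and at least 10% of
those show B — with no minimum-coverage requirement, so a single B read
passes.  Zero-coverage pileups fail both.

Also implements the nucleotide-swap specificity control: replace B with one
of the two nucleotides outside {A, B} and re-apply the stringent criterion.
"""

from __future__ import annotations

import dataclasses
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np

from .align import SitePileup
from .calling import RddCall
from .io import RddSite

STRINGENT_AB = Fraction(9, 10)
STRINGENT_B = Fraction(1, 10)


@dataclasses.dataclass(frozen=True, slots=True)
class EvidenceVerdict:
    site_id: str
    individual: str
    lenient_pass: bool
    stringent_pass: bool
    n_A: int
    n_B: int
    n_other: int


def _stringent(n_a: int, n_b: int, total: int) -> bool:
    if total == 0 or n_a + n_b == 0:
        return False
    return (
        Fraction(n_a + n_b, total) >= STRINGENT_AB
        and Fraction(n_b, n_a + n_b) >= STRINGENT_B
    )


def evaluate_evidence(pile: SitePileup, site: RddSite) -> EvidenceVerdict:
    """Lenient and stringent verdict for one DNA pileup."""
    if pile.source != "DNA":
        raise ValueError(f"evaluate_evidence expects a DNA pileup, got {pile.source!r}")
    n_a, n_b, n_other = pile.abo(site.ref_nt, site.rdd_nt)
    return EvidenceVerdict(
        site_id=pile.site_id,
        individual=pile.individual,
        lenient_pass=n_b >= 1,
        stringent_pass=_stringent(n_a, n_b, pile.total),
        n_A=n_a,
        n_B=n_b,
        n_other=n_other,
    )


@dataclasses.dataclass
class SiteEvidence:
    site_id: str
    lenient_any: bool
    stringent_any: bool
    explained_union: bool  # stringent_any OR reference-genome explanation


def aggregate_any_individual(
    verdicts: Iterable[EvidenceVerdict],
    reference_explained: Iterable[str] = (),
    site_ids: Iterable[str] | None = None,
) -> dict[str, SiteEvidence]:
    """Per-site OR over individuals, plus the union with reference explanations
    (reference-mismatch or matching reference paralog)."""
    ref_set = set(reference_explained)
    out: dict[str, SiteEvidence] = {}
    if site_ids is not None:
        for sid in site_ids:
            out[sid] = SiteEvidence(sid, False, False, sid in ref_set)
    for v in verdicts:
        se = out.get(v.site_id)
        if se is None:
            se = out[v.site_id] = SiteEvidence(v.site_id, False, False, v.site_id in ref_set)
        se.lenient_any |= v.lenient_pass
        se.stringent_any |= v.stringent_pass
        se.explained_union |= v.stringent_pass
    return out


_OTHERS = {frozenset(p): tuple(sorted(set("ACGT") - set(p))) for p in
           [(a, b) for a in "ACGT" for b in "ACGT" if a != b]}


@dataclasses.dataclass(frozen=True)
class SwapControlResult:
    iterations: int
    seed: int
    mean_passing: float
    sd_passing: float
    true_passing: int  # sites passing stringent-any with the real B
    counts: tuple[int, ...] = ()


def swap_control(
    pileups: Mapping[tuple[str, str], SitePileup],
    sites: Sequence[RddSite],
    iterations: int = 10_000,
    seed: int = 0,
    keep_counts: bool = False,
) -> SwapControlResult:
    """Mean number of sites passing stringent-any when B is replaced, per
    iteration, by a uniform draw from the two nucleotides outside {A, B}."""
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    rng = np.random.default_rng(seed)
    by_site: dict[str, list[SitePileup]] = {}
    for (sid, _ind), p in pileups.items():
        by_site.setdefault(sid, []).append(p)

    pass_alt = np.zeros((len(sites), 2), dtype=bool)
    true_passing = 0
    for i, site in enumerate(sites):
        alts = _OTHERS[frozenset((site.ref_nt, site.rdd_nt))]
        piles = by_site.get(site.site_id, [])
        if any(_stringent(*p.abo(site.ref_nt, site.rdd_nt)[:2], p.total) for p in piles):
            true_passing += 1
        for j, alt in enumerate(alts):
            pass_alt[i, j] = any(
                _stringent(p.n_of(site.ref_nt), p.n_of(alt), p.total) for p in piles
            )

    draws = rng.integers(0, 2, size=(iterations, len(sites)))
    passing = np.where(draws == 0, pass_alt[:, 0], pass_alt[:, 1])
    counts = passing.sum(axis=1)
    return SwapControlResult(
        iterations=iterations,
        seed=seed,
        mean_passing=float(counts.mean()),
        sd_passing=float(counts.std(ddof=1)) if iterations > 1 else 0.0,
        true_passing=true_passing,
        counts=tuple(int(c) for c in counts) if keep_counts else (),
    )


@dataclasses.dataclass(frozen=True)
class MatchRateResult:
    per_individual: dict[str, float]        # fraction of called events with >=1 B read
    mean_rate: float
    per_individual_control: dict[str, float]  # >=1 read of a non-A/B nucleotide
    mean_control_rate: float
    excluded: tuple[str, ...]               # individuals with no called events / no DNA


def per_individual_match_rate(
    calls: Iterable[RddCall],
    pileups: Mapping[tuple[str, str], SitePileup],
    sites: Mapping[str, RddSite],
    dna_individuals: Iterable[str] | None = None,
) -> MatchRateResult:
    """Fraction of each individual's called RDD events matched by at least one
    same-individual genomic read showing B, and the other-nucleotide control."""
    dna_set = set(dna_individuals) if dna_individuals is not None else None
    events: dict[str, list[RddCall]] = {}
    for c in calls:
        if c.called:
            events.setdefault(c.individual, []).append(c)

    rates: dict[str, float] = {}
    control: dict[str, float] = {}
    excluded: list[str] = []
    for ind, evts in sorted(events.items()):
        if dna_set is not None and ind not in dna_set:
            excluded.append(ind)
            continue
        n_matched = 0
        n_control = 0
        for c in evts:
            site = sites[c.site_id]
            pile = pileups.get((c.site_id, ind))
            if pile is not None:
                if pile.n_of(site.rdd_nt) >= 1:
                    n_matched += 1
                alts = _OTHERS[frozenset((site.ref_nt, site.rdd_nt))]
                if any(pile.n_of(a) >= 1 for a in alts):
                    n_control += 1
        rates[ind] = n_matched / len(evts)
        control[ind] = n_control / len(evts)
    return MatchRateResult(
        per_individual=rates,
        mean_rate=float(np.mean(list(rates.values()))) if rates else 0.0,
        per_individual_control=control,
        mean_control_rate=float(np.mean(list(control.values()))) if control else 0.0,
        excluded=tuple(excluded),
    )
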