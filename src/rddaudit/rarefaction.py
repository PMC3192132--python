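"""Site-elimination rarefaction: cumulative sites explained as individuals'
genomic data are added in random order, with saturation-curve extrapolation.

The curve value at k is |baseline ∪ elim(i_1) ∪ ... ∪ elim(i_k)| for a random
ordering (i_1..i_n), averaged over replicates.  Two saturation forms are
provided: Michaelis-Menten (default, closed-form invertible) and exponential
approach; the extrapolation method is a modelling choice, reported with the
fit.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares


class FitRejectedError(ValueError):
    """Curve carries no usable saturation signal (flat or non-increasing)."""


@dataclasses.dataclass(frozen=True)
class RarefactionCurve:
    k: tuple[int, ...]
    mean_eliminated: tuple[float, ...]
    sd_eliminated: tuple[float, ...]
    baseline: int
    replicates: int
    seed: int


@dataclasses.dataclass(frozen=True)
class SaturationFit:
    form: str               # "michaelis" | "exponential"
    e_max: float            # asymptotic sites above baseline
    k_half: float           # half-saturation constant (tau for exponential)
    baseline: int
    residual: float

    def predicted(self, k: float) -> float:
        if k < 0:
            raise ValueError("k must be >= 0")
        if self.form == "michaelis":
            return self.baseline + self.e_max * k / (self.k_half + k)
        return self.baseline + self.e_max * (1.0 - np.exp(-k / self.k_half))


def build_curve(
    elimination: Mapping[str, set[str]],
    baseline: set[str],
    individuals: Sequence[str],
    replicates: int = 1000,
    seed: int = 0,
    exhaustive: bool = False,
) -> RarefactionCurve:
    """Mean/sd eliminated-site counts for k = 0..n individuals added.

    ``elimination`` maps site_id -> set of individuals whose genomic data
    eliminate it; ``baseline`` is the set of sites eliminated by the reference
    alone (the k = 0 value).  With ``exhaustive`` the mean is the exact
    expectation over all n! orderings (n <= 8) instead of a Monte Carlo
    average.
    """
    import itertools
    import math

    individuals = list(individuals)
    n = len(individuals)
    universe = sorted(set(elimination) | baseline)
    if n == 0 or replicates < 1:
        b = len(baseline)
        return RarefactionCurve((0,), (float(b),), (0.0,), b, replicates, seed)
    site_index = {s: i for i, s in enumerate(universe)}
    M = np.zeros((len(universe), n), dtype=bool)
    for sid, inds in elimination.items():
        for ind in inds:
            if ind in individuals:
                M[site_index[sid], individuals.index(ind)] = True
    b_vec = np.zeros(len(universe), dtype=bool)
    for sid in baseline:
        b_vec[site_index[sid]] = True

    if exhaustive:
        if n > 8:
            raise ValueError("exhaustive enumeration limited to n <= 8 individuals")
        perms = [np.array(p) for p in itertools.permutations(range(n))]
        replicates = math.factorial(n)
    rng = np.random.default_rng(seed)
    counts = np.empty((replicates, n + 1), dtype=np.int64)
    counts[:, 0] = int(b_vec.sum())
    for r in range(replicates):
        perm = perms[r] if exhaustive else rng.permutation(n)
        cum = np.logical_or.accumulate(M[:, perm], axis=1)
        counts[r, 1:] = np.sum(cum | b_vec[:, None], axis=0)
    if replicates > 1:
        sds = tuple(float(x) for x in counts.std(axis=0, ddof=1))
    else:
        sds = tuple(0.0 for _ in range(n + 1))
    return RarefactionCurve(
        k=tuple(range(n + 1)),
        mean_eliminated=tuple(float(x) for x in counts.mean(axis=0)),
        sd_eliminated=sds,
        baseline=int(b_vec.sum()),
        replicates=replicates,
        seed=seed,
    )


def fit_saturation(curve: RarefactionCurve, form: str = "michaelis") -> SaturationFit:
    """Least-squares saturation fit over k >= 1 with the baseline held fixed."""
    if form not in ("michaelis", "exponential"):
        raise ValueError(f"unknown form {form!r}")
    ks = np.array([k for k in curve.k if k >= 1], dtype=float)
    ys = np.array([m for k, m in zip(curve.k, curve.mean_eliminated) if k >= 1])
    if len(ks) < 3:
        raise FitRejectedError("need at least 3 points with k >= 1")
    rise = ys - curve.baseline
    if np.max(rise) <= 1e-9 or np.any(np.diff(ys) < -1e-9):
        raise FitRejectedError("curve is flat or non-increasing above baseline")

    def resid(params: np.ndarray) -> np.ndarray:
        e_max, k_half = params
        if form == "michaelis":
            pred = e_max * ks / (k_half + ks)
        else:
            pred = e_max * (1.0 - np.exp(-ks / k_half))
        return pred - rise

    # asymptote must clear the highest observed mean
    lo = [float(np.max(rise)), 1e-9]
    x0 = [max(2.0 * float(np.max(rise)), lo[0] + 1e-6), max(float(ks[len(ks) // 2]), 1e-3)]
    sol = least_squares(resid, x0=x0, bounds=(lo, [np.inf, np.inf]))
    e_max, k_half = float(sol.x[0]), float(sol.x[1])
    return SaturationFit(
        form=form,
        e_max=e_max,
        k_half=k_half,
        baseline=curve.baseline,
        residual=float(np.sum(sol.fun**2)),
    )


@dataclasses.dataclass(frozen=True)
class ExtrapolationResult:
    reachable: bool
    k_star: int | None
    target_sites: float
    asymptote: float


def individuals_to_fraction(
    fit: SaturationFit,
    total_sites: int,
    target_fraction: float,
) -> ExtrapolationResult:
    """Smallest integer k with predicted(k) >= target_fraction * total_sites,
    by closed-form inversion of the saturation model."""
    if not 0 < target_fraction <= 1:
        raise ValueError("target_fraction must be in (0, 1]")
    target = target_fraction * total_sites
    asymptote = fit.baseline + fit.e_max
    if target <= fit.baseline:
        return ExtrapolationResult(True, 0, target, asymptote)
    if target >= asymptote:
        return ExtrapolationResult(False, None, target, asymptote)
    rise = target - fit.baseline
    if fit.form == "michaelis":
        k_exact = fit.k_half * rise / (fit.e_max - rise)
    else:
        k_exact = -fit.k_half * np.log(1.0 - rise / fit.e_max)
    k_star = int(np.ceil(k_exact - 1e-12))
    # guard against floating point on the boundary
    while fit.predicted(k_star) < target - 1e-9:
        k_star += 1
    return ExtrapolationResult(True, max(k_star, 1), target, asymptote)


def write_curve_tsv(curve: RarefactionCurve, path) -> None:
    with open(path, "w") as fh:
        fh.write("k\tmean_eliminated\tsd_eliminated\n")
        for k, m, s in zip(curve.k, curve.mean_eliminated, curve.sd_eliminated):
            fh.write(f"{k}\t{m:.6f}\t{s:.6f}\n")


def plot_curve(curve: RarefactionCurve, fit: SaturationFit | None, path) -> None:
    """Mean curve with optional fitted overlay (PNG/SVG by extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.errorbar(curve.k, curve.mean_eliminated, yerr=curve.sd_eliminated,
                fmt="o-", capsize=2, label="mean eliminated")
    if fit is not None:
        ks = np.linspace(0, max(curve.k), 200)
        ax.plot(ks, [fit.predicted(k) for k in ks], "--", label=f"{fit.form} fit")
    ax.set_xlabel("individuals added")
    ax.set_ylabel("sites eliminated")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
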