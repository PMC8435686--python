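"""Species-constrained rarefaction and asymptotic richness estimation.

Gamma (total) compound richness per organ is estimated from bootstrap
accumulation curves.  Because samples of the same species are not
independent, accumulation is species-constrained: each replicate picks a
uniformly random starting sample, adds the remaining samples of that
species in random order, then picks the next sample at random among those
remaining, adds its species-mates, and so on — same-species samples are
always contiguous.  Total richness is the asymptote of the 3-parameter
asymptotic regression

    S(n) = Asym + (R0 - Asym) * exp(-exp(lrc) * n)

fitted per replicate curve by nonlinear least squares; the estimate is the
mean of per-replicate asymptotes, its SE the standard error of that mean,
and the 95% CI the normal approximation (a percentile CI is available).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from phytodiv.occurrence import FeatureTable

logger = logging.getLogger(__name__)

__all__ = ["RarefactionResult", "constrained_accumulation", "fit_asymptote",
           "asymptotic_model"]


def asymptotic_model(n: np.ndarray, asym: float, r0: float, lrc: float) -> np.ndarray:
    """Asymptotic regression S(n) = Asym + (R0 - Asym) exp(-exp(lrc) n)."""
    return asym + (r0 - asym) * np.exp(-np.exp(lrc) * n)


@dataclass
class RarefactionResult:
    """Accumulation curves and (after fitting) the asymptotic estimate."""

    organ: str
    mean_curve: np.ndarray
    per_replicate_curves: np.ndarray | None
    n_replicates: int
    seed: int
    estimate: float | None = None
    se: float | None = None
    ci95: tuple[float, float] | None = None
    n_failed_fits: int = 0
    estimate_below_observed: bool = False
    per_replicate_asym: np.ndarray | None = field(default=None, repr=False)

    @property
    def observed_richness(self) -> int:
        return int(round(float(self.mean_curve[-1])))

    def to_dict(self) -> dict:
        return {
            "organ": self.organ,
            "observed_richness": self.observed_richness,
            "estimate": self.estimate,
            "se": self.se,
            "ci95": list(self.ci95) if self.ci95 else None,
            "n_replicates": self.n_replicates,
            "n_failed_fits": self.n_failed_fits,
            "estimate_below_observed": self.estimate_below_observed,
            "mean_curve": [float(v) for v in self.mean_curve],
            "ci_method": "normal approximation on per-replicate asymptote fits",
        }


def constrained_accumulation(
    table: FeatureTable,
    organ: str,
    n_replicates: int = 5000,
    seed: int = 0,
    keep_replicates: bool = True,
) -> RarefactionResult:
    """Species-constrained bootstrap accumulation curves for one organ."""
    mask = table.metadata["organ"] == organ
    if not mask.any():
        raise ValueError(f"organ {organ!r} absent from table")
    sub = table.subset(mask.to_numpy())
    if sub.n_samples < 2:
        raise ValueError(f"organ {organ!r} has fewer than 2 samples")
    pres = sub.presence.to_numpy(bool)
    species = sub.metadata["species"].to_numpy()
    n = sub.n_samples
    rng = np.random.default_rng(seed)

    by_species: dict[str, np.ndarray] = {
        sp: np.flatnonzero(species == sp) for sp in np.unique(species)}
    curves = np.empty((n_replicates, n), dtype=np.float64)
    for r in range(n_replicates):
        order: list[int] = []
        remaining = set(by_species)
        # weight species choice by remaining sample count: the *sample*
        # (not the species) is drawn uniformly at random
        while remaining:
            pool = np.concatenate([by_species[sp] for sp in sorted(remaining)])
            start = int(rng.choice(pool))
            sp = species[start]
            mates = by_species[sp].copy()
            rng.shuffle(mates)
            mates = [start] + [int(i) for i in mates if i != start]
            order.extend(mates)
            remaining.discard(sp)
        seen = np.logical_or.accumulate(pres[order], axis=0)
        curves[r] = seen.sum(axis=1)

    result = RarefactionResult(
        organ=organ,
        mean_curve=curves.mean(axis=0),
        per_replicate_curves=curves if keep_replicates else None,
        n_replicates=n_replicates,
        seed=seed,
    )
    return result


def _fit_one(curve: np.ndarray) -> float | None:
    """Fit the asymptotic model to one curve; return Asym or None.

    Starts from Asym0 = 1.1 x final value, R0_0 = first value and an lrc0
    from a log-linear probe of the residual decay; falls back to a small
    grid of bounded restarts if the first attempt does not converge.
    """
    n = np.arange(1, curve.size + 1, dtype=float)
    final, first = float(curve[-1]), float(curve[0])
    if np.allclose(curve, final):
        return final  # already saturated
    asym0 = 1.1 * final
    resid = np.maximum(asym0 - curve, 1e-9)
    slope = np.polyfit(n, np.log(resid), 1)[0]
    lrc0 = float(np.log(max(-slope, 1e-6)))

    def _accept(popt: np.ndarray) -> float | None:
        asym = float(popt[0])
        if np.isfinite(asym) and 0 < asym <= 10 * final:
            return asym
        return None

    try:
        popt, _ = curve_fit(
            asymptotic_model, n, curve, p0=[asym0, first, lrc0], maxfev=5000)
        got = _accept(popt)
        if got is not None:
            return got
    except (RuntimeError, ValueError):
        pass
    bounds = ([first, 0.0, -10.0], [10 * final, final, 5.0])
    for lrc_try in (lrc0, -1.0, 0.0, 1.0):
        try:
            popt, _ = curve_fit(
                asymptotic_model, n, curve,
                p0=[min(asym0, 10 * final), first, float(np.clip(lrc_try, -10, 5))],
                bounds=bounds, method="trf", maxfev=5000)
        except (RuntimeError, ValueError):
            continue
        got = _accept(popt)
        if got is not None:
            return got
    return None


def fit_asymptote(
    result: RarefactionResult, max_failure_fraction: float = 0.05
) -> RarefactionResult:
    """Fit the asymptotic model to every replicate curve and aggregate.

    Individual non-converged fits are dropped and counted; more than
    ``max_failure_fraction`` failures raises with diagnostics.
    """
    if result.per_replicate_curves is None:
        raise ValueError("per-replicate curves were not retained; rerun "
                         "constrained_accumulation(keep_replicates=True)")
    curves = result.per_replicate_curves
    if curves.shape[1] < 3:
        raise ValueError("need >= 3 accumulation steps to fit an asymptote")
    asyms = []
    n_failed = 0
    for curve in curves:
        a = _fit_one(curve)
        if a is None:
            n_failed += 1
        else:
            asyms.append(a)
    if n_failed > max_failure_fraction * curves.shape[0]:
        raise RuntimeError(
            f"asymptote fit failed for {n_failed}/{curves.shape[0]} replicates "
            f"(organ {result.organ!r}; observed richness "
            f"{result.observed_richness}, {curves.shape[1]} steps)")
    arr = np.asarray(asyms)
    estimate = float(arr.mean())
    se = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0
    result.estimate = estimate
    result.se = se
    result.ci95 = (estimate - 1.96 * se, estimate + 1.96 * se)
    result.n_failed_fits = n_failed
    result.per_replicate_asym = arr
    result.estimate_below_observed = bool(estimate < result.mean_curve[-1])
    if result.estimate_below_observed:
        logger.warning("organ %r: asymptote estimate %.1f below observed "
                       "richness %.1f", result.organ, estimate,
                       float(result.mean_curve[-1]))
    return result
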