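"""Mixed-model contrasts of alpha richness and structural complexity.

Per-sample responses (compound richness or within-sample structural
complexity) are modeled with a linear mixed model: organ, species and
their interaction as fixed effects, plant identity as a random intercept.
Fixed terms are tested by likelihood-ratio tests between maximum-likelihood
fits of nested models (ML, not REML — REML likelihoods are not comparable
across fixed-effect structures).  Per-species follow-ups fit organ as the
only fixed effect with plant random, and compare organs pairwise with a
Tukey (studentized-range) adjustment on large-sample Wald contrasts,
summarized as a compact letter display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

from phytodiv.multivariate import compact_letter_display

__all__ = ["LmmResult", "fit_diversity_lmm", "tukey_letters",
           "per_species_organ_contrasts"]

_TERMS = ("organ", "species", "organ:species")


@dataclass
class LmmResult:
    """Likelihood-ratio test of one fixed term, with optional follow-ups."""

    response: str
    test_term: str
    chi2: float
    df: int
    p: float
    full_formula: str
    reduced_formula: str
    per_species: dict[str, pd.DataFrame] = field(default_factory=dict)
    letters: dict[str, dict[str, str]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "test_term": self.test_term,
            "chi2": self.chi2,
            "df": self.df,
            "p": self.p,
            "full_formula": self.full_formula,
            "reduced_formula": self.reduced_formula,
            "letters": self.letters,
            "p_adjust": "Tukey studentized-range, large-sample normal approximation",
        }


def _fit_ml(formula: str, data: pd.DataFrame):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data=data, groups=data["plant"])
        fit = model.fit(reml=False, method=["lbfgs", "powell"])
    if not np.isfinite(fit.llf):
        raise np.linalg.LinAlgError("non-finite likelihood")
    return fit


def _fit_pair(full_f: str, red_f: str, data: pd.DataFrame):
    """ML fits of a nested model pair; on a degenerate random-effect
    variance (singular fit) both models fall back to the boundary fit
    (zero plant variance, i.e. an ordinary ML regression), keeping the
    likelihoods comparable."""
    try:
        return _fit_ml(full_f, data), _fit_ml(red_f, data)
    except (np.linalg.LinAlgError, ValueError):
        warnings.warn("mixed-model fit degenerate (plant variance at the "
                      "boundary); using the zero-variance boundary fit",
                      stacklevel=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return (smf.ols(full_f, data=data).fit(),
                    smf.ols(red_f, data=data).fit())


def _fixed_effects(fit):
    params = getattr(fit, "fe_params", None)
    if params is None:
        params = fit.params
    cov = fit.cov_params().loc[params.index, params.index]
    return params, cov


def fit_diversity_lmm(
    responses: pd.Series,
    design: pd.DataFrame,
    test_term: str = "organ:species",
    response_name: str = "response",
) -> LmmResult:
    """Likelihood-ratio test of a fixed term in the diversity LMM.

    Nested model pairs (random intercept for plant throughout):
    ``organ:species``: organ*species vs organ+species;
    ``organ``: organ+species vs species; ``species``: organ+species vs organ.
    chi2 = 2 (ll_full - ll_reduced), df = difference in fixed-effect
    parameters, p from the chi-squared distribution.
    """
    if test_term not in _TERMS:
        raise ValueError(f"test_term must be one of {_TERMS}")
    if not responses.index.equals(design.index):
        raise ValueError("responses do not align with design rows")
    data = design.copy()
    data["y"] = np.asarray(responses, dtype=float)
    if test_term == "organ:species":
        cells = data.groupby(["organ", "species"]).size()
        if (cells < 1).any():
            raise ValueError("interaction test needs every organ x species cell")
        full_f, red_f = "y ~ organ * species", "y ~ organ + species"
    elif test_term == "organ":
        full_f, red_f = "y ~ organ + species", "y ~ species"
    else:
        full_f, red_f = "y ~ organ + species", "y ~ organ"

    if np.ptp(data["y"].to_numpy()) == 0.0:
        # constant response: likelihoods identical in any nested pair
        return LmmResult(response=response_name, test_term=test_term,
                         chi2=0.0, df=_term_df(data, test_term), p=1.0,
                         full_formula=full_f, reduced_formula=red_f)

    full, reduced = _fit_pair(full_f, red_f, data)
    chi2 = max(0.0, 2.0 * (full.llf - reduced.llf))
    df = _term_df(data, test_term)
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return LmmResult(response=response_name, test_term=test_term,
                     chi2=float(chi2), df=df, p=p,
                     full_formula=full_f, reduced_formula=red_f)


def _term_df(data: pd.DataFrame, term: str) -> int:
    n_o = data["organ"].nunique()
    n_s = data["species"].nunique()
    if term == "organ":
        return n_o - 1
    if term == "species":
        return n_s - 1
    return (n_o - 1) * (n_s - 1)


def per_species_organ_contrasts(
    responses: pd.Series,
    design: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[dict[str, pd.DataFrame], dict[str, dict[str, str]], dict[str, LmmResult]]:
    """Per-species organ contrasts with Tukey-adjusted p and letters.

    For each species: fit ``y ~ organ`` with plant random; build all
    pairwise organ contrasts from the fixed-effect estimates and their
    covariance; adjust with the studentized range (large-sample df).
    Returns (pairwise tables, letter displays, per-species organ LRTs).
    """
    tables: dict[str, pd.DataFrame] = {}
    letters: dict[str, dict[str, str]] = {}
    lrts: dict[str, LmmResult] = {}
    for sp in sorted(design["species"].astype(str).unique()):
        mask = design["species"].astype(str) == sp
        data = design.loc[mask].copy()
        data["y"] = np.asarray(responses.loc[mask], dtype=float)
        organs = sorted(data["organ"].unique())
        k = len(organs)
        if k < 2:
            raise ValueError(f"species {sp!r} has a single organ level")

        # species-level LRT of the organ effect
        if np.ptp(data["y"].to_numpy()) == 0.0:
            lrts[sp] = LmmResult(response="y", test_term="organ", chi2=0.0,
                                 df=k - 1, p=1.0, full_formula="y ~ organ",
                                 reduced_formula="y ~ 1")
            pair_rows = [{"organ_a": a, "organ_b": b, "difference": 0.0,
                          "p_adjusted": 1.0}
                         for i, a in enumerate(organs) for b in organs[i + 1:]]
            tables[sp] = pd.DataFrame(pair_rows)
            letters[sp] = compact_letter_display(organs, set())
            continue

        full, reduced = _fit_pair("y ~ organ", "y ~ 1", data)
        chi2 = max(0.0, 2.0 * (full.llf - reduced.llf))
        lrts[sp] = LmmResult(response="y", test_term="organ",
                             chi2=float(chi2), df=k - 1,
                             p=float(stats.chi2.sf(chi2, k - 1)),
                             full_formula="y ~ organ", reduced_formula="y ~ 1")

        # organ means from treatment coding: reference organ = organs[0]
        fe, cov = _fixed_effects(full)
        coef_of = {organs[0]: None}
        for o in organs[1:]:
            name = f"organ[T.{o}]"
            if name not in fe.index:
                raise RuntimeError(f"missing fixed effect {name!r}")
            coef_of[o] = name
        df_resid = max(len(data) - k, 2)
        rows = []
        sig = set()
        for i, a in enumerate(organs):
            for b in organs[i + 1:]:
                vec = pd.Series(0.0, index=fe.index)
                if coef_of[a] is not None:
                    vec[coef_of[a]] += 1.0
                if coef_of[b] is not None:
                    vec[coef_of[b]] -= 1.0
                diff = float(vec @ fe)
                se = float(np.sqrt(vec @ cov @ vec))
                if se == 0.0:
                    p_adj = 1.0 if diff == 0 else 0.0
                else:
                    q = abs(diff) / se * np.sqrt(2.0)
                    p_adj = float(stats.studentized_range.sf(q, k, df_resid))
                rows.append({"organ_a": a, "organ_b": b,
                             "difference": diff, "p_adjusted": p_adj})
                if p_adj < alpha:
                    sig.add((a, b))
        tables[sp] = pd.DataFrame(rows)
        letters[sp] = compact_letter_display(organs, sig)
    return tables, letters, lrts


def tukey_letters(
    pairwise_p: dict[tuple[str, str], float], alpha: float = 0.05
) -> dict[str, str]:
    """Compact letter display from Tukey-adjusted pairwise p-values.

    ``pairwise_p`` must cover every unordered pair of the groups it
    mentions; groups share a letter iff not significantly different.
    """
    groups = sorted({g for pair in pairwise_p for g in pair})
    seen = {tuple(sorted(p)) for p in pairwise_p}
    for i, a in enumerate(groups):
        for b in groups[i + 1:]:
            if (a, b) not in seen:
                raise ValueError(f"missing p-value for pair ({a!r}, {b!r})")
    sig = {tuple(sorted(pair)) for pair, p in pairwise_p.items() if p < alpha}
    return compact_letter_display(groups, sig)
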