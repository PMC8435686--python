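"""Permutation-based multivariate statistics on distance matrices.

PERMANOVA with sequential (Type-I) sums of squares and optional
within-strata permutation restriction, pairwise PERMANOVA with
multiple-testing correction, beta-dispersion (distance to group centroid in
principal-coordinates space, with permutation test and Tukey HSD), and
per-organ variance partitioning (eta-squared for species vs residual).

The machinery follows the standard Gower construction: from squared
dissimilarities, G = -1/2 C D2 C with C the centering matrix; the sum of
squares attributable to a projector P is tr(P G), and the permutation null
is obtained by relabeling samples (optionally only within strata).
p-values use the (1 + exceedances) / (1 + permutations) convention, so the
smallest attainable p at 999 permutations is 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from phytodiv.occurrence import DistanceMatrix

__all__ = [
    "PermanovaTable", "DispersionResult", "VariancePartition",
    "permanova", "pairwise_permanova", "dispersion", "variance_partition",
    "compact_letter_display",
]


# ---------------------------------------------------------------- helpers

def _gower_center(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    a = -0.5 * d ** 2
    c = np.eye(n) - np.ones((n, n)) / n
    return c @ a @ c


def _dummies(series: pd.Series) -> np.ndarray:
    return pd.get_dummies(series.astype(str), drop_first=True).to_numpy(float)


def _term_columns(meta: pd.DataFrame, term: str) -> np.ndarray:
    """Design columns for a main effect or an 'a:b' interaction."""
    parts = term.split(":")
    for p in parts:
        if p not in meta.columns:
            raise ValueError(f"term {term!r}: unknown metadata key {p!r}")
    blocks = [_dummies(meta[p]) for p in parts]
    x = blocks[0]
    for b in blocks[1:]:
        x = (x[:, :, None] * b[:, None, :]).reshape(len(meta), -1)
    return x


def _hat(x: np.ndarray) -> np.ndarray:
    return x @ np.linalg.pinv(x)


def _permutations(
    n: int,
    n_permutations: int,
    rng: np.random.Generator,
    strata: np.ndarray | None,
) -> np.ndarray:
    perms = np.empty((n_permutations, n), dtype=int)
    base = np.arange(n)
    if strata is None:
        for k in range(n_permutations):
            perms[k] = rng.permutation(n)
    else:
        groups = [np.flatnonzero(strata == s) for s in pd.unique(strata)]
        for k in range(n_permutations):
            p = base.copy()
            for g in groups:
                p[g] = g[rng.permutation(len(g))]
            perms[k] = p
    return perms


# ---------------------------------------------------------------- PERMANOVA

@dataclass
class PermanovaTable:
    """Machine-readable PERMANOVA table (one row per term, plus Residual
    and Total rows) with the permutation setup used."""

    table: pd.DataFrame  # index: term labels; columns: df, SS, F, R2, p
    n_permutations: int
    strata: str | None
    seed: int

    def __str__(self) -> str:  # human-readable, vegan-style layout
        return self.table.to_string(float_format=lambda v: f"{v:.4g}")

    def term(self, label: str) -> pd.Series:
        return self.table.loc[label]

    def to_dict(self) -> dict:
        return {
            "table": {
                t: {k: (None if pd.isna(v) else float(v)) for k, v in row.items()}
                for t, row in self.table.iterrows()
            },
            "n_permutations": self.n_permutations,
            "strata": self.strata,
            "seed": self.seed,
        }


def permanova(
    d: DistanceMatrix,
    design: pd.DataFrame,
    terms: list[str],
    strata: str | None = None,
    n_permutations: int = 999,
    seed: int = 0,
) -> PermanovaTable:
    """PERMANOVA with sequential (Type-I) SS in the given term order.

    ``design`` rows must align with ``d.sample_ids``.  With ``strata``,
    permutations shuffle sample labels only within each stratum.
    """
    if list(design.index) != list(d.sample_ids):
        raise ValueError("design rows do not align with the distance matrix")
    n = len(d.sample_ids)
    if strata is not None:
        if strata not in design.columns:
            raise ValueError(f"unknown strata key {strata!r}")
        if strata in terms:
            raise ValueError(f"strata {strata!r} is also a model term; the "
                             "permutation restriction would be confounded")
    g = _gower_center(d.d)
    ss_total = float(np.trace(g))

    x = np.ones((n, 1))
    h_prev = _hat(x)
    rank_prev = 1
    projectors: list[np.ndarray] = []
    dfs: list[int] = []
    for term in terms:
        x = np.hstack([x, _term_columns(design, term)])
        h = _hat(x)
        rank = int(np.round(np.trace(h)))
        df = rank - rank_prev
        if df < 1:
            raise ValueError(f"singular design: term {term!r} adds no rank "
                             "(confounded with earlier terms)")
        projectors.append(h - h_prev)
        dfs.append(df)
        h_prev, rank_prev = h, rank
    p_res = np.eye(n) - h_prev
    df_res = n - rank_prev
    if df_res < 1:
        raise ValueError("saturated design: no residual degrees of freedom")

    dfs_arr = np.asarray(dfs, dtype=float)
    tol = 1e-12 * max(1.0, abs(ss_total))

    def pseudo_f(gp: np.ndarray) -> tuple[np.ndarray, float]:
        ss_t = np.array([float(np.sum(proj * gp)) for proj in projectors])
        ss_r = float(np.sum(p_res * gp))
        if ss_r <= tol:
            # degenerate residual (e.g. duplicated points within groups):
            # any positive term SS gives an unbounded pseudo-F
            return np.where(ss_t > tol, np.inf, 0.0), max(ss_r, 0.0)
        return (ss_t / dfs_arr) / (ss_r / df_res), ss_r

    f_obs, ss_res = pseudo_f(g)
    ss_terms = np.array([float(np.sum(proj * g)) for proj in projectors])

    rng = np.random.default_rng(seed)
    strata_vals = design[strata].to_numpy() if strata else None
    perms = _permutations(n, n_permutations, rng, strata_vals)
    exceed = np.zeros(len(terms))
    for p in perms:
        f_p, _ = pseudo_f(g[np.ix_(p, p)])
        exceed += f_p >= f_obs
    pvals = (1.0 + exceed) / (1.0 + n_permutations)

    rows = {}
    for i, term in enumerate(terms):
        rows[term] = [dfs[i], ss_terms[i], f_obs[i], ss_terms[i] / ss_total, pvals[i]]
    rows["Residual"] = [df_res, ss_res, np.nan, ss_res / ss_total, np.nan]
    rows["Total"] = [n - 1, ss_total, np.nan, 1.0, np.nan]
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=["df", "SS", "F", "R2", "p"])
    return PermanovaTable(table=table, n_permutations=n_permutations,
                          strata=strata, seed=seed)


def pairwise_permanova(
    d: DistanceMatrix,
    design: pd.DataFrame,
    factor: str,
    n_permutations: int = 999,
    correction: str = "holm",
    seed: int = 0,
) -> tuple[dict[tuple[str, str], PermanovaTable], pd.DataFrame]:
    """One two-level PERMANOVA per unordered level pair of ``factor``,
    with Holm (default) or Benjamini-Hochberg adjusted p-values."""
    if correction not in ("holm", "bh"):
        raise ValueError("correction must be 'holm' or 'bh'")
    if factor not in design.columns:
        raise ValueError(f"unknown metadata key {factor!r}")
    levels = sorted(design[factor].astype(str).unique())
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} has fewer than 2 levels")
    counts = design[factor].astype(str).value_counts()
    small = [lv for lv in levels if counts[lv] < 2]
    if small:
        raise ValueError(f"level {small[0]!r} of {factor!r} has < 2 samples")

    tables: dict[tuple[str, str], PermanovaTable] = {}
    raw = []
    pairs = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1:]]
    for k, (a, b) in enumerate(pairs):
        mask = design[factor].astype(str).isin([a, b]).to_numpy()
        ids = [s for s, m in zip(d.sample_ids, mask) if m]
        sub_d = d.subset(ids)
        sub_meta = design.loc[mask]
        tab = permanova(sub_d, sub_meta, [factor],
                        n_permutations=n_permutations, seed=seed + k)
        tables[(a, b)] = tab
        raw.append(tab.term(factor)["p"])
    method = "holm" if correction == "holm" else "fdr_bh"
    adjusted = multipletests(raw, method=method)[1]
    summary = pd.DataFrame({
        "level_a": [a for a, _ in pairs],
        "level_b": [b for _, b in pairs],
        "F": [tables[p].term(factor)["F"] for p in pairs],
        "p_raw": raw,
        "p_adjusted": adjusted,
    })
    return tables, summary


# ---------------------------------------------------------------- dispersion

def compact_letter_display(
    groups: list[str], significant_pairs: set[tuple[str, str]]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Two groups share a letter iff their pair is not in
    ``significant_pairs``.  Letter assignment is deterministic: columns are
    ordered by their first member in sorted group order.
    """
    groups = sorted(groups)
    sig = {tuple(sorted(p)) for p in significant_pairs}
    columns: list[set[str]] = [set(groups)]
    for a, b in sorted(sig):
        new_columns: list[set[str]] = []
        for col in columns:
            if a in col and b in col:
                new_columns.append(col - {a})
                new_columns.append(col - {b})
            else:
                new_columns.append(col)
        # absorb columns contained in another; deduplicate
        columns = []
        for col in new_columns:
            if col and not any(col < other for other in new_columns):
                if col not in columns:
                    columns.append(col)
    columns.sort(key=lambda col: [groups.index(x) for x in sorted(col)][0])
    letters = {gp: "" for gp in groups}
    for i, col in enumerate(columns):
        letter = chr(ord("a") + i)
        for gp in sorted(col):
            letters[gp] += letter
    return letters


@dataclass
class DispersionResult:
    """Beta-dispersion: distances to group centroids plus tests."""

    distances: pd.Series            # per-sample distance to its group centroid
    group_means: pd.Series
    f: float
    p: float
    tukey: pd.DataFrame             # per pair: difference, p_adjusted
    letters: dict[str, str]
    n_permutations: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "group_means": {k: float(v) for k, v in self.group_means.items()},
            "F": float(self.f),
            "p": float(self.p),
            "tukey": self.tukey.to_dict(orient="records"),
            "letters": self.letters,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }


def _anova_f(values: np.ndarray, labels: np.ndarray) -> float:
    grand = values.mean()
    ss_between = ss_within = 0.0
    k = 0
    for lv in np.unique(labels):
        v = values[labels == lv]
        ss_between += len(v) * (v.mean() - grand) ** 2
        ss_within += ((v - v.mean()) ** 2).sum()
        k += 1
    df1, df2 = k - 1, len(values) - k
    if ss_within == 0.0:
        return np.inf if ss_between > 0 else 0.0
    return (ss_between / df1) / (ss_within / df2)


def dispersion(
    d: DistanceMatrix,
    design: pd.DataFrame,
    groups: str,
    n_permutations: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
) -> DispersionResult:
    """Distance to group centroid in principal-coordinates space.

    The PCoA of ``d`` retains negative-eigenvalue axes as an imaginary
    block; each sample's distance to its group centroid is
    sqrt(max(0, d_real^2 - d_imag^2)).  The overall test is a one-way F on
    these distances with a permutation p (group labels permuted freely),
    followed by Tukey HSD and a compact letter display at ``alpha``.
    """
    if list(design.index) != list(d.sample_ids):
        raise ValueError("design rows do not align with the distance matrix")
    if groups not in design.columns:
        raise ValueError(f"unknown metadata key {groups!r}")
    labels = design[groups].astype(str).to_numpy()
    lv_counts = pd.Series(labels).value_counts()
    if (lv_counts < 2).any():
        bad = lv_counts[lv_counts < 2].index[0]
        raise ValueError(f"group {bad!r} has a single sample")

    g = _gower_center(d.d)
    eigval, eigvec = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(1e-10, 1e-8 * abs(eigval).max())
    keep = np.abs(eigval) > tol
    eigval, eigvec = eigval[keep], eigvec[:, keep]
    coords = eigvec * np.sqrt(np.abs(eigval))
    real = eigval > 0

    z = np.empty(len(labels))
    for lv in np.unique(labels):
        idx = labels == lv
        centroid = coords[idx].mean(axis=0)
        delta2 = (coords[idx] - centroid) ** 2
        dr2 = delta2[:, real].sum(axis=1)
        di2 = delta2[:, ~real].sum(axis=1)
        z[idx] = np.sqrt(np.maximum(0.0, dr2 - di2))

    f_obs = _anova_f(z, labels)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        exceed += _anova_f(z, labels[rng.permutation(len(labels))]) >= f_obs
    p = (1.0 + exceed) / (1.0 + n_permutations)

    level_names = sorted(np.unique(labels))
    samples = [z[labels == lv] for lv in level_names]
    hsd = stats.tukey_hsd(*samples)
    rows = []
    sig_pairs = set()
    for i, a in enumerate(level_names):
        for j in range(i + 1, len(level_names)):
            b = level_names[j]
            p_adj = float(hsd.pvalue[i, j])
            rows.append({"level_a": a, "level_b": b,
                         "difference": float(samples[i].mean() - samples[j].mean()),
                         "p_adjusted": p_adj})
            if p_adj < alpha:
                sig_pairs.add((a, b))
    letters = compact_letter_display(level_names, sig_pairs)

    dist_series = pd.Series(z, index=d.sample_ids, name="distance_to_centroid")
    means = dist_series.groupby(pd.Series(labels, index=d.sample_ids)).mean()
    return DispersionResult(
        distances=dist_series, group_means=means.sort_index(),
        f=float(f_obs), p=float(p), tukey=pd.DataFrame(rows),
        letters=letters, n_permutations=n_permutations, seed=seed)


# ------------------------------------------------------- variance partition

@dataclass
class VariancePartition:
    organ: str
    f: float
    p: float
    eta2_species: float
    eta2_residual: float

    def to_dict(self) -> dict:
        return {"organ": self.organ, "F": self.f, "p": self.p,
                "eta2_species": self.eta2_species,
                "eta2_residual": self.eta2_residual}


def variance_partition(
    d: DistanceMatrix,
    design: pd.DataFrame,
    factor: str = "species",
    subset_by: str = "organ",
    n_permutations: int = 999,
    seed: int = 0,
) -> list[VariancePartition]:
    """Per-organ one-factor PERMANOVA partitioning within-organ variance
    into the fraction explained by ``factor`` (eta^2) and the residual."""
    if subset_by not in design.columns:
        raise ValueError(f"unknown metadata key {subset_by!r}")
    out = []
    for k, organ in enumerate(sorted(design[subset_by].astype(str).unique())):
        mask = (design[subset_by].astype(str) == organ).to_numpy()
        sub_meta = design.loc[mask]
        if sub_meta[factor].nunique() < 2:
            raise ValueError(f"{subset_by} {organ!r} has a single {factor} level")
        ids = [s for s, m in zip(d.sample_ids, mask) if m]
        tab = permanova(d.subset(ids), sub_meta, [factor],
                        n_permutations=n_permutations, seed=seed + k)
        row = tab.term(factor)
        eta2 = float(row["SS"] / tab.table.loc["Total", "SS"])
        out.append(VariancePartition(
            organ=organ, f=float(row["F"]), p=float(row["p"]),
            eta2_species=eta2, eta2_residual=1.0 - eta2))
    return out
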