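"""Inferential layer for treatment comparisons and association analysis.

One-way fixed-effects ANOVA is provided both on raw per-plot values and
directly on (n, mean, sd) summaries, because agronomic tables print only
means +/- SD; the two routes are algebraically identical. Post-hoc pairwise
comparison uses Tukey's HSD on the pooled within-group variance, summarized
as a compact letter display (shared letter = not significantly different,
'a' assigned to the largest mean). Association analyses are a permutation
Mantel test between distance matrices and a permutation-importance ranking
from an ensemble-of-trees regressor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.ensemble import RandomForestRegressor

from .datamodel import GroupSummary
from .errors import (
    DegenerateInputError,
    DomainError,
    InsufficientReplicationError,
    ValidationError,
)

#: reported in place of an exact zero p when within-group variance vanishes
P_UNDERFLOW_FLOOR = 1e-300


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    flagged: bool = False  # True when p hit the underflow floor


@dataclass(frozen=True)
class CLDResult:
    """Compact letter display: group -> letter string, at level ``alpha``."""

    letters: dict[str, str]
    alpha: float


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r: float
    p: float
    ci_level: float
    n: int
    x_mean: float
    sxx: float
    resid_sd: float

    def ci_halfwidth(self, x0) -> np.ndarray:
        """Half-width of the confidence band for the mean response at x0."""
        x0 = np.asarray(x0, dtype=float)
        t = sps.t.ppf(0.5 + self.ci_level / 2, self.n - 2)
        return t * self.resid_sd * np.sqrt(1 / self.n + (x0 - self.x_mean) ** 2 / self.sxx)


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_permutations: int
    seed: int


@dataclass(frozen=True)
class ImportanceRanking:
    """Features ranked by decreasing importance with permutation p-values."""

    ranked_features: tuple[tuple[str, float, float], ...]


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

def _anova_from_ss(ssb: float, ssw: float, k: int, df_within: int) -> AnovaResult:
    df_between = k - 1
    if ssw <= 0:
        if ssb <= 0:
            return AnovaResult(0.0, df_between, df_within, 1.0)
        return AnovaResult(np.inf, df_between, df_within, P_UNDERFLOW_FLOOR, flagged=True)
    F = (ssb / df_between) / (ssw / df_within)
    p = float(sps.f.sf(F, df_between, df_within))
    return AnovaResult(float(F), df_between, df_within, p)


def anova_oneway(groups: list[np.ndarray]) -> AnovaResult:
    """Classical fixed-effects one-way ANOVA on raw per-group values."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise DomainError("need at least 2 groups")
    for g in groups:
        if len(g) < 2:
            raise InsufficientReplicationError("every group needs >= 2 values")
    all_vals = np.concatenate(groups)
    if np.ptp(all_vals) == 0:
        return AnovaResult(0.0, len(groups) - 1, len(all_vals) - len(groups), 1.0)
    grand = all_vals.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    return _anova_from_ss(ssb, ssw, len(groups), len(all_vals) - len(groups))


def anova_from_summary(summaries: list[GroupSummary]) -> AnovaResult:
    """One-way ANOVA computed from (n, mean, sd) summaries alone.

    SSB = sum n_g (mean_g - grand)^2 with the grand mean weighted by n;
    SSW = sum (n_g - 1) sd_g^2. Identical to :func:`anova_oneway` on the
    underlying raw data.
    """
    if len(summaries) < 2:
        raise DomainError("need at least 2 groups")
    for s in summaries:
        if s.n < 2:
            raise InsufficientReplicationError(f"group {s.group!r}: n must be >= 2")
    n = np.array([s.n for s in summaries], dtype=float)
    means = np.array([s.mean for s in summaries])
    sds = np.array([s.sd for s in summaries])
    grand = float((n * means).sum() / n.sum())
    ssb = float((n * (means - grand) ** 2).sum())
    ssw = float(((n - 1) * sds**2).sum())
    return _anova_from_ss(ssb, ssw, len(summaries), int(n.sum()) - len(summaries))


# ---------------------------------------------------------------------------
# Tukey HSD + compact letter display
# ---------------------------------------------------------------------------

def tukey_pairwise_p(summaries: list[GroupSummary]) -> dict[tuple[str, str], float]:
    """Tukey HSD p-value for every group pair, from summary statistics.

    Uses the studentized range distribution with the pooled within-group
    mean square; unequal n falls back to the Tukey-Kramer standard error.
    """
    k = len(summaries)
    if k < 2:
        raise DomainError("need at least 2 groups")
    df_within = sum(s.n - 1 for s in summaries)
    msw = sum((s.n - 1) * s.sd**2 for s in summaries) / df_within
    out: dict[tuple[str, str], float] = {}
    for i in range(k):
        for j in range(i + 1, k):
            a, b = summaries[i], summaries[j]
            if msw <= 0:
                out[(a.group, b.group)] = 0.0 if a.mean != b.mean else 1.0
                continue
            se = np.sqrt(msw / 2 * (1 / a.n + 1 / b.n))
            q = abs(a.mean - b.mean) / se
            out[(a.group, b.group)] = float(sps.studentized_range.sf(q, k, df_within))
    return out


def tukey_cld(summaries: list[GroupSummary], alpha: float = 0.05) -> CLDResult:
    """Compact letter display from Tukey HSD on summary statistics.

    Letters are built by insert-and-absorb: start from one column holding
    all groups, split a column for every significant pair it contains, drop
    columns subsumed by another, then assign 'a', 'b', ... to columns in
    descending order of their best member's mean. Two groups share a letter
    iff their pairwise comparison is non-significant at ``alpha``.
    """
    if not 0 < alpha < 1:
        raise DomainError("alpha must be in (0, 1)")
    pvals = tukey_pairwise_p(summaries)
    df_within = sum(s.n - 1 for s in summaries)
    msw = sum((s.n - 1) * s.sd**2 for s in summaries) / df_within
    if msw <= 0:
        warnings.warn(
            "zero pooled within-group variance; distinct means treated as distinct",
            stacklevel=2,
        )
    order = sorted(summaries, key=lambda s: -s.mean)
    names = [s.group for s in order]
    sig_pairs = sorted(
        (tuple(sorted(pair)) for pair, p in pvals.items() if p < alpha)
    )

    columns: list[set[str]] = [set(names)]
    for a, b in sig_pairs:
        new_columns: list[set[str]] = []
        for col in columns:
            if a in col and b in col:
                new_columns.append(col - {a})
                new_columns.append(col - {b})
            else:
                new_columns.append(col)
        # absorb: drop any column contained in another
        columns = [
            col
            for idx, col in enumerate(new_columns)
            if not any(
                col < other or (col == other and idx2 < idx)
                for idx2, other in enumerate(new_columns)
            )
        ]
    rank = {name: i for i, name in enumerate(names)}
    columns.sort(key=lambda col: min(rank[g] for g in col))
    letters = {name: "" for name in names}
    for letter_idx, col in enumerate(columns):
        letter = chr(ord("a") + letter_idx)
        for g in names:
            if g in col:
                letters[g] += letter
    return CLDResult(letters=letters, alpha=alpha)


# ---------------------------------------------------------------------------
# Regression
# ---------------------------------------------------------------------------

def pearson_regression(x, y, ci_level: float = 0.95) -> RegressionResult:
    """Least-squares line with Pearson r and its two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise DomainError("x and y must have equal length >= 3")
    if np.ptp(x) == 0:
        raise DomainError("x is constant; regression undefined")
    if np.ptp(y) == 0:
        raise DegenerateInputError("y is constant; correlation undefined")
    fit = sps.linregress(x, y)
    n = len(x)
    resid = y - (fit.slope * x + fit.intercept)
    resid_sd = float(np.sqrt((resid**2).sum() / (n - 2)))
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        p=float(fit.pvalue),
        ci_level=ci_level,
        n=n,
        x_mean=float(x.mean()),
        sxx=float(((x - x.mean()) ** 2).sum()),
        resid_sd=resid_sd,
    )


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

def _check_distance_matrix(d: np.ndarray, name: str) -> None:
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValidationError(f"{name}: distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValidationError(f"{name}: distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0):
        raise ValidationError(f"{name}: distance matrix must have a zero diagonal")


def mantel(
    d1: np.ndarray,
    d2: np.ndarray,
    n_permutations: int = 999,
    seed: int = 0,
) -> MantelResult:
    """One-sided (positive association) permutation Mantel test.

    r is the Pearson correlation of the strict upper triangles; the null is
    built by jointly permuting rows and columns of ``d2``; the p-value uses
    the add-one rule p = (1 + #{r_perm >= r_obs}) / (1 + B).
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    _check_distance_matrix(d1, "d1")
    _check_distance_matrix(d2, "d2")
    if d1.shape != d2.shape:
        raise ValidationError("distance matrices must have the same size")
    n = d1.shape[0]
    if n < 4:
        raise DomainError("need at least 4 samples for a Mantel test")
    if n_permutations < 1:
        raise DomainError("n_permutations must be >= 1")
    iu, ju = np.triu_indices(n, k=1)
    x = d1[iu, ju]
    y = d2[iu, ju]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("a distance matrix is constant off-diagonal")
    xc = x - x.mean()
    xnorm = np.sqrt((xc**2).sum())
    def corr_with_x(rows: np.ndarray) -> np.ndarray:
        rc = rows - rows.mean(axis=-1, keepdims=True)
        return (rc @ xc) / (np.sqrt((rc**2).sum(axis=-1)) * xnorm)

    r_obs = float(corr_with_x(y[None, :])[0])
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_permutations)])
    y_perm = d2[perms[:, iu], perms[:, ju]]  # (B, n_pairs)
    r_null = corr_with_x(y_perm)
    count = int(np.sum(r_null >= r_obs - 1e-12))  # ties count as >=
    p = (1 + count) / (1 + n_permutations)
    return MantelResult(r=r_obs, p=float(p), n_permutations=n_permutations, seed=seed)


# ---------------------------------------------------------------------------
# Predictor ranking
# ---------------------------------------------------------------------------

def rank_predictors(
    features,
    response,
    feature_names: list[str] | None = None,
    n_permutations: int = 99,
    seed: int = 0,
    n_estimators: int = 100,
) -> ImportanceRanking:
    """Ensemble-of-trees importance ranking with permutation significance.

    Fits a random-forest regressor, records each feature's impurity
    importance, then refits ``n_permutations`` times on a permuted response
    to build a per-feature null; p = (1 + #{null >= observed}) / (1 + B).
    Features are returned in descending importance order.
    """
    try:
        import pandas as pd

        if isinstance(features, pd.DataFrame):
            feature_names = feature_names or [str(c) for c in features.columns]
            features = features.to_numpy()
    except ImportError:  # pragma: no cover
        pass
    X = np.asarray(features, dtype=float)
    y = np.asarray(response, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise DomainError("need a 2-D feature matrix with >= 2 features")
    if X.shape[0] < 8:
        raise InsufficientReplicationError("need at least 8 rows")
    if np.ptp(y) == 0:
        raise DegenerateInputError("response is constant")
    if feature_names is None:
        feature_names = [f"x{i}" for i in range(X.shape[1])]

    rng = np.random.default_rng(seed)
    def fit_importances(target: np.ndarray, state: int) -> np.ndarray:
        model = RandomForestRegressor(
            n_estimators=n_estimators, random_state=state, n_jobs=1
        )
        model.fit(X, target)
        return model.feature_importances_

    obs = fit_importances(y, int(rng.integers(2**31 - 1)))
    null = np.empty((n_permutations, X.shape[1]))
    for b in range(n_permutations):
        y_perm = rng.permutation(y)
        null[b] = fit_importances(y_perm, int(rng.integers(2**31 - 1)))
    pvals = (1 + (null >= obs[None, :]).sum(axis=0)) / (1 + n_permutations)
    order = np.argsort(-obs, kind="stable")
    ranked = tuple(
        (feature_names[i], float(obs[i]), float(pvals[i])) for i in order
    )
    return ImportanceRanking(ranked_features=ranked)
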