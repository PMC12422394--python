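"""Cohort statistics: mixed models with Bonferroni contrasts, absolute-
agreement ICC, Pearson correlations and Fisher exact tests."""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

log = logging.getLogger(__name__)

ICC_BANDS = ((0.50, "poor"), (0.75, "moderate"), (0.90, "good"))


def bonferroni(p: float, m: int = 3) -> float:
    """Bonferroni-adjusted p value, capped at 1."""
    return min(1.0, float(p) * m)


@dataclass
class LMMResult:
    biomarker: str
    sector: str
    group_estimates: dict[str, float]
    omnibus_p: float
    pairwise_p: dict[tuple[str, str], float]  # Bonferroni-adjusted
    pairwise_p_raw: dict[tuple[str, str], float]
    random_intercept_var: float
    shapiro: dict[str, tuple[float, float]]  # group -> (W, p) on residuals
    fallback_subject_eye: bool = False


def _fit_mixedlm(y: np.ndarray, exog: np.ndarray, groups: np.ndarray,
                 reml: bool):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        model = MixedLM(y, exog, groups=groups)
        try:
            return model.fit(reml=reml)
        except np.linalg.LinAlgError:
            # variance on the boundary can leave a singular Hessian
            return model.fit(reml=reml, method="powell")


def fit_group_lmm(table: pd.DataFrame, biomarker: str,
                  sector: str = "mean", omnibus_only: bool = False) -> LMMResult:
    """Linear mixed model of one biomarker in one sector.

    Fixed effect: group; random intercept: subject (paired eyes share one).
    The omnibus group test is a likelihood-ratio test between maximum-
    likelihood fits with and without the group effect; the three pairwise
    contrasts are Wald tests Bonferroni-adjusted by 3. Shapiro-Wilk is
    reported per group on the residuals.
    """
    data = table[table["sector"] == sector].reset_index(drop=True)
    if data.empty:
        raise ValueError(f"no rows for sector {sector!r}")
    groups = sorted(data["group"].unique())
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    sizes = data["group"].value_counts()
    if (sizes < 3).any():
        raise ValueError("need >= 3 eyes per group")

    fallback = data["subject_id"].nunique() == len(data)
    if fallback:
        log.info("no paired eyes: random-intercept groups fall back to one "
                 "subject per eye")
    subj = data["subject_id"].to_numpy()
    y_raw = data[biomarker].to_numpy(dtype=float)
    if np.ptp(y_raw) == 0:
        # no variance anywhere: no group effect by construction
        const = float(y_raw[0])
        return LMMResult(
            biomarker=biomarker, sector=sector,
            group_estimates={g: const for g in groups},
            omnibus_p=1.0,
            pairwise_p={pair: 1.0 for pair in itertools.combinations(groups, 2)},
            pairwise_p_raw={pair: 1.0 for pair in itertools.combinations(groups, 2)},
            random_intercept_var=0.0,
            shapiro={g: (float("nan"), float("nan")) for g in groups},
            fallback_subject_eye=fallback)
    # standardize for numerical stability; all p values are affine-invariant
    loc = float(y_raw.mean())
    scale = float(y_raw.std()) or 1.0
    y = (y_raw - loc) / scale

    dummies = np.column_stack(
        [np.ones(len(data))]
        + [(data["group"] == g).to_numpy(dtype=float) for g in groups[1:]])
    intercept_only = dummies[:, :1]

    fit_ml = _fit_mixedlm(y, dummies, subj, reml=False)
    fit_null = _fit_mixedlm(y, intercept_only, subj, reml=False)
    lr = 2.0 * (fit_ml.llf - fit_null.llf)
    omnibus_p = float(sps.chi2.sf(max(lr, 0.0), df=len(groups) - 1))
    if omnibus_only:
        return LMMResult(biomarker=biomarker, sector=sector, group_estimates={},
                         omnibus_p=omnibus_p, pairwise_p={}, pairwise_p_raw={},
                         random_intercept_var=float("nan"), shapiro={},
                         fallback_subject_eye=fallback)

    fit = _fit_mixedlm(y, dummies, subj, reml=True)
    params = fit.fe_params
    estimates = {groups[0]: loc + scale * float(params[0])}
    for i, g in enumerate(groups[1:], start=1):
        estimates[g] = loc + scale * float(params[0] + params[i])

    k = len(params)
    pairwise_raw: dict[tuple[str, str], float] = {}
    for a, b in itertools.combinations(groups, 2):
        contrast = np.zeros(k)
        for i, g in enumerate(groups[1:], start=1):
            if g == a:
                contrast[i] += 1.0
            if g == b:
                contrast[i] -= 1.0
        est = contrast @ params
        se = float(np.sqrt(contrast @ fit.cov_params()[:k, :k] @ contrast))
        z = est / se if se > 0 else 0.0
        pairwise_raw[(a, b)] = float(2.0 * sps.norm.sf(abs(z)))
    m = len(pairwise_raw)
    pairwise = {pair: bonferroni(p, m) for pair, p in pairwise_raw.items()}

    resid = fit.resid
    shapiro: dict[str, tuple[float, float]] = {}
    for g in groups:
        r = resid[(data["group"] == g).to_numpy()]
        if len(r) >= 3 and np.ptp(r) > 0:
            w, p = sps.shapiro(r)
            shapiro[g] = (float(w), float(p))
        else:
            shapiro[g] = (float("nan"), float("nan"))

    return LMMResult(
        biomarker=biomarker, sector=sector, group_estimates=estimates,
        omnibus_p=omnibus_p, pairwise_p=pairwise, pairwise_p_raw=pairwise_raw,
        random_intercept_var=float(np.asarray(fit.cov_re).ravel()[0]) * scale ** 2,
        shapiro=shapiro, fallback_subject_eye=fallback)


@dataclass
class ICCResult:
    icc: float
    ci95: tuple[float, float]
    interpretation: str
    n: int
    defined: bool = True


def _icc_band(icc: float) -> str:
    for cutoff, name in ICC_BANDS:
        if icc < cutoff:
            return name
    return "excellent"


def icc_agreement(grader1: np.ndarray, grader2: np.ndarray,
                  alpha: float = 0.05) -> ICCResult:
    """Two-way random-effects, absolute-agreement, single-rater ICC (ICC(A,1))
    with its F-distribution 95% confidence interval, computed from the
    two-way ANOVA mean squares."""
    x = np.asarray(grader1, dtype=float)
    y = np.asarray(grader2, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("graders must be equal-length 1D vectors")
    n = len(x)
    if n < 5:
        raise ValueError("need >= 5 paired measurements")
    data = np.column_stack([x, y])
    k = 2
    if np.ptp(data) == 0:
        return ICCResult(icc=float("nan"), ci95=(float("nan"), float("nan")),
                         interpretation="undefined", n=n, defined=False)

    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err / ((n - 1) * (k - 1)), 0.0)

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0:
        return ICCResult(icc=float("nan"), ci95=(float("nan"), float("nan")),
                         interpretation="undefined", n=n, defined=False)
    icc = (msr - mse) / denom

    # McGraw & Wong F-based bounds for ICC(A,1)
    if mse > 0:
        a = k * icc / (n * (1.0 - icc)) if icc < 1 else np.inf
        b = 1.0 + k * icc * (n - 1.0) / (n * (1.0 - icc)) if icc < 1 else np.inf
        if np.isfinite(a) and np.isfinite(b):
            v = (a * msc + b * mse) ** 2 / (
                (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1)))
            f1 = sps.f.ppf(1 - alpha / 2, n - 1, v)
            f2 = sps.f.ppf(1 - alpha / 2, v, n - 1)
            lower = n * (msr - f1 * mse) / (
                f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
            upper = n * (f2 * msr - mse) / (
                k * msc + (k * n - k - n) * mse + n * f2 * msr)
        else:
            lower, upper = icc, icc
    else:
        lower, upper = icc, icc
    lower = float(min(lower, icc))
    upper = float(max(upper, icc))
    return ICCResult(icc=float(icc), ci95=(lower, upper),
                     interpretation=_icc_band(float(icc)), n=n)


def icc_consistency(grader1: np.ndarray, grader2: np.ndarray) -> float:
    """Two-way mixed, consistency, single-rater ICC (ICC(C,1)); used to
    contrast against the absolute-agreement form."""
    x = np.asarray(grader1, dtype=float)
    y = np.asarray(grader2, dtype=float)
    n = len(x)
    k = 2
    data = np.column_stack([x, y])
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_err = np.sum((data - grand) ** 2) - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    mse = max(ss_err / ((n - 1) * (k - 1)), 0.0)
    return float((msr - mse) / (msr + (k - 1) * mse))


@dataclass
class PearsonResult:
    pair: tuple[str, str]
    r: float
    p: float
    n: int
    group: str | None = None
    defined: bool = True


def pearson_matrix(table: pd.DataFrame, pairs: list[tuple[str, str]],
                   sector: str = "mean", by_group: bool = False
                   ) -> list[PearsonResult]:
    """Pearson r (two-sided p) between biomarker pairs on per-eye values of
    one sector, optionally stratified per group."""
    data = table[table["sector"] == sector]
    strata = ([(g, d) for g, d in data.groupby("group")] if by_group
              else [(None, data)])
    results: list[PearsonResult] = []
    for gname, d in strata:
        for a, b in pairs:
            sub = d[[a, b]].dropna()
            n = len(sub)
            if n < 3:
                raise ValueError(f"pair ({a}, {b}): need >= 3 complete pairs")
            xa = sub[a].to_numpy(dtype=float)
            xb = sub[b].to_numpy(dtype=float)
            if np.ptp(xa) == 0 or np.ptp(xb) == 0:
                results.append(PearsonResult(pair=(a, b), r=float("nan"),
                                             p=float("nan"), n=n, group=gname,
                                             defined=False))
                continue
            r, p = sps.pearsonr(xa, xb)
            results.append(PearsonResult(pair=(a, b), r=float(r), p=float(p),
                                         n=n, group=gname))
    return results


@dataclass
class FisherResult:
    p: float
    method: str  # "hypergeometric" | "enumeration" | "monte-carlo"


def _table_log_prob(table: np.ndarray, lgamma_cache=None) -> float:
    """Log probability of an r x c table under fixed margins (multivariate
    hypergeometric null)."""
    from scipy.special import gammaln
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = table.sum()
    return (gammaln(rows + 1).sum() + gammaln(cols + 1).sum()
            - gammaln(n + 1) - gammaln(table + 1).sum())


def _enumerate_tables(rows: np.ndarray, cols: np.ndarray):
    """Yield every nonnegative integer table with the given margins."""
    r, c = len(rows), len(cols)

    def rec(i: int, remaining_cols: np.ndarray, acc: list[np.ndarray]):
        if i == r - 1:
            yield acc + [remaining_cols.copy()]
            return
        def fill(j: int, left: int, row: np.ndarray):
            if j == c - 1:
                if left <= remaining_cols[j]:
                    row[j] = left
                    yield row.copy()
                return
            for v in range(min(left, remaining_cols[j]) + 1):
                row[j] = v
                yield from fill(j + 1, left - v, row)
        for row in fill(0, int(rows[i]), np.zeros(c, dtype=int)):
            yield from rec(i + 1, remaining_cols - row, acc + [row])

    yield from rec(0, cols.astype(int).copy(), [])


def fisher_categorical(counts: np.ndarray, max_enumeration: int = 200_000,
                       n_monte_carlo: int = 100_000,
                       seed: int = 0) -> FisherResult:
    """Fisher exact test of an r x c contingency table.

    2 x 2 tables use the closed-form hypergeometric two-sided sum; larger
    tables are solved by exhaustive enumeration over all tables with the
    observed margins when feasible, else by seeded Monte Carlo sampling of
    the null. The method used is recorded in the result.
    """
    table = np.asarray(counts)
    if table.ndim != 2:
        raise ValueError("counts must be a 2D contingency table")
    if not np.issubdtype(table.dtype, np.integer):
        if not np.allclose(table, np.round(table)):
            raise ValueError("counts must be integers")
        table = np.round(table).astype(int)
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("empty row or column in the contingency table")

    if table.shape == (2, 2):
        # two-sided: sum of hypergeometric probabilities <= P(observed)
        n = int(table.sum())
        r1 = int(rows[0])
        c1 = int(cols[0])
        support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
        probs = sps.hypergeom.pmf(support, n, r1, c1)
        p_obs = sps.hypergeom.pmf(int(table[0, 0]), n, r1, c1)
        p = float(probs[probs <= p_obs * (1 + 1e-9)].sum())
        return FisherResult(p=min(p, 1.0), method="hypergeometric")

    # rough enumeration-size bound: product of per-row composition counts
    from math import comb
    est = 1
    for r in rows:
        est *= comb(int(r) + len(cols) - 1, len(cols) - 1)
        if est > max_enumeration:
            break
    logp_obs = _table_log_prob(table)
    if est <= max_enumeration:
        total = 0.0
        for t in _enumerate_tables(rows, cols):
            lp = _table_log_prob(np.asarray(t))
            if lp <= logp_obs + 1e-9:
                total += np.exp(lp)
        return FisherResult(p=min(float(total), 1.0), method="enumeration")

    rng = np.random.default_rng([seed, 0x11A])
    hits = 0
    flat_rows = np.repeat(np.arange(len(rows)), rows)
    col_assign = np.repeat(np.arange(len(cols)), cols)
    for _ in range(n_monte_carlo):
        perm = rng.permutation(col_assign)
        t = np.zeros_like(table)
        np.add.at(t, (flat_rows, perm), 1)
        if _table_log_prob(t) <= logp_obs + 1e-9:
            hits += 1
    return FisherResult(p=(hits + 1) / (n_monte_carlo + 1), method="monte-carlo")
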