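"""Inferential layer: factorial ANOVA (parametric and aligned-rank), condition-wise
Pearson correlations with Fisher-z intervals, within-person centering, and a
random-intercept linear mixed model.

Two ANOVA computation modes are provided for balanced two-factor layouts:

* ``"pooled"`` -- ordinary two-way fixed-effects partitioning on the rows as
  given (by default one row per participant x cell after aggregation), with
  a common error term; this is the mode whose degrees of freedom match a
  participant-by-cell table (e.g. df = (2, 261) for 30 participants and a
  3 x 3 design).
* ``"repeated"`` -- full within-subject partitioning in which each effect is
  tested against its own effect-by-subject interaction.

The aligned rank transform (ART) handles non-normal responses: for each
effect the response is aligned (all estimated effects except the target are
subtracted), midranked, and the factorial ANOVA is run on the ranks, keeping
only the target effect's row.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------


@dataclass
class AnovaTable:
    """Per-effect F tests with the underlying sums of squares retained."""

    table: pd.DataFrame
    mode: str
    dv: str

    def effect(self, name: str) -> pd.Series:
        return self.table.set_index("effect").loc[name]


def _cell_aggregate(table, dv, factor_a, factor_b, unit):
    """Average replicate rows to one observation per unit x A x B cell."""
    return (
        table.groupby([unit, factor_a, factor_b], observed=True, sort=True)[dv]
        .mean()
        .reset_index()
    )


def _check_balanced(counts: np.ndarray, context: str) -> None:
    if counts.min() < 1 or counts.max() != counts.min():
        raise ValueError(f"unbalanced design in {context}: cell counts {counts.ravel()}")


def anova_two_way(
    table: pd.DataFrame,
    dv: str,
    factor_a: str,
    factor_b: str,
    unit: str = "participant",
    mode: str = "pooled",
    aggregate: bool = True,
) -> AnovaTable:
    """Balanced two-way ANOVA with partial and generalized eta squared.

    With ``aggregate=True`` replicate rows within a unit x cell (e.g. the
    three rhythmic patterns) are averaged first.  ``mode="pooled"`` treats the
    resulting rows as independent; ``mode="repeated"`` partitions subject
    variance and tests each effect against its own interaction with subjects.
    """
    if mode not in ("pooled", "repeated"):
        raise ValueError(f"unknown mode {mode!r}")
    data = _cell_aggregate(table, dv, factor_a, factor_b, unit) if aggregate else table
    data = data[[unit, factor_a, factor_b, dv]].dropna()

    a_levels = list(pd.unique(data[factor_a]))
    b_levels = list(pd.unique(data[factor_b]))
    na, nb = len(a_levels), len(b_levels)
    if na < 2 or nb < 2:
        raise ValueError("both factors need at least two levels")

    y = data[dv].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("all observations are equal: zero variance")
    grand = y.mean()
    ss_total = float(np.sum((y - grand) ** 2))

    a_means = data.groupby(factor_a, observed=True)[dv].mean()
    b_means = data.groupby(factor_b, observed=True)[dv].mean()
    cell_means = data.groupby([factor_a, factor_b], observed=True)[dv].mean()
    cell_counts = data.groupby([factor_a, factor_b], observed=True)[dv].count()
    _check_balanced(cell_counts.to_numpy(), f"{factor_a} x {factor_b}")
    r = int(cell_counts.iloc[0])  # replicates per cell

    ss_a = r * nb * float(np.sum((a_means - grand) ** 2))
    ss_b = r * na * float(np.sum((b_means - grand) ** 2))
    ss_ab = 0.0
    for (ai, bi), m in cell_means.items():
        ss_ab += (m - a_means[ai] - b_means[bi] + grand) ** 2
    ss_ab *= r
    df_a, df_b, df_ab = na - 1, nb - 1, (na - 1) * (nb - 1)

    rows = []
    if mode == "pooled":
        ss_err = ss_total - ss_a - ss_b - ss_ab
        df_err = len(y) - na * nb
        if df_err <= 0:
            raise ValueError("no residual degrees of freedom in pooled mode")
        ms_err = ss_err / df_err
        if ms_err <= 0:
            raise ValueError("zero error variance")
        for name, ss_e, df_e in (
            (factor_a, ss_a, df_a),
            (factor_b, ss_b, df_b),
            (f"{factor_a}:{factor_b}", ss_ab, df_ab),
        ):
            f_val = (ss_e / df_e) / ms_err
            rows.append(
                {
                    "effect": name,
                    "df1": df_e,
                    "df2": df_err,
                    "SS": ss_e,
                    "SS_error": ss_err,
                    "F": f_val,
                    "p": float(sps.f.sf(f_val, df_e, df_err)),
                    "eta_p2": ss_e / (ss_e + ss_err),
                    "eta_g2": ss_e / (ss_e + ss_err),
                }
            )
    else:
        per_unit_cell = data.groupby([unit, factor_a, factor_b], observed=True)[dv].count()
        if per_unit_cell.max() != 1:
            raise ValueError(
                "repeated mode expects one observation per unit x cell "
                "(use aggregate=True to average replicates)"
            )
        subjects = list(pd.unique(data[unit]))
        ns = len(subjects)
        if ns < 2:
            raise ValueError("repeated mode needs at least two subjects")
        s_means = data.groupby(unit, observed=True)[dv].mean()
        ss_s = na * nb * float(np.sum((s_means - grand) ** 2))
        as_means = data.groupby([factor_a, unit], observed=True)[dv].mean()
        ss_as = 0.0
        for (ai, si), m in as_means.items():
            ss_as += (m - a_means[ai] - s_means[si] + grand) ** 2
        ss_as *= nb
        bs_means = data.groupby([factor_b, unit], observed=True)[dv].mean()
        ss_bs = 0.0
        for (bi, si), m in bs_means.items():
            ss_bs += (m - b_means[bi] - s_means[si] + grand) ** 2
        ss_bs *= na
        ss_abs = ss_total - ss_a - ss_b - ss_ab - ss_s - ss_as - ss_bs
        df_as, df_bs = df_a * (ns - 1), df_b * (ns - 1)
        df_abs = df_ab * (ns - 1)
        noise_ss = ss_s + ss_as + ss_bs + ss_abs
        for name, ss_e, df_e, ss_err, df_err in (
            (factor_a, ss_a, df_a, ss_as, df_as),
            (factor_b, ss_b, df_b, ss_bs, df_bs),
            (f"{factor_a}:{factor_b}", ss_ab, df_ab, ss_abs, df_abs),
        ):
            if ss_err <= 0 or df_err <= 0:
                raise ValueError("zero error variance")
            f_val = (ss_e / df_e) / (ss_err / df_err)
            rows.append(
                {
                    "effect": name,
                    "df1": df_e,
                    "df2": df_err,
                    "SS": ss_e,
                    "SS_error": ss_err,
                    "F": f_val,
                    "p": float(sps.f.sf(f_val, df_e, df_err)),
                    "eta_p2": ss_e / (ss_e + ss_err),
                    "eta_g2": ss_e / (ss_e + noise_ss),
                }
            )
    return AnovaTable(table=pd.DataFrame(rows), mode=mode, dv=dv)


def art_anova(
    table: pd.DataFrame,
    dv: str,
    factor_a: str,
    factor_b: str,
    unit: str = "participant",
    mode: str = "pooled",
    aggregate: bool = True,
) -> AnovaTable:
    """Aligned rank transform ANOVA for a two-factor layout.

    For each effect: subtract every estimated effect except the target from
    the response (alignment, built from cell means), rank the aligned values
    with midranks, run the factorial ANOVA on the ranks, and keep only the
    target effect's row.
    """
    data = _cell_aggregate(table, dv, factor_a, factor_b, unit) if aggregate else table
    data = data[[unit, factor_a, factor_b, dv]].dropna().reset_index(drop=True)

    grand = data[dv].mean()
    a_eff = data.groupby(factor_a, observed=True)[dv].mean() - grand
    b_eff = data.groupby(factor_b, observed=True)[dv].mean() - grand
    cell_mean = data.groupby([factor_a, factor_b], observed=True)[dv].mean()
    resid = data[dv].to_numpy() - cell_mean.loc[
        list(zip(data[factor_a], data[factor_b]))
    ].to_numpy()

    effects = {
        factor_a: a_eff.loc[data[factor_a]].to_numpy(),
        factor_b: b_eff.loc[data[factor_b]].to_numpy(),
        f"{factor_a}:{factor_b}": (
            cell_mean.loc[list(zip(data[factor_a], data[factor_b]))].to_numpy()
            - a_eff.loc[data[factor_a]].to_numpy()
            - b_eff.loc[data[factor_b]].to_numpy()
            - grand
        ),
    }

    rows = []
    for name, target in effects.items():
        aligned = resid + target
        ranked = data.copy()
        ranked[dv] = sps.rankdata(aligned, method="average")
        sub = anova_two_way(
            ranked, dv, factor_a, factor_b, unit=unit, mode=mode, aggregate=False
        )
        row = sub.table.set_index("effect").loc[name].to_dict()
        row["effect"] = name
        row["aligned_grand_mean"] = float(np.mean(aligned))
        rows.append(row)
    return AnovaTable(table=pd.DataFrame(rows), mode=f"art-{mode}", dv=dv)


def normality_violated(
    table: pd.DataFrame,
    dv: str,
    factor_a: str,
    factor_b: str,
    alpha: float = 0.05,
) -> bool:
    """Shapiro-Wilk gate on within-cell residuals (configurable alpha)."""
    resid = (
        table[dv]
        - table.groupby([factor_a, factor_b], observed=True)[dv].transform("mean")
    ).to_numpy()
    resid = resid[np.isfinite(resid)]
    if resid.size < 3 or np.ptp(resid) == 0:
        return False
    return bool(sps.shapiro(resid).pvalue < alpha)


def posthoc_pairwise(
    table: pd.DataFrame,
    dv: str,
    factor: str,
    unit: str = "participant",
    method: str = "holm",
) -> pd.DataFrame:
    """Paired t-tests between factor levels with Holm (default) or Bonferroni
    correction of the family-wise error rate."""
    if method not in ("holm", "bonferroni"):
        raise ValueError("method must be 'holm' or 'bonferroni'")
    means = (
        table.groupby([unit, factor], observed=True)[dv].mean().unstack(factor)
    )
    levels = list(means.columns)
    raw = []
    for a, b in itertools.combinations(levels, 2):
        res = sps.ttest_rel(means[a], means[b], nan_policy="omit")
        raw.append({"level_a": a, "level_b": b, "t": float(res.statistic), "p_raw": float(res.pvalue)})
    out = pd.DataFrame(raw)
    m = len(out)
    if method == "bonferroni":
        out["p_adj"] = np.minimum(out["p_raw"] * m, 1.0)
    else:
        order = np.argsort(out["p_raw"].to_numpy())
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * out["p_raw"].iloc[idx])
            adj[idx] = min(running, 1.0)
        out["p_adj"] = adj
    return out


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson r with two-sided t-test p and Fisher-z confidence interval."""

    r: float
    n: int
    p: float
    ci_low: float
    ci_high: float
    alpha: float = 0.05


def correlation_with_ci(x, y, alpha: float = 0.05) -> CorrelationResult:
    """Pearson correlation with the classical small-sample inference.

    p is two-sided from ``t = r * sqrt((n-2)/(1-r^2))`` on n-2 df; the CI is
    the Fisher-z interval ``tanh(atanh(r) +/- z_{1-a/2}/sqrt(n-3))``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")
    r = float(np.corrcoef(x, y)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0 - 1e-15:
        r = 1.0 if r > 0 else -1.0
        p = 0.0
        ci_low, ci_high = (1.0, 1.0) if r > 0 else (-1.0, -1.0)
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2 * sps.t.sf(abs(t), n - 2))
        z = np.arctanh(r)
        hw = sps.norm.ppf(1 - alpha / 2) / np.sqrt(n - 3)
        ci_low, ci_high = float(np.tanh(z - hw)), float(np.tanh(z + hw))
    return CorrelationResult(r=r, n=n, p=p, ci_low=ci_low, ci_high=ci_high, alpha=alpha)


def conditionwise_correlations(
    trial_table: pd.DataFrame,
    rating_cols: tuple[str, ...] = ("urge", "pleasure"),
    plv_cols: tuple[str, ...] = ("plv1", "plv2"),
    by: tuple[str, str] = ("movement", "syncopation"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlations for every (movement x syncopation) cell and every
    rating-synchrony pair, mirroring the published tables' layout.

    Empty or too-small cells are flagged in the ``ok`` column rather than
    silently dropped.
    """
    rows = []
    for (cond, level), cell in trial_table.groupby(list(by), observed=True, sort=False):
        for rating in rating_cols:
            for plv_col in plv_cols:
                sub = cell[[rating, plv_col]].dropna()
                base = {by[0]: cond, by[1]: level, "rating": rating, "plv": plv_col}
                try:
                    res = correlation_with_ci(sub[rating], sub[plv_col], alpha=alpha)
                    rows.append(
                        base
                        | {
                            "r": res.r,
                            "n": res.n,
                            "p": res.p,
                            "ci_low": res.ci_low,
                            "ci_high": res.ci_high,
                            "ok": True,
                        }
                    )
                except ValueError as exc:
                    rows.append(
                        base
                        | {
                            "r": np.nan,
                            "n": len(sub),
                            "p": np.nan,
                            "ci_low": np.nan,
                            "ci_high": np.nan,
                            "ok": False,
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# within-person centering and the random-intercept model
# ---------------------------------------------------------------------------


def center_within(
    table: pd.DataFrame, predictor: str, unit: str = "participant"
) -> pd.DataFrame:
    """Split a trial-level predictor into within- and between-person columns.

    ``<predictor>_between`` is the participant mean; ``<predictor>_within``
    the trial's deviation from it (summing to zero within each participant).
    """
    out = table.copy()
    mean = out.groupby(unit, observed=True)[predictor].transform("mean")
    out[f"{predictor}_between"] = mean
    out[f"{predictor}_within"] = out[predictor] - mean
    return out


@dataclass
class LmmFit:
    """Maximum-likelihood fit of a random-intercept linear mixed model."""

    params: pd.Series
    se: pd.Series
    z: pd.Series
    p: pd.Series
    sigma_b: float
    sigma: float
    loglik: float
    converged: bool
    at_boundary: bool
    n_obs: int
    n_groups: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"estimate": self.params, "se": self.se, "z": self.z, "p": self.p}
        )


def fit_random_intercept(
    table: pd.DataFrame,
    dv: str,
    formula: str,
    unit: str = "participant",
) -> LmmFit:
    """ML fit of ``dv ~ formula + (1 | unit)`` by profiling.

    The residual variance is profiled out and the likelihood reduced to a
    one-dimensional search over the variance ratio ``theta = sigma_b^2 /
    sigma^2``; at each theta the fixed effects have a closed generalized
    least squares form (the per-group inverse of ``I + theta * J`` is
    analytic).  Wald z tests are reported for the fixed effects.
    """
    from patsy import dmatrix

    data = table.dropna(subset=[dv]).reset_index(drop=True)
    design = dmatrix(formula, data, return_type="dataframe")
    keep = design.notna().all(axis=1)
    design, data = design.loc[keep], data.loc[keep]
    y = data[dv].to_numpy(dtype=float)
    x = design.to_numpy(dtype=float)
    names = list(design.columns)
    groups = data[unit].to_numpy()
    uniq, inv = np.unique(groups, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("need at least two participants")
    sizes = np.bincount(inv)
    if np.sum(sizes >= 2) < 2:
        raise ValueError("need at least two participants with two or more trials")
    n, q = x.shape

    order = np.argsort(inv, kind="stable")
    xo, yo, go = x[order], y[order], inv[order]
    bounds = np.concatenate(([0], np.cumsum(sizes)))

    def _gls(theta: float):
        """Closed-form GLS pieces at a given variance ratio."""
        xtvx = np.zeros((q, q))
        xtvy = np.zeros(q)
        ytvy = 0.0
        logdet = 0.0
        for g in range(len(uniq)):
            sl = slice(bounds[g], bounds[g + 1])
            ni = bounds[g + 1] - bounds[g]
            xi, yi = xo[sl], yo[sl]
            w = theta / (1.0 + theta * ni)
            sx, sy = xi.sum(axis=0), yi.sum()
            xtvx += xi.T @ xi - w * np.outer(sx, sx)
            xtvy += xi.T @ yi - w * sx * sy
            ytvy += yi @ yi - w * sy * sy
            logdet += np.log1p(theta * ni)
        return xtvx, xtvy, ytvy, logdet

    def _profile_nll(theta: float) -> float:
        xtvx, xtvy, ytvy, logdet = _gls(theta)
        try:
            beta = np.linalg.solve(xtvx, xtvy)
        except np.linalg.LinAlgError:
            return np.inf
        rss = ytvy - 2 * beta @ xtvy + beta @ xtvx @ beta
        if rss <= 0:
            return np.inf
        sigma2 = rss / n
        return 0.5 * (n * np.log(sigma2) + logdet + n * (1 + np.log(2 * np.pi)))

    res = optimize.minimize_scalar(
        lambda lt: _profile_nll(np.exp(lt)), bounds=(-14.0, 10.0), method="bounded",
        options={"xatol": 1e-10},
    )
    theta_hat = float(np.exp(res.x))
    nll_hat = _profile_nll(theta_hat)
    nll_zero = _profile_nll(0.0)
    at_boundary = False
    if nll_zero <= nll_hat + 1e-9 or theta_hat < 1e-7:
        theta_hat, nll_hat, at_boundary = 0.0, nll_zero, True

    xtvx, xtvy, ytvy, _ = _gls(theta_hat)
    beta = np.linalg.solve(xtvx, xtvy)
    rss = ytvy - 2 * beta @ xtvy + beta @ xtvx @ beta
    sigma2 = rss / n
    cov = sigma2 * np.linalg.inv(xtvx)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    p = 2 * sps.norm.sf(np.abs(z))
    idx = pd.Index(names)
    return LmmFit(
        params=pd.Series(beta, index=idx),
        se=pd.Series(se, index=idx),
        z=pd.Series(z, index=idx),
        p=pd.Series(p, index=idx),
        sigma_b=float(np.sqrt(theta_hat * sigma2)),
        sigma=float(np.sqrt(sigma2)),
        loglik=-nll_hat,
        converged=bool(res.success),
        at_boundary=at_boundary,
        n_obs=n,
        n_groups=len(uniq),
    )
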