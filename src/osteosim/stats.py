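"""Statistical analysis of the inclination-angle experiment.

Implements the repeated-measures workflow: one-way within-subject ANOVA
per arm with Mauchly's sphericity test and Huynh-Feldt correction,
Bonferroni pairwise comparisons, paired t-tests against the
pre-osteotomy slope, and a linear mixed model (per-subject random
intercept, residuals either independent or AR(1) across the ordered
inclination levels) fitted by REML, with AIC/BIC model selection.

The ANOVA/Mauchly/epsilon computations are coded directly from the
classical formulas; the test suite cross-checks them against pingouin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import minimize

__all__ = [
    "ANGLE_GRID",
    "AnovaResult",
    "PairedResult",
    "LmmResult",
    "validate_long_table",
    "arm_table",
    "rm_anova",
    "paired_vs_preop",
    "fit_inclination_lmm",
    "build_report",
]

ANGLE_GRID = tuple(range(-30, 31, 5))

LONG_COLUMNS = ("subject_id", "inclination_deg", "pts_deg", "pts_change_deg")


class ValidationError(ValueError):
    pass


# ---------------------------------------------------------------------- #
# long table plumbing
# ---------------------------------------------------------------------- #
def validate_long_table(table: pd.DataFrame,
                        angles: tuple[int, ...] = ANGLE_GRID) -> pd.DataFrame:
    for c in LONG_COLUMNS:
        if c not in table.columns:
            raise ValidationError(f"long table missing column {c!r}")
    counts = table.groupby("subject_id")["inclination_deg"].agg(
        lambda s: tuple(sorted(s)))
    expect = tuple(sorted(angles))
    bad = counts[counts != expect]
    if len(bad):
        raise ValidationError(
            f"unbalanced long table for subjects {list(bad.index)[:5]}")
    return table


def arm_table(table: pd.DataFrame, direction: str) -> pd.DataFrame:
    """Restrict to one arm: anterior = inclinations 0..+30, posterior =
    0..-30 (both arms include the parallel osteotomy)."""
    if direction == "anterior":
        sel = table["inclination_deg"] >= 0
    elif direction == "posterior":
        sel = table["inclination_deg"] <= 0
    else:
        raise ValidationError(f"direction must be anterior/posterior, "
                              f"got {direction!r}")
    return table.loc[sel].copy()


def _wide(table: pd.DataFrame, value: str = "pts_deg") -> pd.DataFrame:
    wide = table.pivot(index="subject_id", columns="inclination_deg",
                       values=value)
    if wide.isna().any().any():
        raise ValidationError("incomplete subject x angle table")
    return wide.reindex(sorted(wide.columns, key=abs), axis=1)


# ---------------------------------------------------------------------- #
# repeated-measures ANOVA
# ---------------------------------------------------------------------- #
@dataclass
class AnovaResult:
    f_stat: float
    df1: float
    df2: float
    p_value: float          # uncorrected
    mauchly_w: float
    mauchly_p: float
    gg_epsilon: float
    hf_epsilon: float
    corrected_p: float      # Huynh-Feldt corrected when sphericity fails
    sphericity_alpha: float
    levels: tuple
    pairwise_p: pd.DataFrame = field(repr=False, default=None)


def _mauchly(Y: np.ndarray) -> tuple[float, float]:
    """Mauchly's W and its chi-square approximation p-value."""
    n, k = Y.shape
    C = _helmert(k)
    S = np.cov(Y, rowvar=False, ddof=1)
    A = C @ S @ C.T
    eig = np.linalg.eigvalsh(A)
    eig = np.clip(eig, 1e-300, None)
    W = float(np.prod(eig) / (np.mean(eig) ** (k - 1)))
    d = k - 1
    df = d * (d + 1) // 2 - 1
    f = 1.0 - (2 * d ** 2 + d + 2) / (6.0 * d * (n - 1))
    chi2 = -(n - 1) * f * np.log(max(W, 1e-300))
    # second-order term of the chi-square approximation (as in SPSS/ezANOVA)
    w2 = ((d + 2) * (d - 1) * (d - 2) * (2 * d ** 3 + 6 * d ** 2 + 3 * k + 2)
          / (288.0 * ((n - 1) * d * f) ** 2))
    p1 = sps.chi2.sf(chi2, df)
    p2 = sps.chi2.sf(chi2, df + 4)
    p = float(p1 + w2 * (p2 - p1))
    return W, p


def _helmert(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast matrix."""
    H = np.zeros((k - 1, k))
    for i in range(1, k):
        H[i - 1, :i] = 1.0
        H[i - 1, i] = -i
        H[i - 1] /= np.linalg.norm(H[i - 1])
    return H


def _epsilons(Y: np.ndarray) -> tuple[float, float]:
    """Greenhouse-Geisser and Huynh-Feldt epsilons."""
    n, k = Y.shape
    C = _helmert(k)
    S = np.cov(Y, rowvar=False, ddof=1)
    A = C @ S @ C.T
    d = k - 1
    gg = float(np.trace(A) ** 2 / (d * np.trace(A @ A)))
    hf = (n * d * gg - 2.0) / (d * (n - 1.0 - d * gg))
    return gg, float(min(hf, 1.0))


def rm_anova(table: pd.DataFrame, direction: str,
             value: str = "pts_deg",
             sphericity_alpha: float = 0.05) -> AnovaResult:
    """One-way within-subject ANOVA over the 7 inclination levels of one
    arm, with sphericity handling and Bonferroni pairwise comparisons.

    The Huynh-Feldt correction is applied to the reported
    ``corrected_p`` when Mauchly's test rejects at ``sphericity_alpha``.
    """
    arm = arm_table(table, direction)
    validate_long_table(arm, tuple(sorted(arm["inclination_deg"].unique())))
    wide = _wide(arm, value)
    Y = wide.to_numpy(dtype=float)
    n, k = Y.shape
    if n < 3 or k < 2:
        raise ValidationError("need >= 3 subjects and >= 2 levels")

    grand = Y.mean()
    subj_means = Y.mean(axis=1)
    level_means = Y.mean(axis=0)
    ss_levels = n * np.sum((level_means - grand) ** 2)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_total = np.sum((Y - grand) ** 2)
    ss_err = ss_total - ss_levels - ss_subj
    df1 = k - 1
    df2 = (n - 1) * (k - 1)
    ms_levels = ss_levels / df1
    ms_err = ss_err / df2
    F = ms_levels / ms_err
    p = float(sps.f.sf(F, df1, df2))

    W, mp = _mauchly(Y)
    gg, hf = _epsilons(Y)
    if mp < sphericity_alpha:
        corrected = float(sps.f.sf(F, df1 * hf, df2 * hf))
    else:
        corrected = p

    levels = tuple(wide.columns)
    m = len(levels)
    n_pairs = m * (m - 1) // 2
    padj = np.full((m, m), np.nan)
    for i in range(m):
        for j in range(i + 1, m):
            t, praw = sps.ttest_rel(Y[:, i], Y[:, j])
            padj[i, j] = padj[j, i] = min(1.0, praw * n_pairs)
    pairwise = pd.DataFrame(padj, index=levels, columns=levels)

    return AnovaResult(f_stat=float(F), df1=float(df1), df2=float(df2),
                       p_value=p, mauchly_w=W, mauchly_p=mp,
                       gg_epsilon=gg, hf_epsilon=hf, corrected_p=corrected,
                       sphericity_alpha=sphericity_alpha,
                       levels=levels, pairwise_p=pairwise)


# ---------------------------------------------------------------------- #
# paired t-tests vs. pre-op
# ---------------------------------------------------------------------- #
@dataclass
class PairedResult:
    inclination_deg: int
    t_stat: float
    p_value: float
    mean_diff: float
    degenerate: bool = False


def paired_vs_preop(table: pd.DataFrame, pre: pd.Series) -> list[PairedResult]:
    """Paired t-test of post-osteotomy slope vs. pre-op slope, per angle.

    ``pre`` maps subject_id -> pre-op slope. Zero-variance differences
    are flagged as degenerate rather than producing spurious statistics.
    """
    validate_long_table(table, tuple(sorted(table["inclination_deg"].unique())))
    results = []
    for ang, grp in table.groupby("inclination_deg"):
        grp = grp.set_index("subject_id")
        missing = set(grp.index) - set(pre.index)
        if missing:
            raise ValidationError(f"missing pre-op values for {sorted(missing)[:5]}")
        post = grp["pts_deg"]
        diff = post - pre.loc[post.index]
        if np.std(diff.to_numpy(), ddof=1) < 1e-12:
            mean = float(diff.mean())
            results.append(PairedResult(int(ang),
                                        t_stat=0.0 if mean == 0 else np.inf,
                                        p_value=1.0 if mean == 0 else 0.0,
                                        mean_diff=mean, degenerate=True))
            continue
        t, p = sps.ttest_rel(post.to_numpy(), pre.loc[post.index].to_numpy())
        results.append(PairedResult(int(ang), float(t), float(p),
                                    float(diff.mean())))
    return sorted(results, key=lambda r: r.inclination_deg)


# ---------------------------------------------------------------------- #
# linear mixed model: random intercept, optional AR(1) residuals
# ---------------------------------------------------------------------- #
@dataclass
class LmmResult:
    beta: float                 # slope of pts change per degree
    se: float
    p_value: float
    intercept: float
    aic: float
    bic: float
    covariance_structure: str   # "random-intercept" or "random-intercept+AR1"
    rho: float                  # AR(1) parameter (0 for independent)
    tau2: float                 # random-intercept variance
    sigma2: float               # residual variance
    candidates: dict = field(repr=False, default_factory=dict)


def _group_index_lists(groups: np.ndarray, order: np.ndarray) -> list[np.ndarray]:
    out = []
    for g in np.unique(groups):
        idx = np.where(groups == g)[0]
        out.append(idx[np.argsort(order[idx])])
    return out


def _gls_pieces(tau2: float, sig2: float, rho: float, X: np.ndarray,
                y: np.ndarray, idx_lists: list[np.ndarray]
                ) -> tuple[float, np.ndarray, np.ndarray, float] | None:
    """(sum log|V_i|, X'V^-1X, X'V^-1y, y'V^-1y); None if V is not PD.

    Balanced designs share one V across subjects, which keeps repeated
    REML evaluations cheap.
    """
    sizes = {len(i) for i in idx_lists}
    if len(sizes) == 1:  # balanced: one shared V, fully vectorized
        k = sizes.pop()
        lag = np.abs(np.subtract.outer(np.arange(k), np.arange(k)))
        V = tau2 + sig2 * rho ** lag
        try:
            L = np.linalg.cholesky(V)
            Vinv = np.linalg.inv(V)
        except np.linalg.LinAlgError:
            return None
        if not np.all(np.isfinite(Vinv)):
            return None
        ld = 2.0 * np.log(np.diag(L)).sum()
        idx = np.asarray(idx_lists)
        Xs, ys = X[idx], y[idx]          # (g, k, p), (g, k)
        VX = np.einsum("ij,gjp->gip", Vinv, Xs)
        XtVX = np.einsum("gip,giq->pq", Xs, VX)
        Vy = ys @ Vinv.T
        XtVy = np.einsum("gip,gi->p", Xs, Vy)
        ytVy = float(np.einsum("gi,gi->", ys, Vy))
        return ld * len(idx_lists), XtVX, XtVy, ytVy
    logdet = 0.0
    XtVX = np.zeros((X.shape[1], X.shape[1]))
    XtVy = np.zeros(X.shape[1])
    ytVy = 0.0
    for idx in idx_lists:
        k = len(idx)
        lag = np.abs(np.subtract.outer(np.arange(k), np.arange(k)))
        V = tau2 + sig2 * rho ** lag
        try:
            L = np.linalg.cholesky(V)
            Xi, yi = X[idx], y[idx]
            sol = np.linalg.solve(V, np.column_stack([Xi, yi]))
        except np.linalg.LinAlgError:
            return None
        logdet += 2.0 * np.log(np.diag(L)).sum()
        XtVX += Xi.T @ sol[:, :-1]
        XtVy += Xi.T @ sol[:, -1]
        ytVy += yi @ sol[:, -1]
    return logdet, XtVX, XtVy, ytVy


#: keeps the variance-ratio search inside the numerically invertible
#: range (lambda = tau2/sigma2 can diverge on noise-free data)
_LOG_LAMBDA_BOUND = 16.0


def _neg2_reml_profiled(theta: np.ndarray, X: np.ndarray, y: np.ndarray,
                        idx_lists: list[np.ndarray], ar1: bool) -> float:
    """-2 REML with the residual scale profiled out.

    theta = (log lambda[, atanh rho]) with lambda = tau2/sigma2; the
    common scale s has the closed-form optimum rss/(n-p).
    """
    if abs(theta[0]) > _LOG_LAMBDA_BOUND:
        return 1e12 + 1e10 * (abs(theta[0]) - _LOG_LAMBDA_BOUND)
    if ar1 and abs(theta[1]) > 5.0:  # |rho| < 0.9999
        return 1e12 + 1e10 * (abs(theta[1]) - 5.0)
    lam = np.exp(theta[0])
    rho = np.tanh(theta[1]) if ar1 else 0.0
    pieces = _gls_pieces(lam, 1.0, rho, X, y, idx_lists)
    if pieces is None:
        return 1e12
    logdet, XtVX, XtVy, ytVy = pieces
    try:
        beta = np.linalg.solve(XtVX, XtVy)
    except np.linalg.LinAlgError:
        return 1e12
    rss = max(ytVy - XtVy @ beta, 1e-300)
    sign, logdet_XtVX = np.linalg.slogdet(XtVX)
    if sign <= 0:
        return 1e12
    n, p = X.shape
    s_hat = rss / (n - p)
    val = float(logdet + logdet_XtVX
                + (n - p) * (np.log(s_hat) + 1.0 + np.log(2 * np.pi)))
    return val if np.isfinite(val) else 1e12


def _fit_structure(X, y, groups, order, ar1: bool) -> dict:
    idx_lists = _group_index_lists(groups, order)
    nparam = 3 if ar1 else 2  # tau2, sigma2 (+ rho)
    best = None
    starts = ([np.array([0.0, 0.0]), np.array([-3.0, 0.5]),
               np.array([2.0, -0.3])] if ar1
              else [np.array([0.0]), np.array([-3.0]), np.array([2.0])])
    for x0 in starts:
        res = minimize(_neg2_reml_profiled, x0, args=(X, y, idx_lists, ar1),
                       method="Nelder-Mead",
                       options={"xatol": 1e-9, "fatol": 1e-11,
                                "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    theta = best.x
    theta[0] = np.clip(theta[0], -_LOG_LAMBDA_BOUND, _LOG_LAMBDA_BOUND)
    lam = float(np.exp(theta[0]))
    rho = float(np.tanh(theta[1])) if ar1 else 0.0
    # recover the profiled scale
    pieces = _gls_pieces(lam, 1.0, rho, X, y, idx_lists)
    logdet0, XtVX0, XtVy0, ytVy0 = pieces
    beta0 = np.linalg.solve(XtVX0, XtVy0)
    n, p = X.shape
    s_hat = float(max(ytVy0 - XtVy0 @ beta0, 1e-300) / (n - p))
    sig2 = s_hat
    tau2 = lam * s_hat

    # GLS fixed effects at the optimum
    _, XtVX, XtVy, _ = _gls_pieces(tau2, sig2, rho, X, y, idx_lists)
    cov = np.linalg.inv(XtVX)
    beta = cov @ XtVy
    n, p = X.shape
    q = nparam
    neg2 = float(best.fun)
    return {
        "beta": beta, "cov": cov, "tau2": tau2, "sigma2": sig2, "rho": rho,
        "neg2_reml": neg2,
        "aic": neg2 + 2 * q,
        "bic": neg2 + q * np.log(n - p),
        "df": n - len(np.unique(groups)) - (p - 1),
    }


def fit_inclination_lmm(table: pd.DataFrame, direction: str,
                        value: str = "pts_change_deg",
                        criterion: str = "aic") -> LmmResult:
    """Slope of the change in posterior slope per degree of inclination.

    Fits ``value ~ 1 + |inclination|`` with a per-subject random
    intercept, under independent and AR(1) residual covariance (levels
    ordered by |inclination|, equally spaced), both by REML; reports the
    model preferred by the chosen information criterion. The regressor is
    |inclination| so that both arms report the magnitude of change per
    degree of (increasing or decreasing) inclination, matching the
    reporting convention of the analysis this reproduces.
    """
    arm = arm_table(table, direction)
    if arm.empty:
        raise ValidationError("empty arm")
    x = np.abs(arm["inclination_deg"].to_numpy(dtype=float))
    y = arm[value].to_numpy(dtype=float)
    subjects, groups = np.unique(arm["subject_id"].to_numpy(), return_inverse=True)
    X = np.column_stack([np.ones_like(x), x])
    order = x  # AR(1) lags follow the ordered inclination levels

    fits = {"random-intercept": _fit_structure(X, y, groups, order, ar1=False),
            "random-intercept+AR1": _fit_structure(X, y, groups, order, ar1=True)}
    key = "aic" if criterion == "aic" else "bic"
    chosen = min(fits, key=lambda k: fits[k][key])
    f = fits[chosen]
    beta = float(f["beta"][1])
    se = float(np.sqrt(f["cov"][1, 1]))
    if se <= 0 or not np.isfinite(se):
        raise RuntimeError("mixed-model fit produced invalid standard error")
    df = max(f["df"], 1)
    p = float(2 * sps.t.sf(abs(beta) / se, df)) if se > 0 else 0.0
    return LmmResult(beta=beta, se=se, p_value=p,
                     intercept=float(f["beta"][0]),
                     aic=float(f["aic"]), bic=float(f["bic"]),
                     covariance_structure=chosen, rho=float(f["rho"]),
                     tau2=float(f["tau2"]), sigma2=float(f["sigma2"]),
                     candidates={k: {kk: (float(vv) if np.isscalar(vv) or
                                          isinstance(vv, (int, float)) else None)
                                     for kk, vv in v.items()
                                     if kk in ("neg2_reml", "aic", "bic",
                                               "tau2", "sigma2", "rho")}
                                 for k, v in fits.items()})


# ---------------------------------------------------------------------- #
# report bundle
# ---------------------------------------------------------------------- #
def build_report(table: pd.DataFrame, pre: pd.Series,
                 sphericity_alpha: float = 0.05) -> dict:
    """Assemble the per-angle summary, both ANOVA arms, the paired tests
    and both mixed-model slopes into one machine-readable bundle.

    On reduced angle grids the inferential pieces that need more levels
    are omitted (set to None) rather than failing.
    """
    angles = tuple(sorted(table["inclination_deg"].unique()))
    validate_long_table(table, angles)

    summary = (table.groupby("inclination_deg")
               .agg(pts_mean=("pts_deg", "mean"), pts_sd=("pts_deg", "std"),
                    change_mean=("pts_change_deg", "mean"),
                    change_sd=("pts_change_deg", "std"))
               .reset_index()
               .sort_values("inclination_deg", ascending=False))

    n_subjects = table["subject_id"].nunique()

    def arm_levels(d):
        return arm_table(table, d)["inclination_deg"].nunique()

    anova = {d: (rm_anova(table, d, sphericity_alpha=sphericity_alpha)
                 if arm_levels(d) >= 2 and n_subjects >= 3 else None)
             for d in ("anterior", "posterior")}
    paired = (paired_vs_preop(table, pre) if n_subjects >= 2 else [])
    lmm = {d: (fit_inclination_lmm(table, d)
               if arm_levels(d) >= 2 and n_subjects >= 2 else None)
           for d in ("anterior", "posterior")}

    # scatter/CI data: per-angle mean change with 95% CI of the mean
    n = n_subjects
    scatter = (table.groupby("inclination_deg")["pts_change_deg"]
               .agg(["mean", "std"]).reset_index())
    scatter["ci95_half"] = (sps.t.ppf(0.975, n - 1) * scatter["std"] / np.sqrt(n)
                            if n >= 2 else np.nan)

    return {"summary": summary, "anova": anova, "paired": paired,
            "lmm": lmm, "scatter": scatter}
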