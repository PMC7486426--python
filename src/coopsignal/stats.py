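"""Statistical pipeline: every analysis the behavioral study reports.

Implemented from first principles on top of numpy/scipy distributions:

* between-subjects factorial ANOVA with Type III sums of squares
  (sum-to-zero effects coding; cells may be unbalanced) and Bonferroni
  pairwise post-hoc comparisons;
* partial eta-squared effect sizes;
* single-df planned contrasts on cell means (the "synergistic" triangular
  pattern is the default weighting);
* pooled-variance independent-samples t tests with the point-biserial
  effect size r = sqrt(t^2 / (t^2 + df));
* split-plot (mixed) ANOVA with Greenhouse-Geisser epsilon and the
  Huynh-Feldt small-sample adjustment for sphericity violations;
* multiple mediation with OLS path estimates and seeded percentile
  bootstrap confidence intervals;
* a priori sample-size determination from the noncentral F distribution.

p-values come from exact F/t distributions, never normal approximations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "cooperation_rate",
    "participant_summary",
    "anova_two_way",
    "partial_eta_sq",
    "planned_contrast",
    "ttest_ind",
    "effect_size_r",
    "mixed_anova",
    "multiple_mediation",
    "power_sample_size",
    "fixed_effects_power",
    "AnovaResult",
    "ContrastResult",
    "TTestResult",
    "MixedAnovaResult",
    "MediationResult",
    "PowerSpec",
    "SYNERGISTIC_WEIGHTS",
]


# ---------------------------------------------------------------------------
# per-participant aggregation
# ---------------------------------------------------------------------------

def cooperation_rate(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-participant cooperation rate (cooperative moves / rounds).

    Expects a trial table with ``participant_id``, ``participant_move``
    and the condition columns ``strategy`` and ``emotion``.
    """
    if len(trials) == 0:
        raise ValueError("empty trial table")
    g = trials.groupby("participant_id", sort=True)
    out = g.agg(
        strategy=("strategy", "first"),
        emotion=("emotion", "first"),
        n_rounds=("round", "size"),
        coop_rate=("participant_move", lambda s: float(np.mean(s == "C"))),
    ).reset_index()
    return out


def participant_summary(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-participant measures consumed by the ANOVAs and mediation.

    Returns cooperation rate, mean expectation rating, and the proportion
    of rounds each emotion was self-reported (columns ``report_joy`` ...
    ``report_neutral``).
    """
    out = cooperation_rate(trials)
    g = trials.groupby("participant_id", sort=True)
    out = out.merge(
        g["expectation_rating"].mean().rename("expectation").reset_index(),
        on="participant_id",
    )
    for emo in ("joy", "sadness", "anger", "regret", "neutral"):
        prop = g["self_report"].apply(lambda s, e=emo: float(np.mean(s == e)))
        out = out.merge(prop.rename(f"report_{emo}").reset_index(), on="participant_id")
    return out


# ---------------------------------------------------------------------------
# factorial ANOVA (Type III, effects coding)
# ---------------------------------------------------------------------------

def _effects_coding(levels: np.ndarray) -> tuple[np.ndarray, list]:
    """Sum-to-zero coding: k levels -> k-1 columns (last level = -1)."""
    uniq = sorted(pd.unique(levels))
    k = len(uniq)
    X = np.zeros((len(levels), k - 1))
    for j, lev in enumerate(uniq[:-1]):
        X[:, j] = np.where(levels == lev, 1.0, np.where(levels == uniq[-1], -1.0, 0.0))
    return X, uniq


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ coef
    return float(r @ r)


def partial_eta_sq(F: float, df1: float, df2: float) -> float:
    """Partial eta-squared from an F statistic: F*df1 / (F*df1 + df2)."""
    if F < 0 or df1 <= 0 or df2 <= 0:
        raise ValueError("need F >= 0 and positive degrees of freedom")
    return float(F * df1 / (F * df1 + df2))


@dataclass
class AnovaResult:
    """Type III factorial ANOVA table plus Bonferroni post-hoc tests."""

    table: pd.DataFrame
    posthoc: pd.DataFrame
    residual_ss: float
    residual_df: int


def anova_two_way(
    data: pd.DataFrame, dv: str, factor_a: str, factor_b: str
) -> AnovaResult:
    """Two-way between-subjects ANOVA, Type III SS, effects coding.

    Each cell needs at least two observations; unbalanced cells are
    handled by the Type III model comparisons.  Bonferroni-adjusted
    pairwise comparisons of each factor's marginal means (via the omnibus
    MSE) are attached.
    """
    df = data[[dv, factor_a, factor_b]].dropna()
    y = df[dv].to_numpy(dtype=float)
    counts = df.groupby([factor_a, factor_b], observed=True).size()
    if (counts < 2).any():
        raise ValueError("every cell needs >= 2 observations")
    Xa, levels_a = _effects_coding(df[factor_a].to_numpy())
    Xb, levels_b = _effects_coding(df[factor_b].to_numpy())
    Xab = np.column_stack(
        [Xa[:, i] * Xb[:, j] for i in range(Xa.shape[1]) for j in range(Xb.shape[1])]
    )
    ones = np.ones((len(df), 1))
    blocks = {factor_a: Xa, factor_b: Xb, f"{factor_a}:{factor_b}": Xab}
    X_full = np.column_stack([ones, Xa, Xb, Xab])
    rss_full = _rss(X_full, y)
    df_err = len(df) - X_full.shape[1]
    if df_err <= 0:
        raise ValueError("no residual degrees of freedom")
    mse = rss_full / df_err
    if mse <= 1e-14 * max(1.0, float(np.var(y))):
        raise ValueError("zero error variance: ANOVA undefined")

    rows = []
    for name, block in blocks.items():
        others = [ones] + [b for n, b in blocks.items() if n != name]
        rss_red = _rss(np.column_stack(others), y)
        ss = max(rss_red - rss_full, 0.0)
        df1 = block.shape[1]
        F = (ss / df1) / mse
        p = float(sps.f.sf(F, df1, df_err))
        rows.append(
            {
                "effect": name,
                "SS": ss,
                "df1": df1,
                "df2": df_err,
                "F": F,
                "p": p,
                "partial_eta_sq": partial_eta_sq(F, df1, df_err),
            }
        )
    table = pd.DataFrame(rows)

    # Bonferroni pairwise comparisons of marginal means, omnibus MSE error
    ph_rows = []
    for fac, levels in ((factor_a, levels_a), (factor_b, levels_b)):
        pairs = list(itertools.combinations(levels, 2))
        for l1, l2 in pairs:
            g1 = y[df[fac].to_numpy() == l1]
            g2 = y[df[fac].to_numpy() == l2]
            est = g1.mean() - g2.mean()
            se = np.sqrt(mse * (1 / len(g1) + 1 / len(g2)))
            t = est / se
            p_raw = float(2 * sps.t.sf(abs(t), df_err))
            ph_rows.append(
                {
                    "factor": fac,
                    "level_1": l1,
                    "level_2": l2,
                    "estimate": est,
                    "se": se,
                    "t": t,
                    "df": df_err,
                    "p_bonferroni": min(1.0, p_raw * len(pairs)),
                }
            )
    posthoc = pd.DataFrame(ph_rows)
    return AnovaResult(table=table, posthoc=posthoc, residual_ss=rss_full, residual_df=df_err)


# ---------------------------------------------------------------------------
# planned contrast
# ---------------------------------------------------------------------------

#: Triangular ("synergistic") weighting: the generosity-with-cooperative-
#: display cell against the other three.
SYNERGISTIC_WEIGHTS = {
    ("generosity", "cooperative"): 3.0,
    ("generosity", "competitive"): -1.0,
    ("extortion", "cooperative"): -1.0,
    ("extortion", "competitive"): -1.0,
}


@dataclass
class ContrastResult:
    estimate: float
    se: float
    t: float
    df: float
    p: float
    weights: dict


def planned_contrast(
    data: pd.DataFrame,
    dv: str,
    cells: tuple[str, str] = ("strategy", "emotion"),
    weights: dict | None = None,
    df_policy: str | int = "omnibus",
) -> ContrastResult:
    """Single-df contrast on cell means.

    t = sum(w_i * mean_i) / sqrt(MSE * sum(w_i^2 / n_i)), with MSE the
    pooled within-cell variance.  ``df_policy`` is either "omnibus"
    (df = N - k, the omnibus error term) or an explicit integer; the
    published contrast's df is not derivable from the obvious error-term
    choices, so the policy is exposed rather than guessed.
    """
    weights = dict(weights) if weights is not None else dict(SYNERGISTIC_WEIGHTS)
    if abs(sum(weights.values())) > 1e-9:
        raise ValueError("contrast weights must sum to 0")
    grouped = data.groupby(list(cells), observed=True)[dv]
    means = grouped.mean()
    ns = grouped.size()
    missing = [c for c in weights if c not in means.index]
    if missing:
        raise ValueError(f"cells missing from data: {missing}")
    N = int(ns.sum())
    k = len(means)
    ss_within = float(((data[dv] - grouped.transform("mean")) ** 2).sum())
    df_err = N - k
    mse = ss_within / df_err
    est = sum(w * means[c] for c, w in weights.items())
    se = np.sqrt(mse * sum(w**2 / ns[c] for c, w in weights.items()))
    t = est / se
    dof = float(df_err if df_policy == "omnibus" else int(df_policy))
    p = float(2 * sps.t.sf(abs(t), dof))
    return ContrastResult(float(est), float(se), float(t), dof, p, weights)


# ---------------------------------------------------------------------------
# t test
# ---------------------------------------------------------------------------

def effect_size_r(t: float, df: float) -> float:
    """Point-biserial effect size of a t statistic: sqrt(t^2/(t^2+df))."""
    if df <= 0:
        raise ValueError("df must be positive")
    return float(np.sqrt(t**2 / (t**2 + df)))


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    r: float


def ttest_ind(a, b) -> TTestResult:
    """Pooled-variance independent t test with effect size r.

    r = sqrt(t^2 / (t^2 + df)), the point-biserial correlation magnitude.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    na, nb = len(a), len(b)
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    if sp2 <= 0:
        raise ValueError("zero pooled variance: t test undefined")
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = float(2 * sps.t.sf(abs(t), df))
    return TTestResult(float(t), int(df), p, effect_size_r(t, df))


# ---------------------------------------------------------------------------
# mixed (split-plot) ANOVA with sphericity correction
# ---------------------------------------------------------------------------

@dataclass
class MixedAnovaResult:
    """Between- and within-subject effects of a split-plot design.

    ``between`` follows the :class:`AnovaResult` table layout;
    ``within`` carries uncorrected and Huynh-Feldt-corrected df and p per
    effect, plus the epsilon estimates.
    """

    between: pd.DataFrame
    within: pd.DataFrame
    eps_gg: float
    eps_hf: float


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """Deterministic k x (k-1) matrix, columns orthonormal and _|_ 1."""
    A = np.column_stack([np.ones(k), np.eye(k)[:, : k - 1]])
    Q, _ = np.linalg.qr(A)
    return Q[:, 1:]


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    within: str,
    subject: str,
    between: list[str],
) -> MixedAnovaResult:
    """Split-plot ANOVA: between factors x one within factor.

    Every subject must have a complete set of within-factor levels (no
    imputation).  Between-subject effects are tested on subject means with
    Type III sums of squares.  Within-subject effects use the multivariate
    transform: responses are projected on orthonormal within-contrasts and
    each effect's hypothesis SSCP trace is compared to the residual SSCP
    trace.  Greenhouse-Geisser epsilon comes from the pooled residual
    covariance of the contrast scores; the Huynh-Feldt adjustment
    (with error df = N - g, reducing to the classic formula when g = 1)
    is capped at 1.  Corrected df are epsilon times the uncorrected df.
    """
    cols = [subject, within, dv] + list(between)
    df = data[cols].dropna()
    wide = df.pivot_table(index=subject, columns=within, values=dv, aggfunc="first")
    if wide.isna().any().any():
        bad = wide.index[wide.isna().any(axis=1)].tolist()
        raise ValueError(f"missing within-factor cells for subjects {bad[:5]}")
    k = wide.shape[1]
    n = wide.shape[0]
    Y = wide.to_numpy(dtype=float)
    meta = df.groupby(subject, sort=True)[list(between)].first().loc[wide.index]

    # Between design, Type III effects coding with all interactions
    ones = np.ones((n, 1))
    blocks: dict[str, np.ndarray] = {}
    codings = {}
    for fac in between:
        Xf, levels = _effects_coding(meta[fac].to_numpy())
        blocks[fac] = Xf
        codings[fac] = levels
    for r in range(2, len(between) + 1):
        for combo in itertools.combinations(between, r):
            parts = [blocks[f] for f in combo]
            cols_ = parts[0]
            for p_ in parts[1:]:
                cols_ = np.column_stack(
                    [cols_[:, i] * p_[:, j] for i in range(cols_.shape[1]) for j in range(p_.shape[1])]
                )
            blocks[":".join(combo)] = cols_
    X = np.column_stack([ones] + list(blocks.values()))
    p_full = X.shape[1]
    df_err = n - p_full
    if df_err <= 0:
        raise ValueError("not enough subjects for the between design")

    # ---- between-subject effects on subject means (classical scaling x k)
    ym = Y.mean(axis=1)
    rss_full = _rss(X, ym)
    mse = rss_full / df_err
    rows_b = []
    for name, block in blocks.items():
        others = [ones] + [b for nm, b in blocks.items() if nm != name]
        ss = max(_rss(np.column_stack(others), ym) - rss_full, 0.0)
        df1 = block.shape[1]
        F = (ss / df1) / mse
        rows_b.append(
            {
                "effect": name,
                "SS": ss * k,
                "df1": df1,
                "df2": df_err,
                "F": F,
                "p": float(sps.f.sf(F, df1, df_err)),
                "partial_eta_sq": partial_eta_sq(F, df1, df_err),
            }
        )

    # ---- within-subject effects via orthonormal contrast scores
    C = _orthonormal_contrasts(k)
    Z = Y @ C  # n x (k-1)
    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    B = XtX_inv @ (X.T @ Z)
    resid = Z - X @ B
    E = resid.T @ resid  # residual SSCP, df_err
    tr_E = float(np.trace(E))

    if k == 2:
        eps_gg = 1.0
    else:
        sigma = E / df_err
        eps_gg = float(np.trace(sigma) ** 2 / ((k - 1) * np.trace(sigma @ sigma)))
        eps_gg = min(1.0, max(eps_gg, 1.0 / (k - 1)))
    num = (df_err + 1) * (k - 1) * eps_gg - 2
    den = (k - 1) * (df_err - (k - 1) * eps_gg)
    eps_hf = min(1.0, num / den) if den > 0 else 1.0

    # term -> coefficient rows in X (intercept row tests the within main effect)
    col_of = {"(intercept)": list(range(1))}
    start = 1
    for name, block in blocks.items():
        col_of[name] = list(range(start, start + block.shape[1]))
        start += block.shape[1]

    rows_w = []
    for name, idx in col_of.items():
        L = np.zeros((len(idx), p_full))
        for r_, c_ in enumerate(idx):
            L[r_, c_] = 1.0
        LB = L @ B
        H = LB.T @ np.linalg.solve(L @ XtX_inv @ L.T, LB)
        ss_h = float(np.trace(H))
        df1 = len(idx) * (k - 1)
        df2 = df_err * (k - 1)
        F = (ss_h / df1) / (tr_E / df2)
        label = within if name == "(intercept)" else f"{within}:{name}"
        rows_w.append(
            {
                "effect": label,
                "SS": ss_h,
                "df1": df1,
                "df2": df2,
                "F": F,
                "p_uncorrected": float(sps.f.sf(F, df1, df2)),
                "eps_gg": eps_gg,
                "eps_hf": eps_hf,
                "df1_hf": eps_hf * df1,
                "df2_hf": eps_hf * df2,
                "p_hf": float(sps.f.sf(F, eps_hf * df1, eps_hf * df2)),
                "partial_eta_sq": partial_eta_sq(F, df1, df2),
            }
        )
    return MixedAnovaResult(
        between=pd.DataFrame(rows_b),
        within=pd.DataFrame(rows_w),
        eps_gg=eps_gg,
        eps_hf=eps_hf,
    )


# ---------------------------------------------------------------------------
# multiple mediation with percentile bootstrap
# ---------------------------------------------------------------------------

@dataclass
class MediationResult:
    """OLS path estimates and percentile bootstrap CIs.

    ``paths`` has one row per mediator: a (iv -> mediator), b (mediator ->
    dv given iv and the other mediators), indirect = a*b, and the CI.
    The OLS identity total = direct + sum(indirect) holds exactly.
    """

    paths: pd.DataFrame
    total: float
    direct: float
    total_ci: tuple[float, float]
    direct_ci: tuple[float, float]
    n_boot: int
    seed: int | None
    conf: float = 0.95

    @property
    def indirect_sum(self) -> float:
        return float(self.paths["indirect"].sum())


def _batched_ols(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Solve OLS for a batch: X (b, n, p), Y (b, n, q) -> coef (b, p, q)."""
    G = np.einsum("bni,bnj->bij", X, X)
    R = np.einsum("bni,bnq->biq", X, Y)
    try:
        return np.linalg.solve(G, R)
    except np.linalg.LinAlgError:
        return np.einsum("bij,bjq->biq", np.linalg.pinv(G), R)


def multiple_mediation(
    iv,
    mediators: pd.DataFrame,
    dv,
    n_boot: int = 5000,
    seed: int | None = None,
    conf: float = 0.95,
) -> MediationResult:
    """Multiple mediation of a binary condition effect.

    Paths by OLS: a_j regresses mediator j on the condition; b_j and the
    direct effect c' come from one outcome model with all mediators and
    the condition; the total effect c regresses the outcome on the
    condition alone.  Indirect effects are a_j * b_j; CIs are percentile
    bootstrap over participants, seeded and deterministic.
    """
    iv = np.asarray(iv, dtype=float)
    M = mediators.to_numpy(dtype=float)
    names = list(mediators.columns)
    y = np.asarray(dv, dtype=float)
    n, m = M.shape
    if set(np.unique(iv)) - {0.0, 1.0}:
        raise ValueError("iv must be coded {0, 1}")
    if min((iv == 0).sum(), (iv == 1).sum()) < 10:
        raise ValueError("need n >= 10 per condition level")

    # collinearity among mediators (given intercept and iv)
    base = np.column_stack([np.ones(n), iv])
    offending = []
    for j in range(m):
        others = np.column_stack([base, np.delete(M, j, axis=1)])
        rss = _rss(others, M[:, j])
        scale = float(np.var(M[:, j]) * n) or 1.0
        if rss / scale < 1e-12:
            offending.append(names[j])
    if offending:
        raise ValueError(f"collinear mediators: {offending}")

    Xa = base
    Xb = np.column_stack([np.ones(n), iv, M])
    a_coef = np.linalg.lstsq(Xa, M, rcond=None)[0][1]  # (m,)
    out_coef = np.linalg.lstsq(Xb, y, rcond=None)[0]
    direct = float(out_coef[1])
    b_coef = out_coef[2:]
    total = float(np.linalg.lstsq(Xa, y, rcond=None)[0][1])
    indirect = a_coef * b_coef

    rng = np.random.default_rng(seed)
    alpha = (1 - conf) / 2
    boots_ind = np.empty((n_boot, m))
    boots_dir = np.empty(n_boot)
    boots_tot = np.empty(n_boot)
    chunk = 1000
    done = 0
    data = np.column_stack([iv, M, y])
    while done < n_boot:
        b = min(chunk, n_boot - done)
        idx = rng.integers(0, n, size=(b, n))
        D = data[idx]  # (b, n, 1+m+1)
        iv_b = D[:, :, :1]
        M_b = D[:, :, 1 : 1 + m]
        y_b = D[:, :, 1 + m :]
        ones_b = np.ones((b, n, 1))
        Xa_b = np.concatenate([ones_b, iv_b], axis=2)
        a_b = _batched_ols(Xa_b, M_b)[:, 1, :]  # (b, m)
        Xb_b = np.concatenate([ones_b, iv_b, M_b], axis=2)
        out_b = _batched_ols(Xb_b, y_b)[:, :, 0]  # (b, 2+m)
        tot_b = _batched_ols(Xa_b, y_b)[:, 1, 0]
        boots_ind[done : done + b] = a_b * out_b[:, 2:]
        boots_dir[done : done + b] = out_b[:, 1]
        boots_tot[done : done + b] = tot_b
        done += b

    lo, hi = 100 * alpha, 100 * (1 - alpha)
    ci_ind = np.percentile(boots_ind, [lo, hi], axis=0)
    paths = pd.DataFrame(
        {
            "mediator": names,
            "a": a_coef,
            "b": b_coef,
            "indirect": indirect,
            "ci_low": ci_ind[0],
            "ci_high": ci_ind[1],
        }
    )
    return MediationResult(
        paths=paths,
        total=total,
        direct=direct,
        total_ci=tuple(np.percentile(boots_tot, [lo, hi])),
        direct_ci=tuple(np.percentile(boots_dir, [lo, hi])),
        n_boot=n_boot,
        seed=seed,
        conf=conf,
    )


# ---------------------------------------------------------------------------
# power analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PowerSpec:
    """A priori power specification for a fixed-effects F test."""

    f: float
    alpha: float = 0.05
    power: float = 0.95
    n_groups: int = 4
    df1: int = 1

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if not (0 < self.power < 1):
            raise ValueError("power must be in (0, 1)")
        if self.f <= 0:
            raise ValueError("effect size f must be > 0")
        if self.n_groups < 2 or self.df1 < 1:
            raise ValueError("need n_groups >= 2 and df1 >= 1")


def fixed_effects_power(spec: PowerSpec, n_total: int) -> float:
    """Power of the fixed-effects F test at total sample size ``n_total``.

    Noncentrality lambda = f^2 * N; denominator df = N - n_groups;
    critical value at ``alpha`` from the central F.
    """
    df2 = n_total - spec.n_groups
    if df2 < 1:
        return 0.0
    lam = spec.f**2 * n_total
    crit = sps.f.isf(spec.alpha, spec.df1, df2)
    return float(sps.ncf.sf(crit, spec.df1, df2, lam))


def power_sample_size(spec: PowerSpec, n_max: int = 10**6) -> int:
    """Smallest total N whose fixed-effects F test reaches the target power."""
    for n_total in range(spec.n_groups + 1, n_max + 1):
        if fixed_effects_power(spec, n_total) >= spec.power:
            return n_total
    raise ValueError(f"power {spec.power} unreachable below N = {n_max}")
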