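"""Questionnaire scoring, one-factor analysis, and inferential statistics.

The behavioral measures go through a 2 (noise) x 4 (animation)
repeated-measures ANOVA with Mauchly's sphericity test, a
Greenhouse-Geisser correction when sphericity is violated, partial
eta-squared effect sizes, and Bonferroni-corrected pairwise comparisons
of the estimated marginal means for significant effects.  Ratings are
ordinal and use Kruskal-Wallis rank-sum tests with Dunn's post-hoc
z-tests (Bonferroni-adjusted).  The two rating constructs — sense of
presence (Q1-Q5, Q7) and perceived conversation success (Q6, Q8-Q10) —
are each summarised by a one-factor model with regression-method factor
scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import FactorAnalysis

ALPHA = 0.05

PRESENCE_ITEMS = ("q1", "q2", "q3", "q4", "q5", "q7")
SUCCESS_ITEMS = ("q6", "q8", "q9", "q10")
CONSTRUCT_ITEMS = {"presence": PRESENCE_ITEMS, "success": SUCCESS_ITEMS}
DEFAULT_REVERSE = frozenset({"q10"})

_GRID = np.arange(-3.0, 3.01, 0.5)


@dataclass
class TestResult:
    """One inferential test: statistic, dfs, p, effect size, post-hoc table."""

    name: str
    statistic: float
    df1: float
    df2: float | None
    p: float
    eta_p2: float | None = None
    correction: str | None = None  # e.g. "greenhouse-geisser"
    eps: float | None = None
    sphericity_w: float | None = None
    sphericity_p: float | None = None
    pairwise: pd.DataFrame | None = None

    @property
    def significant(self) -> bool:
        return self.p <= ALPHA

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "statistic": None if self.statistic is None or not np.isfinite(
                self.statistic) else round(float(self.statistic), 6),
            "df1": self.df1,
            "df2": self.df2,
            "p": None if not np.isfinite(self.p) else float(self.p),
            "eta_p2": self.eta_p2,
            "correction": self.correction,
            "eps": self.eps,
            "sphericity_W": self.sphericity_w,
            "sphericity_p": self.sphericity_p,
        }
        if self.pairwise is not None:
            d["pairwise"] = self.pairwise.to_dict(orient="records")
        return d


# ---------------------------------------------------------------------------
# Questionnaire scoring
# ---------------------------------------------------------------------------

def score_questionnaire(responses: pd.DataFrame,
                        reverse=DEFAULT_REVERSE) -> pd.DataFrame:
    """Map reversed items v -> -v for factor-analysis input.

    ``responses`` holds one row per rating with item columns ``q1..q10``
    on the 0.5 grid in [-3, 3]; raw values should be kept separately for
    item-level tests.  Off-grid values raise, naming the item.
    """
    out = responses.copy()
    for item in [c for c in out.columns if c.startswith("q")]:
        vals = out[item].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        if not np.all(np.isclose(vals[ok][:, None], _GRID, atol=1e-9).any(axis=1)):
            raise ValueError(
                f"item {item}: values must lie on the 0.5 grid in [-3, 3]")
        if item in reverse:
            out[item] = -out[item]
    return out


# ---------------------------------------------------------------------------
# One-factor analysis
# ---------------------------------------------------------------------------

@dataclass
class FactorResult:
    construct: str
    items: tuple
    loadings: np.ndarray
    specific_variances: np.ndarray
    scores: np.ndarray

    def to_dict(self) -> dict:
        return {
            "construct": self.construct,
            "items": list(self.items),
            "loadings": [round(float(v), 4) for v in self.loadings],
            "specific_variances": [round(float(v), 4)
                                   for v in self.specific_variances],
        }


class OneFactorModel(BaseEstimator, TransformerMixin):
    """Single-factor model on standardized items, no rotation.

    Items are z-scored and a one-factor model is fitted by maximum
    likelihood (``method="ml"``, the default) or iterated principal-axis
    factoring (``method="principal_axis"``); ``transform`` returns factor
    scores by the regression method (the Gaussian posterior mean /
    Thomson scores).  The loading sign is fixed so that the loadings sum
    positive.  On the standardized scale the specific variance of item
    *j* is approximately ``1 - loading_j**2``.

    With weakly correlated items the one-factor ML solution is only
    weakly identified and can place a large loading on a single item
    (a near-Heywood case); principal-axis factoring shrinks toward zero
    loadings in that regime and is the more conservative choice for
    noisy questionnaires.

    Fitted attributes: ``loadings_``, ``specific_variances_``, ``mean_``,
    ``scale_``.
    """

    def __init__(self, method: str = "ml", max_iter: int = 2000,
                 tol: float = 1e-4, random_state: int = 0):
        self.method = method
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None) -> "OneFactorModel":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] < 3:
            raise ValueError("need a 2-D item matrix with at least 3 items")
        if X.shape[0] < 20:
            raise ValueError("need at least 20 pooled responses")
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=0)
        if np.any(self.scale_ == 0):
            raise ValueError(
                "an item has zero variance; drop it or add responses "
                "before fitting the factor model")
        Z = (X - self.mean_) / self.scale_
        corr = np.corrcoef(Z, rowvar=False)
        if np.min(np.linalg.eigvalsh(corr)) < 1e-10:
            raise ValueError(
                "item correlation matrix is not positive definite; items "
                "may be linearly dependent — drop duplicated items or "
                "add jitter/responses")
        if self.method == "ml":
            fa = FactorAnalysis(n_components=1, rotation=None,
                                max_iter=self.max_iter, tol=self.tol,
                                random_state=self.random_state)
            fa.fit(Z)
            loadings = fa.components_[0].copy()
            psi = fa.noise_variance_.copy()
        elif self.method == "principal_axis":
            loadings, psi = self._principal_axis(corr)
        else:
            raise ValueError("method must be 'ml' or 'principal_axis'")
        if loadings.sum() < 0:
            loadings = -loadings
        self.loadings_ = loadings
        self.specific_variances_ = psi
        # regression-method score weights: lambda' Sigma^{-1}
        sigma = np.outer(loadings, loadings) + np.diag(np.maximum(psi, 1e-6))
        self._weights = np.linalg.solve(sigma, loadings)
        return self

    def _principal_axis(self, corr: np.ndarray):
        p = corr.shape[0]
        inv = np.linalg.inv(corr)
        h = 1.0 - 1.0 / np.diag(inv)  # squared multiple correlations
        for _ in range(self.max_iter):
            reduced = corr.copy()
            reduced[np.diag_indices(p)] = h
            vals, vecs = np.linalg.eigh(reduced)
            lam = vecs[:, -1] * np.sqrt(max(vals[-1], 0.0))
            h_new = np.clip(lam ** 2, 0.0, 0.995)
            if np.max(np.abs(h_new - h)) < self.tol:
                h = h_new
                break
            h = h_new
        reduced = corr.copy()
        reduced[np.diag_indices(p)] = h
        vals, vecs = np.linalg.eigh(reduced)
        lam = vecs[:, -1] * np.sqrt(max(vals[-1], 0.0))
        return lam, 1.0 - lam ** 2

    def transform(self, X) -> np.ndarray:
        """Regression-method factor scores, one per response row."""
        Z = (np.asarray(X, dtype=float) - self.mean_) / self.scale_
        return Z @ self._weights


def one_factor_analysis(items: pd.DataFrame, construct: str,
                        method: str = "ml") -> FactorResult:
    """Fit the one-factor model for a rating construct.

    ``items`` must contain the construct's item columns (reversed items
    already scored); rows are pooled responses across participants and
    conditions.
    """
    cols = CONSTRUCT_ITEMS.get(construct)
    if cols is None:
        cols = tuple(items.columns)
    X = items[list(cols)].to_numpy(dtype=float)
    model = OneFactorModel(method=method).fit(X)
    return FactorResult(construct, tuple(cols), model.loadings_,
                        model.specific_variances_, model.transform(X))


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn
# ---------------------------------------------------------------------------

def _dunn_posthoc(values: np.ndarray, groups: np.ndarray,
                  levels: list) -> pd.DataFrame:
    """All pairwise Dunn z-tests on the pooled ranks, Bonferroni-adjusted."""
    n = len(values)
    ranks = sps.rankdata(values)
    mean_rank = {g: ranks[groups == g].mean() for g in levels}
    counts = {g: int((groups == g).sum()) for g in levels}
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term
    rows = []
    pairs = list(combinations(levels, 2))
    m = len(pairs)
    for a, b in pairs:
        se = np.sqrt(var_base * (1.0 / counts[a] + 1.0 / counts[b]))
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"A": a, "B": b, "z": z, "p_unc": p,
                     "p_bonf": min(1.0, p * m)})
    return pd.DataFrame(rows)


def kruskal_wallis_with_dunn(values, groups, alpha: float = ALPHA,
                             name: str = "kruskal-wallis") -> TestResult:
    """Kruskal-Wallis rank-sum test with Dunn's post-hoc when significant.

    The H statistic uses the tie correction; Dunn's pairwise z-tests (run
    only when the omnibus p <= alpha) are Bonferroni-adjusted over all
    level pairs.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = sorted(pd.unique(groups).tolist())
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    samples = [values[groups == g] for g in levels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group must be non-empty")
    if np.ptp(values) == 0:
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*samples)
    pairwise = _dunn_posthoc(values, groups, levels) if p <= alpha else None
    return TestResult(name=name, statistic=float(h), df1=len(levels) - 1,
                      df2=None, p=float(p), pairwise=pairwise)


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA (2 x 4 within-subject design)
# ---------------------------------------------------------------------------

def _partial_eta2(F: float, df1: float, df2: float) -> float:
    return float(F * df1 / (F * df1 + df2))


def _pairwise_emm(data: pd.DataFrame, dv: str, factor: str,
                  subject: str) -> pd.DataFrame:
    """Bonferroni-corrected pairwise comparisons of marginal means."""
    cell = data.groupby([subject, factor])[dv].mean().reset_index()
    pw = pg.pairwise_tests(data=cell, dv=dv, within=factor, subject=subject,
                           padjust="bonf")
    means = cell.groupby(factor)[dv].mean()
    pw = pw.rename(columns={"p_corr": "p_bonf"})
    if "p_bonf" not in pw.columns:
        pw["p_bonf"] = pw["p_unc"]
    pw["delta"] = [means[b] - means[a] for a, b in zip(pw["A"], pw["B"])]
    return pw[["A", "B", "T", "dof", "p_unc", "p_bonf", "delta"]]


def rm_anova_2x4(data: pd.DataFrame, dv: str = "value",
                 subject: str = "participant", noise: str = "noise",
                 animation: str = "animation",
                 posthoc: bool = True) -> dict:
    """Two-way repeated-measures ANOVA for the complete balanced design.

    Parameters name the long-format columns.  Participants with
    incomplete cells are dropped listwise; at least three complete
    participants are required.  Returns a dict of
    :class:`TestResult` keyed ``"noise"``, ``"animation"``,
    ``"interaction"``.

    Mauchly's test is run per within factor with more than two levels;
    when it is violated (p <= .05) the Greenhouse-Geisser-corrected
    degrees of freedom and p-value are reported for that factor (and for
    the interaction, which shares the multi-level factor).  Partial
    eta-squared is computed from the uncorrected F and dfs.  Pairwise
    Bonferroni comparisons of the estimated marginal means are attached
    for significant effects.
    """
    df = data[[subject, noise, animation, dv]].dropna().copy()
    cells = df.groupby(subject).size()
    n_levels = df[noise].nunique() * df[animation].nunique()
    complete = cells[cells == n_levels].index
    df = df[df[subject].isin(complete)]
    if df[subject].nunique() < 3:
        raise ValueError("need at least 3 participants with complete data")

    with np.errstate(divide="ignore", invalid="ignore"):
        aov = pg.rm_anova(data=df, dv=dv, within=[noise, animation],
                          subject=subject, detailed=True)
    aov = aov.set_index("Source")

    # Mauchly per multi-level factor (collapsing over the other factor)
    spher = {}
    for factor in (noise, animation):
        if df[factor].nunique() > 2:
            marg = df.groupby([subject, factor])[dv].mean().reset_index()
            with np.errstate(divide="ignore", invalid="ignore"):
                res = pg.sphericity(data=marg, dv=dv, within=factor,
                                    subject=subject)
            spher[factor] = res
    interaction_key = [s for s in aov.index if "*" in s][0]

    results = {}
    for key, source in (("noise", noise), ("animation", animation),
                        ("interaction", interaction_key)):
        row = aov.loc[source]
        F = float(row["F"])
        df1, df2 = float(row["ddof1"]), float(row["ddof2"])
        p = float(row["p_unc"])
        if not np.isfinite(F) and abs(float(row["SS"])) < 1e-12:
            # a response constant in this effect carries no evidence
            F, p = 0.0, 1.0
        correction = eps = w = sp = None
        # the multi-level factor drives the sphericity decision; the
        # interaction inherits it
        driver = animation if key in ("animation", "interaction") else noise
        if driver in spher:
            res = spher[driver]
            w, sp = float(res.W), float(res.pval)
            if sp <= ALPHA:
                eps = float(row.get("eps", np.nan))
                if np.isfinite(eps):
                    correction = "greenhouse-geisser"
                    p = float(row.get("p_GG_corr", p))
                    df1, df2 = df1 * eps, df2 * eps
        result = TestResult(
            name=key, statistic=F, df1=df1, df2=df2, p=p,
            eta_p2=_partial_eta2(F, float(row["ddof1"]), float(row["ddof2"])),
            correction=correction, eps=eps, sphericity_w=w, sphericity_p=sp,
        )
        if posthoc and result.significant and key != "noise":
            # an animation main effect or an interaction is followed up by
            # pairwise comparisons of the animation marginal means
            result.pairwise = _pairwise_emm(df, dv, animation, subject)
        results[key] = result

    # marginal-mean noise difference (noise minus quiet when labelled so)
    noise_means = df.groupby(noise)[dv].mean()
    if set(noise_means.index) == {"quiet", "noise"}:
        results["noise_delta"] = float(
            noise_means["noise"] - noise_means["quiet"])
    return results


def mixed_anova_interlocutor(data: pd.DataFrame, dv: str = "value",
                             subject: str = "trace_id",
                             within: str = "condition",
                             between: str = "interlocutor") -> dict:
    """Mixed ANOVA with interlocutor as a between-subjects factor.

    Used for measures computed for all three interlocutors (e.g. speech
    level) to check that the setup was symmetric; the within factor is
    the 8-level condition.  Pairwise between-group comparisons are
    Bonferroni-adjusted.
    """
    aov = pg.mixed_anova(data=data, dv=dv, within=within, subject=subject,
                         between=between)
    pw = pg.pairwise_tests(data=data, dv=dv, between=between,
                           padjust="bonf")
    return {"anova": aov, "pairwise": pw}
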