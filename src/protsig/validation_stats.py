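"""Downstream statistical validation of candidate protein markers.

Group differences by Wilcoxon rank-sum, monotone association with tumor
stage by Spearman correlation, prognostic value by univariate Cox
proportional-hazards regression and Kaplan-Meier / log-rank comparison,
plus PCA and t-SNE embedding reports for visual class separation.  Every
test is complete-case on the variables it touches.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test

from .io_preprocess import InputError, ProteinMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "TestResult",
    "EmbeddingReport",
    "SurvivalCurve",
    "wilcoxon_rank_sum",
    "spearman_corr",
    "cox_univariate",
    "km_logrank",
    "pca_report",
    "tsne_embed",
]


@dataclass
class TestResult:
    """A statistic, its two-sided p-value, an effect descriptor, and the
    complete-case sample count the test actually used."""

    statistic: float
    p_value: float
    effect: dict[str, float] = field(default_factory=dict)
    n_used: int = 0


@dataclass
class EmbeddingReport:
    """2-D (or 3-D) sample coordinates; for PCA also the percentage of total
    variance carried by each component (non-increasing, summing to <= 100)."""

    coordinates: pd.DataFrame
    variance_pct: np.ndarray | None = None
    method: str = "pca"


@dataclass
class SurvivalCurve:
    """Product-limit survival estimate for one group."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    label: str


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null distribution when both groups have at most six observations
    and no ties straddle the groups; otherwise the normal approximation
    with tie and continuity correction.  The statistic reported is the
    rank-sum of the first group.
    """
    x = np.asarray(pd.Series(x).dropna(), dtype=float)
    y = np.asarray(pd.Series(y).dropna(), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise InputError("both groups must be non-empty")
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (max(len(x), len(y)) <= 6 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    rank_sum = float(res.statistic + len(x) * (len(x) + 1) / 2)
    return TestResult(rank_sum, float(res.pvalue), {"U": float(res.statistic)},
                      len(x) + len(y))


def spearman_corr(x, y) -> TestResult:
    """Tie-aware Spearman rank correlation with two-sided p-value.

    Pairs with a missing value in either variable are dropped; positive rho
    means the first variable rises with the second (e.g. abundance with
    stage).  A constant vector leaves rho undefined (NaN).
    """
    df = pd.DataFrame({"x": x, "y": y}).dropna()
    if len(df) < 3:
        raise InputError(f"need >= 3 complete pairs, got {len(df)}")
    if df["x"].nunique() == 1 or df["y"].nunique() == 1:
        logger.warning("constant input; Spearman rho undefined")
        return TestResult(np.nan, np.nan, {"rho": np.nan}, len(df))
    rho, p = stats.spearmanr(df["x"], df["y"])
    return TestResult(float(rho), float(p), {"rho": float(rho)}, len(df))


def cox_univariate(times, events, covariate, name: str = "x") -> TestResult:
    """Univariate Cox proportional-hazards fit (Efron tie handling).

    Returns the Wald statistic and p-value, with the hazard ratio per unit
    covariate increase and its 95% confidence interval in ``effect``.
    """
    df = pd.DataFrame({"T": times, "E": events, name: covariate}).dropna()
    if df["E"].sum() < 1:
        raise InputError("no events observed")
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="T", event_col="E")
    row = cph.summary.loc[name]
    return TestResult(
        statistic=float(row["z"]),
        p_value=float(row["p"]),
        effect={
            "HR": float(np.exp(row["coef"])),
            "HR_ci_low": float(np.exp(row["coef lower 95%"])),
            "HR_ci_high": float(np.exp(row["coef upper 95%"])),
            "coef": float(row["coef"]),
        },
        n_used=len(df),
    )


def km_logrank(times, events, group) -> tuple[list[SurvivalCurve], TestResult]:
    """Kaplan-Meier curves per group and the two-group log-rank test.

    ``group`` is a binary labelling (a continuous marker is typically
    dichotomized at its median beforehand).  Complete-case on all three
    inputs.
    """
    df = pd.DataFrame({"T": times, "E": events, "g": group}).dropna()
    labels = sorted(df["g"].unique())
    if len(labels) != 2:
        raise InputError(f"need exactly 2 groups, got {labels}")
    curves = []
    for lab in labels:
        sub = df[df["g"] == lab]
        if len(sub) == 0:
            raise InputError(f"group {lab!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["T"], sub["E"], label=str(lab))
        times_out = kmf.survival_function_.index.to_numpy()[1:]
        surv = kmf.survival_function_.iloc[1:, 0].to_numpy()
        at_risk = kmf.event_table["at_risk"].reindex(times_out).to_numpy()
        curves.append(SurvivalCurve(times_out, surv, at_risk, str(lab)))
    a, b = (df[df["g"] == lab] for lab in labels)
    lr = logrank_test(a["T"], b["T"], a["E"], b["E"])
    return curves, TestResult(float(lr.test_statistic), float(lr.p_value),
                              {"chi2": float(lr.test_statistic)}, len(df))


def median_split(values) -> pd.Series:
    """Dichotomize a continuous marker at its median: 'high' = above."""
    v = pd.Series(values)
    med = v.median()
    return pd.Series(np.where(v > med, "high", "low"), index=v.index).where(v.notna())


def pca_report(
    pm: ProteinMatrix | pd.DataFrame,
    standardize: bool = True,
    n_components: int = 2,
) -> EmbeddingReport:
    """PCA scores and per-component variance percentages.

    Columns are centered and, with ``standardize`` (default, matching the
    usual convention for mixed-scale panels), scaled to unit variance;
    zero-variance columns are dropped with a warning in that case.
    Percentages are eigenvalues over their total, times 100, for all
    components; coordinates are returned for the first ``n_components``.
    """
    X = pm.values if isinstance(pm, ProteinMatrix) else pm
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise InputError("PCA needs >= 2 samples and >= 2 proteins")
    Xc = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        dead = sd.index[sd == 0].tolist()
        if dead:
            logger.warning("dropping zero-variance columns under standardization: %s", dead)
            Xc = Xc.drop(columns=dead)
            sd = sd.drop(index=dead)
        Xc = Xc / sd
    pca = PCA(n_components=min(Xc.shape))
    coords = pca.fit_transform(Xc.to_numpy())
    pct = pca.explained_variance_ratio_ * 100.0
    k = min(n_components, coords.shape[1])
    frame = pd.DataFrame(
        coords[:, :k], index=X.index, columns=[f"Dim{i+1}" for i in range(k)]
    )
    return EmbeddingReport(frame, variance_pct=pct, method="pca")


def tsne_embed(
    pm: ProteinMatrix | pd.DataFrame,
    perplexity: float = 30.0,
    seed: int = 0,
    standardize: bool = True,
) -> EmbeddingReport:
    """2-D t-SNE embedding, reproducible given ``seed``; visualization only."""
    X = pm.values if isinstance(pm, ProteinMatrix) else pm
    n = X.shape[0]
    if perplexity >= (n - 1) / 3:
        raise InputError(f"perplexity {perplexity} too large for n={n}")
    Xs = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=1).replace(0, 1.0)
        Xs = Xs / sd
    emb = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed, init="pca"
    ).fit_transform(Xs.to_numpy())
    frame = pd.DataFrame(emb, index=X.index, columns=["Dim1", "Dim2"])
    return EmbeddingReport(frame, variance_pct=None, method="tsne")
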