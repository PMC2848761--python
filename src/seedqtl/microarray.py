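"""Probe-level microarray condensation and differential-accumulation contrasts.

The expression-array arm of the NIL analysis: probe intensities are quantile
normalized across arrays, condensed per probeset by Tukey median polish on the
log2 probe × array matrix, globally rescaled so the experiment-wide linear
median is 10,000, and then screened with Student's t contrasts (genotype and
stage), a Benjamini–Hochberg FDR, a 1.5-fold-change filter, and a balanced
two-factor ANOVA (genotype × stage with interaction).

Background correction is deliberately omitted from the condensation: the
downstream screens depend only on normalized relative values, and the additive
log2 model used throughout (expression + probe affinity + error) is stated
without a background term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

TARGET_MEDIAN = 10_000.0
DEFAULT_FOLD = 1.5
DEFAULT_FDR = 0.05

GENOTYPES = ("LoPro", "HiPro")


@dataclass
class ProbeIntensityMatrix:
    """Raw (or normalized) probe-level intensities with the array design.

    ``values``: DataFrame with a (probeset, probe) MultiIndex and one column
    per array, strictly positive linear intensities.  ``design``: DataFrame
    indexed by array id with columns ``genotype``, ``stage``, ``replicate``.
    """

    values: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if not set(self.values.columns) <= set(self.design.index):
            missing = set(self.values.columns) - set(self.design.index)
            raise ValueError(f"arrays missing from design: {sorted(missing)}")
        if (self.values.to_numpy() <= 0).any():
            raise ValueError("probe intensities must be strictly positive")
        sizes = self.values.groupby(level=0).size()
        if sizes.nunique() > 1:
            raise ValueError("all probesets must have the same probe count")

    @property
    def probesets(self) -> np.ndarray:
        return self.values.index.get_level_values(0).unique().to_numpy()

    @property
    def arrays(self) -> list:
        return list(self.values.columns)


@dataclass
class ExpressionMatrix:
    """Condensed per-probeset expression, linear scale, global median 10,000."""

    values: pd.DataFrame  # probeset x array, linear
    design: pd.DataFrame
    scale_factor: float = field(default=1.0)

    @property
    def log2(self) -> pd.DataFrame:
        return np.log2(self.values)


def quantile_normalize(matrix: ProbeIntensityMatrix) -> ProbeIntensityMatrix:
    """Quantile-normalize intensities so every array shares one distribution.

    After normalization each array's sorted intensity vector equals the
    across-array mean of sorted vectors; tied values within an array receive
    the mean of the reference values at their (average) ranks.
    """
    x = matrix.values.to_numpy(dtype=float)
    n, m = x.shape
    if m < 2:
        raise ValueError("quantile normalization needs at least 2 arrays")
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    grid = np.arange(n, dtype=float)
    for a in range(m):
        ranks = stats.rankdata(x[:, a], method="average") - 1.0
        out[:, a] = np.interp(ranks, grid, reference)
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return ProbeIntensityMatrix(values=values, design=matrix.design)


def median_polish(x: np.ndarray, max_iter: int = 10, tol: float = 1e-6):
    """Tukey median polish of a 2-D array into overall + row + col + residual.

    Iterates row-median and column-median sweeps until the total absolute
    residual changes by less than ``tol`` (relatively) or ``max_iter`` sweeps.

    Returns ``(overall, row_effects, col_effects, residuals)``.
    """
    resid = np.asarray(x, dtype=float).copy()
    nr, nc = resid.shape
    overall = 0.0
    row_eff = np.zeros(nr)
    col_eff = np.zeros(nc)
    last = np.abs(resid).sum()
    for _ in range(max_iter):
        rmed = np.median(resid, axis=1)
        resid -= rmed[:, None]
        row_eff += rmed
        delta = np.median(col_eff)
        overall += delta
        col_eff -= delta

        cmed = np.median(resid, axis=0)
        resid -= cmed[None, :]
        col_eff += cmed
        delta = np.median(row_eff)
        overall += delta
        row_eff -= delta

        total = np.abs(resid).sum()
        if abs(last - total) <= tol * max(1.0, last):
            break
        last = total
    return overall, row_eff, col_eff, resid


def median_polish_condense(matrix: ProbeIntensityMatrix) -> ExpressionMatrix:
    """Condense probe intensities to one expression value per probeset/array.

    Per probeset, median polish on the log2 (probe × array) matrix; the
    per-array log2 expression is overall + array effect.  Anti-logged values
    are then globally rescaled so the experiment-wide median is 10,000.
    """
    if (matrix.values.to_numpy() <= 0).any():
        raise ValueError("non-positive intensity; cannot take log2")
    logx = np.log2(matrix.values.to_numpy(dtype=float))
    codes = matrix.values.index.codes[0]
    probesets = matrix.values.index.levels[0]
    expr = np.empty((len(probesets), logx.shape[1]))
    for k in range(len(probesets)):
        block = logx[codes == k]
        overall, _, col_eff, _ = median_polish(block)
        expr[k] = overall + col_eff
    linear = np.power(2.0, expr)
    factor = TARGET_MEDIAN / np.median(linear)
    values = pd.DataFrame(
        linear * factor, index=pd.Index(probesets, name="probeset"),
        columns=matrix.values.columns,
    )
    return ExpressionMatrix(values=values, design=matrix.design, scale_factor=factor)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, returned in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _ttest_log2(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided pooled-variance Student t-test p-value with degenerate rules.

    Zero variance in both groups: p = 1 when means are equal, 0 otherwise.
    """
    if np.var(a) == 0 and np.var(b) == 0:
        return 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    return float(stats.ttest_ind(a, b, equal_var=True).pvalue)


def _contrast(
    expr: ExpressionMatrix,
    arrays_1: list,
    arrays_2: list,
    label: str,
    fold_min: float,
    fdr: float,
) -> pd.DataFrame:
    lin = expr.values
    log2 = expr.log2
    a1 = log2[arrays_1].to_numpy()
    a2 = log2[arrays_2].to_numpy()
    mean1 = lin[arrays_1].mean(axis=1).to_numpy()
    mean2 = lin[arrays_2].mean(axis=1).to_numpy()
    pvals = np.array([_ttest_log2(a1[i], a2[i]) for i in range(len(lin))])
    q = bh_fdr(pvals)
    ratio = mean1 / mean2
    out = pd.DataFrame(
        {
            "probeset": lin.index,
            "mean_group1": mean1,
            "mean_group2": mean2,
            "ratio": ratio,
            "p": pvals,
            "q": q,
            "contrast": label,
        }
    )
    out["significant"] = (out["q"] <= fdr) & (
        (out["ratio"] >= fold_min) | (out["ratio"] <= 1.0 / fold_min)
    )
    return out


def genotype_contrast(
    expr: ExpressionMatrix,
    fold_min: float = DEFAULT_FOLD,
    fdr: float = DEFAULT_FDR,
) -> pd.DataFrame:
    """LoPro vs HiPro contrast pooling all stages (12 vs 12 arrays).

    Per probeset: pooled-variance Student t-test on log2 expression, ratio of
    linear means (LoPro/HiPro), BH q-values; significant when q ≤ ``fdr`` and
    the ratio passes the fold screen in either direction.
    """
    design = expr.design
    lo = design.index[design["genotype"] == "LoPro"].tolist()
    hi = design.index[design["genotype"] == "HiPro"].tolist()
    if len(lo) < 2 or len(hi) < 2:
        raise ValueError("need >= 2 arrays per genotype")
    return _contrast(expr, lo, hi, "LoPro_vs_HiPro", fold_min, fdr)


def stage_contrast(
    expr: ExpressionMatrix,
    genotype: str,
    stage_b: int,
    stage_a: int,
    fold_min: float = DEFAULT_FOLD,
    fdr: float = DEFAULT_FDR,
) -> pd.DataFrame:
    """Within-genotype contrast of two seed-fill stages (ratio stage_b/stage_a)."""
    design = expr.design
    sel_b = design.index[
        (design["genotype"] == genotype) & (design["stage"] == stage_b)
    ].tolist()
    sel_a = design.index[
        (design["genotype"] == genotype) & (design["stage"] == stage_a)
    ].tolist()
    if len(sel_a) < 2 or len(sel_b) < 2:
        raise ValueError("need >= 2 replicates per stage within the genotype")
    label = f"{genotype}_stage{stage_b}_vs_stage{stage_a}"
    return _contrast(expr, sel_b, sel_a, label, fold_min, fdr)


def two_way_anova(expr: ExpressionMatrix, fdr: float = DEFAULT_FDR) -> pd.DataFrame:
    """Balanced fixed-effects genotype × stage ANOVA on log2 expression.

    Requires the full balanced 2 × S × R design.  Returns per probeset the
    F and p per factor (genotype, stage, interaction), BH q per factor, and
    a ``significant`` flag keyed to the genotype factor's q ≤ ``fdr``.
    Probesets with no residual variance get p = 1 by convention when the
    factor effect is also null, else p = 0.
    """
    design = expr.design
    genos = sorted(design["genotype"].unique())
    stages = sorted(design["stage"].unique())
    a, b = len(genos), len(stages)
    counts = design.groupby(["genotype", "stage"]).size()
    if counts.nunique() != 1 or len(counts) != a * b:
        raise ValueError("unbalanced design; the two-way ANOVA expects equal cells")
    n = int(counts.iloc[0])
    if n < 2:
        raise ValueError("need >= 2 replicates per cell")

    # order arrays as genotype x stage x replicate
    ordered = []
    for g in genos:
        for s in stages:
            cell = design.index[
                (design["genotype"] == g) & (design["stage"] == s)
            ].tolist()
            ordered.extend(sorted(cell))
    x = expr.log2[ordered].to_numpy().reshape(len(expr.values), a, b, n)

    grand = x.mean(axis=(1, 2, 3), keepdims=True)
    m_a = x.mean(axis=(2, 3), keepdims=True)
    m_b = x.mean(axis=(1, 3), keepdims=True)
    m_ab = x.mean(axis=3, keepdims=True)

    ss_a = (b * n) * ((m_a - grand) ** 2).sum(axis=(1, 2, 3))
    ss_b = (a * n) * ((m_b - grand) ** 2).sum(axis=(1, 2, 3))
    ss_ab = n * ((m_ab - m_a - m_b + grand) ** 2).sum(axis=(1, 2, 3))
    ss_e = ((x - m_ab) ** 2).sum(axis=(1, 2, 3))

    df_a, df_b = a - 1, b - 1
    df_ab = df_a * df_b
    df_e = a * b * (n - 1)

    def f_p(ss, df):
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ss / df) / (ss_e / df_e)
        p = stats.f.sf(f, df, df_e)
        degenerate = ss_e <= 0
        p = np.where(degenerate, np.where(ss <= 1e-12, 1.0, 0.0), p)
        return np.where(degenerate, np.nan, f), p

    f_g, p_g = f_p(ss_a, df_a)
    f_s, p_s = f_p(ss_b, df_b)
    f_i, p_i = f_p(ss_ab, df_ab)

    out = pd.DataFrame(
        {
            "probeset": expr.values.index,
            "f_genotype": f_g,
            "p_genotype": p_g,
            "f_stage": f_s,
            "p_stage": p_s,
            "f_interaction": f_i,
            "p_interaction": p_i,
        }
    )
    for factor in ("genotype", "stage", "interaction"):
        out[f"q_{factor}"] = bh_fdr(out[f"p_{factor}"])
    out["significant"] = out["q_genotype"] <= fdr
    return out
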