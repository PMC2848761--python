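"""Single-feature-polymorphism (SFP) detection from probe-level intensities.

A sequence difference between the two NIL genotypes under one probe changes
that probe's hybridization affinity without changing the transcript's
abundance.  Under the additive log2 decomposition

    log2 S(i, j, a) = log2 I(i, a) + A(i, j) + E

(raw probe intensity S, condensed probeset expression I, probe affinity A,
zero-mean error E), the per-array affinity estimate is simply
``log2 S − log2 I``.  A probe is an SFP candidate when its mean affinity
differs between genotypes; significance uses a moderated difference
statistic d = delta / (s + s0) — with s the pooled standard error of the
difference and s0 the median of s over all probes — and a genotype-label
permutation estimate of the false discovery rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .microarray import ExpressionMatrix, ProbeIntensityMatrix


@dataclass
class AffinityMatrix:
    """Per-probe, per-array affinity estimates (log2), plus the array design."""

    values: pd.DataFrame  # (probeset, probe) MultiIndex x arrays
    design: pd.DataFrame


def compute_affinity(
    intensities: ProbeIntensityMatrix, expr: ExpressionMatrix
) -> AffinityMatrix:
    """Estimate probe affinities as log2(intensity) − log2(expression).

    ``intensities`` should be the quantile-normalized probe matrix used to
    produce ``expr``; every probeset present in the intensities must have a
    condensed expression value.
    """
    probesets = intensities.values.index.get_level_values(0)
    missing = set(probesets.unique()) - set(expr.values.index)
    if missing:
        raise ValueError(
            f"probesets without expression values: {sorted(missing)[:5]}..."
            if len(missing) > 5
            else f"probesets without expression values: {sorted(missing)}"
        )
    s_log = np.log2(intensities.values.to_numpy(dtype=float))
    i_log = np.log2(expr.values.loc[probesets, intensities.values.columns].to_numpy())
    values = pd.DataFrame(
        s_log - i_log,
        index=intensities.values.index,
        columns=intensities.values.columns,
    )
    return AffinityMatrix(values=values, design=intensities.design)


def _delta_and_se(x: np.ndarray, g1: np.ndarray, g2: np.ndarray):
    """Mean difference and pooled standard error per row for two array groups."""
    n1, n2 = g1.sum(), g2.sum()
    a, b = x[:, g1], x[:, g2]
    delta = a.mean(axis=1) - b.mean(axis=1)
    sp2 = (a.var(axis=1, ddof=1) * (n1 - 1) + b.var(axis=1, ddof=1) * (n2 - 1)) / (
        n1 + n2 - 2
    )
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return delta, se


def sfp_test(
    affinities: AffinityMatrix,
    n_permutations: int = 200,
    fdr: float = 0.05,
    seed: int = 0,
    s0: float | None = None,
) -> pd.DataFrame:
    """Call SFPs from genotype differences in probe affinity.

    Per probe: delta = mean affinity (LoPro) − mean affinity (HiPro);
    d = delta / (s + s0) with s the pooled standard error and s0 the median
    of s over all probes (pass ``s0=0`` for the unmoderated t statistic).
    The null distribution of |d| comes from ``n_permutations`` random
    permutations of the genotype labels; per probe,
    q = (mean null count of |d| ≥ |d_probe|) / (observed count), made
    monotone in |d| and capped at 1.  ``significant`` is q ≤ ``fdr``.

    Returns a DataFrame with one row per probe; a probeset "contains an SFP"
    when any of its probes is significant (column ``probeset``, summarize
    with :func:`sfp_probeset_summary`).
    """
    if n_permutations < 10:
        raise ValueError("need at least 10 permutations for an FDR estimate")
    design = affinities.design
    arrays = list(affinities.values.columns)
    geno = design.loc[arrays, "genotype"].to_numpy()
    g_lo = geno == "LoPro"
    g_hi = geno == "HiPro"
    if g_lo.sum() < 2 or g_hi.sum() < 2:
        raise ValueError("need >= 2 arrays per genotype")

    x = affinities.values.to_numpy(dtype=float)
    delta, se = _delta_and_se(x, g_lo, g_hi)
    if s0 is None:
        s0 = float(np.median(se))
    with np.errstate(divide="ignore", invalid="ignore"):
        d_obs = delta / (se + s0)
    d_obs = np.nan_to_num(d_obs)
    abs_obs = np.abs(d_obs)

    rng = np.random.default_rng(seed)
    n_lo = int(g_lo.sum())
    null_abs = np.empty((n_permutations, len(abs_obs)))
    for p in range(n_permutations):
        perm = rng.permutation(len(arrays))
        m1 = np.zeros(len(arrays), dtype=bool)
        m1[perm[:n_lo]] = True
        pd_, pse = _delta_and_se(x, m1, ~m1)
        with np.errstate(divide="ignore", invalid="ignore"):
            null_abs[p] = np.abs(np.nan_to_num(pd_ / (pse + s0)))

    # expected false calls at threshold |d_i| vs observed calls
    order = np.argsort(-abs_obs)
    sorted_abs = abs_obs[order]
    null_flat = np.sort(null_abs.ravel())
    # count of null |d| >= t, averaged over permutations
    exceed = len(null_flat) - np.searchsorted(null_flat, sorted_abs, side="left")
    expected = exceed / n_permutations
    observed = np.arange(1, len(sorted_abs) + 1)
    q_sorted = np.minimum.accumulate((expected / observed)[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted

    out = pd.DataFrame(
        {
            "probeset": affinities.values.index.get_level_values(0),
            "probe": affinities.values.index.get_level_values(1),
            "delta": delta,
            "se": se,
            "d_stat": d_obs,
            "q": q,
        }
    )
    out["significant"] = out["q"] <= fdr
    return out


def sfp_probeset_summary(calls: pd.DataFrame) -> pd.DataFrame:
    """Summarize per-probe SFP calls per probeset (any significant probe)."""
    grp = calls.groupby("probeset")
    return pd.DataFrame(
        {
            "n_probes": grp.size(),
            "n_significant": grp["significant"].sum(),
            "max_abs_d": grp["d_stat"].apply(lambda s: s.abs().max()),
            "contains_sfp": grp["significant"].any(),
        }
    ).reset_index()
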