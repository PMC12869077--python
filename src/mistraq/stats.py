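"""Protein summarization, differential testing and kinase-substrate enrichment.

The statistical toolbox mirrors what a label-free proteomics pipeline does
after quantification: Tukey median-polish summarization of precursor
matrices to protein level, pooled-variance two-sample t-tests per feature
with Benjamini-Hochberg adjustment, protein-abundance correction of
phosphosite fold changes, replicate CV distributions for QC, and a
Fisher-exact over-representation test of kinase substrates among regulated
phosphosites (KSEA).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

DEFAULT_ALPHA = 0.05
#: |log2 FC| threshold for calling a feature regulated.  0.585 (fold change
#: 1.5) is the common alternative and is accepted everywhere a threshold is
#: taken.
DEFAULT_FC_THRESHOLD = 0.5


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaNs pass through."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def median_polish(
    matrix: np.ndarray, max_iter: int = 10, tol: float = 1e-6
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Tukey median polish of a 2-D array with NaNs allowed.

    Returns ``(overall, row_effects, col_effects, residuals)`` such that
    ``matrix ~= overall + row + col + residuals`` where observed.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("median_polish expects a 2-D matrix")
    R = X.copy()
    overall = 0.0
    row = np.zeros(X.shape[0])
    col = np.zeros(X.shape[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        for _ in range(max_iter):
            rmed = np.nanmedian(R, axis=1)
            rmed[~np.isfinite(rmed)] = 0.0
            R -= rmed[:, None]
            row += rmed
            cmed = np.nanmedian(R, axis=0)
            cmed[~np.isfinite(cmed)] = 0.0
            R -= cmed[None, :]
            col += cmed
            shift_r = np.median(row)
            row -= shift_r
            shift_c = np.median(col)
            col -= shift_c
            overall += shift_r + shift_c
            moved = max(np.max(np.abs(rmed)), np.max(np.abs(cmed)))
            if moved < tol:
                break
    return overall, row, col, R


def summarize_protein(precursors: pd.DataFrame) -> pd.Series:
    """Summarize a precursor x sample log2 matrix to per-sample abundances.

    The summary for each sample is overall + column effect of the median
    polish; samples with no observed precursor come back NaN.
    """
    overall, _row, col, _res = median_polish(precursors.to_numpy(dtype=float))
    values = overall + col
    observed = precursors.notna().any(axis=0).to_numpy()
    values = np.where(observed, values, np.nan)
    return pd.Series(values, index=precursors.columns)


def differential(
    matrix: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    alpha: float = DEFAULT_ALPHA,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
) -> pd.DataFrame:
    """Per-feature two-sample comparison of log2 abundances (b vs a).

    Pooled-variance t-test with df = na + nb - 2; BH adjustment across
    features; a feature is significant when adj_p < alpha and
    |log2fc| > fc_threshold.  Features with fewer than two observations in
    either group get a fold change (when possible) but no p-value.
    """
    A = matrix[list(group_a)].to_numpy(dtype=float)
    B = matrix[list(group_b)].to_numpy(dtype=float)
    na = np.sum(np.isfinite(A), axis=1)
    nb = np.sum(np.isfinite(B), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_a = np.nanmean(A, axis=1)
        mean_b = np.nanmean(B, axis=1)
        var_a = np.nanvar(A, axis=1, ddof=1)
        var_b = np.nanvar(B, axis=1, ddof=1)
    log2fc = mean_b - mean_a

    df = na + nb - 2.0
    enough = (na >= 2) & (nb >= 2)
    sp2 = np.where(
        enough,
        ((na - 1) * var_a + (nb - 1) * var_b) / np.where(df > 0, df, 1.0),
        np.nan,
    )
    se = np.sqrt(sp2 * (1.0 / np.where(na > 0, na, 1) + 1.0 / np.where(nb > 0, nb, 1)))

    t = np.full(len(matrix), np.nan)
    p = np.full(len(matrix), np.nan)
    nonzero = enough & (se > 0)
    t[nonzero] = log2fc[nonzero] / se[nonzero]
    p[nonzero] = 2.0 * sps.t.sf(np.abs(t[nonzero]), df[nonzero])
    degenerate = enough & (se == 0)
    p[degenerate] = np.where(log2fc[degenerate] == 0, 1.0, 0.0)

    adj_p = bh_adjust(p)
    significant = (
        np.isfinite(adj_p) & (adj_p < alpha) & (np.abs(log2fc) > fc_threshold)
    )
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "se": se,
            "df": np.where(enough, df, np.nan),
            "t": t,
            "p": p,
            "adj_p": adj_p,
            "significant": significant,
            "n_a": na,
            "n_b": nb,
        },
        index=matrix.index,
    )


def adjust_phosphosite(
    site_results: pd.DataFrame,
    protein_results: pd.DataFrame,
    site_protein: Mapping[str, str],
    alpha: float = DEFAULT_ALPHA,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
) -> pd.DataFrame:
    """Correct phosphosite fold changes for their protein's abundance change.

    corrected fc = site fc - protein fc; the standard errors combine in
    quadrature and the degrees of freedom follow Satterthwaite.  Sites whose
    protein has no differential result pass through uncorrected and are
    flagged ``corrected=False``.  BH is re-applied across all reported
    sites.
    """
    fc = site_results["log2fc"].copy()
    se = site_results["se"].copy()
    df = site_results["df"].copy()
    corrected = pd.Series(False, index=site_results.index)

    for site in site_results.index:
        protein = site_protein.get(site)
        if protein is None or protein not in protein_results.index:
            continue
        prow = protein_results.loc[protein]
        if not (np.isfinite(prow["se"]) and np.isfinite(prow["df"])):
            continue
        se_s, se_p = site_results.at[site, "se"], prow["se"]
        df_s, df_p = site_results.at[site, "df"], prow["df"]
        if not (np.isfinite(se_s) and np.isfinite(df_s)):
            continue
        fc[site] = site_results.at[site, "log2fc"] - prow["log2fc"]
        var = se_s**2 + se_p**2
        se[site] = np.sqrt(var)
        if var > 0:
            df[site] = var**2 / (
                se_s**4 / df_s + se_p**4 / df_p
            )
        corrected[site] = True

    t = np.full(len(fc), np.nan)
    p = np.full(len(fc), np.nan)
    ok = np.isfinite(fc) & np.isfinite(se) & np.isfinite(df) & (se > 0)
    t[ok] = fc[ok] / se[ok]
    p[ok] = 2.0 * sps.t.sf(np.abs(t[ok]), df[ok])
    zero = np.isfinite(se) & (se == 0) & np.isfinite(fc)
    p[zero] = np.where(fc[zero] == 0, 1.0, 0.0)

    adj_p = bh_adjust(p)
    significant = (
        np.isfinite(adj_p) & (adj_p < alpha) & (np.abs(fc) > fc_threshold)
    )
    return pd.DataFrame(
        {
            "log2fc": fc,
            "se": se,
            "df": df,
            "p": p,
            "adj_p": adj_p,
            "significant": significant,
            "corrected": corrected,
        },
        index=site_results.index,
    )


def cv_distribution(
    matrix: pd.DataFrame, samples: Sequence[str]
) -> tuple[pd.Series, float]:
    """Per-feature coefficient of variation (percent) within one group.

    Operates on linear-scale intensities.  Features with fewer than two
    observations or non-positive mean are skipped.  Returns the CV series
    and its median.
    """
    X = matrix[list(samples)].to_numpy(dtype=float)
    n = np.sum(np.isfinite(X), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(X, axis=1)
        sd = np.nanstd(X, axis=1, ddof=1)
    keep = (n >= 2) & (mean > 0)
    cv = pd.Series(100.0 * sd[keep] / mean[keep], index=matrix.index[keep])
    median = float(cv.median()) if len(cv) else float("nan")
    return cv, median


def fisher_upper_tail(a: int, b: int, c: int, d: int) -> float:
    """One-sided Fisher exact p for enrichment in cell ``a`` of a 2x2 table.

    Rows: in-set / out-of-set, columns: regulated / not.  Equals the
    hypergeometric upper tail P(X >= a) drawing a+b from a population of
    a+b+c+d with a+c successes.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    if a + b + c + d == 0:
        return 1.0
    return float(sps.hypergeom.sf(a - 1, a + b + c + d, a + c, a + b))


@dataclass
class KseaResult:
    kinase_id: str
    direction: str
    n_substrates_quantified: int
    n_regulated: int
    p: float
    adj_p: float = float("nan")
    reported: bool = False


def ksea(
    site_results: pd.DataFrame,
    annotations: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    min_regulated: int = 4,
    method: str = "fisher",
) -> pd.DataFrame:
    """Kinase-substrate enrichment among up- and downregulated phosphosites.

    ``site_results`` is indexed by site id (``protein:position``) with
    ``log2fc`` and ``adj_p`` columns; ``annotations`` has ``kinase``,
    ``protein`` and ``site`` columns.  For each kinase and direction a
    one-sided Fisher exact test asks whether the kinase's quantified
    substrates are over-represented among sites regulated in that
    direction; BH runs across kinase x direction.  Only kinases with more
    than ``min_regulated`` regulated substrates are flagged ``reported``.

    ``method='zscore'`` instead scores each kinase by the standardized mean
    fold change of its substrates (two-sided normal p).
    """
    quantified = set(site_results.index[np.isfinite(site_results["log2fc"])])
    n_quant = len(quantified)
    sig = (
        np.isfinite(site_results["adj_p"])
        & (site_results["adj_p"] < alpha)
        & (np.abs(site_results["log2fc"]) > fc_threshold)
    )
    up = set(site_results.index[sig & (site_results["log2fc"] > 0)])
    down = set(site_results.index[sig & (site_results["log2fc"] < 0)])

    substrate_sets: dict[str, set] = {}
    for row in annotations.itertuples(index=False):
        site_id = f"{row.protein}:{int(row.site)}"
        if site_id in quantified:
            substrate_sets.setdefault(row.kinase, set()).add(site_id)

    results: list[KseaResult] = []
    if method == "fisher":
        for kinase, subs in sorted(substrate_sets.items()):
            for direction, regulated in (("up", up), ("down", down)):
                a = len(subs & regulated)
                b = len(subs) - a
                c = len(regulated) - a
                d = n_quant - len(subs) - c
                p = fisher_upper_tail(a, b, c, d)
                results.append(
                    KseaResult(kinase, direction, len(subs), a, p)
                )
    elif method == "zscore":
        fc = site_results["log2fc"]
        mu, sd = float(fc.mean()), float(fc.std(ddof=1))
        for kinase, subs in sorted(substrate_sets.items()):
            sub_fc = fc[list(subs)]
            m = len(subs)
            z = (float(sub_fc.mean()) - mu) * np.sqrt(m) / sd if sd > 0 else 0.0
            p = float(2.0 * sps.norm.sf(abs(z)))
            direction = "up" if z > 0 else "down"
            n_reg = len(subs & (up | down))
            results.append(KseaResult(kinase, direction, m, n_reg, p))
    else:
        raise ValueError(f"unknown KSEA method: {method!r}")

    frame = pd.DataFrame(
        {
            "kinase_id": [r.kinase_id for r in results],
            "direction": [r.direction for r in results],
            "n_substrates_quantified": [
                r.n_substrates_quantified for r in results
            ],
            "n_regulated": [r.n_regulated for r in results],
            "p": [r.p for r in results],
        }
    )
    frame["adj_p"] = bh_adjust(frame["p"])
    frame["reported"] = (frame["adj_p"] < alpha) & (
        frame["n_regulated"] > min_regulated
    )
    return frame
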