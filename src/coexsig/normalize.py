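"""Counts → covariate-cleaned log2 expression.

The stage ladder is: remove genes with zero counts in every sample, convert
to log2 FPKM, remove sample-specific GC/length trends and quantile
normalize, then regress out sex/batch indicator covariates per gene.  QC
helpers flag sex-discordant samples (XIST-like vs Y-marker expression) and
low-connectivity outlier samples.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset, StageError


def filter_zero_genes(ds: ExpressionDataset) -> ExpressionDataset:
    """Drop genes whose counts are zero in all samples (order preserved)."""
    ds.require_stage("raw")
    keep = ds.values.sum(axis=1) > 0
    return ds.subset_genes(ds.values.index[keep])


def log2_fpkm(ds: ExpressionDataset) -> ExpressionDataset:
    """log2( (count + 0.5) * 1e9 / (library_size * length_bp) ).

    Library size is the per-sample total count; the 0.5 pseudocount keeps
    zeros finite.
    """
    ds.require_stage("raw")
    libsize = ds.values.sum(axis=0).to_numpy(float)
    if (libsize == 0).any():
        bad = ds.values.columns[libsize == 0].tolist()
        raise ValueError(f"zero library size for samples: {bad}")
    counts = ds.values.to_numpy(float)
    lengths = ds.genes["length_bp"].to_numpy(float)
    fpkm = (counts + 0.5) * 1e9 / (libsize[None, :] * lengths[:, None])
    values = pd.DataFrame(np.log2(fpkm), index=ds.values.index, columns=ds.values.columns)
    return ds.with_values(values, stage="log2fpkm")


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Full quantile normalization: every column gets the mean sorted profile."""
    arr = values.to_numpy(float)
    ref = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        ranks = pd.Series(arr[:, j]).rank(method="average").to_numpy() - 1.0
        lo = np.floor(ranks).astype(int)
        hi = np.ceil(ranks).astype(int)
        out[:, j] = 0.5 * (ref[lo] + ref[hi])  # ties land on averaged positions
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def cqn_like_normalize(ds: ExpressionDataset, quantile: bool = True) -> ExpressionDataset:
    """Remove per-sample GC/length trends, then quantile normalize.

    Per sample, expression is regressed on a quadratic in GC fraction plus
    log10 gene length; the fitted systematic effect is subtracted and the
    column re-centered to preserve the sample mean.  A full quantile
    normalization across samples follows by default.

    ``quantile=False`` keeps only the detrending step.  Full quantile
    normalization assumes most genes do not vary in a coordinated way
    between samples; when co-expression modules make up a large share of
    the gene universe (as in small simulated datasets) it redistributes
    module shifts onto the remaining genes, so recovery experiments at
    that scale are better run without it.
    """
    ds.require_stage("log2fpkm")
    if ds.n_samples < 3:
        raise ValueError("quantile normalization needs at least 3 samples")
    gc = ds.genes["gc_frac"].to_numpy(float)
    loglen = np.log10(ds.genes["length_bp"].to_numpy(float))
    gc_c = gc - gc.mean()
    X = np.column_stack(
        [np.ones_like(gc), gc_c, gc_c**2 - (gc_c**2).mean(), loglen - loglen.mean()]
    )
    arr = ds.values.to_numpy(float).copy()
    for j in range(arr.shape[1]):
        beta, *_ = np.linalg.lstsq(X, arr[:, j], rcond=None)
        fitted = X @ beta
        arr[:, j] -= fitted - arr[:, j].mean()
    detrended = pd.DataFrame(arr, index=ds.values.index, columns=ds.values.columns)
    if quantile:
        detrended = quantile_normalize(detrended)
    return ds.with_values(detrended, stage="normalized")


def regress_covariates(
    ds: ExpressionDataset, covariates: tuple[str, ...] = ("sex", "batch")
) -> ExpressionDataset:
    """Per-gene OLS on indicator-coded covariates; keep residual + grand mean.

    Covariates constant across samples are skipped with a warning (nothing
    to remove).
    """
    ds.require_stage("normalized")
    unknown = set(covariates) - {"sex", "batch"}
    if unknown:
        raise ValueError(f"unsupported covariates: {sorted(unknown)}")
    cols = [np.ones(ds.n_samples)]
    for cov in covariates:
        levels = ds.samples[cov]
        if levels.nunique() < 2:
            warnings.warn(f"covariate {cov!r} is constant across samples; skipped")
            continue
        dummies = pd.get_dummies(levels, drop_first=True).to_numpy(float)
        cols.append(dummies)
    X = np.column_stack(cols)
    Y = ds.values.to_numpy(float).T          # samples x genes
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    out = resid.T + Y.mean(axis=0)[:, None]
    values = pd.DataFrame(out, index=ds.values.index, columns=ds.values.columns)
    return ds.with_values(values, stage="residualized")


def qc_sex_check(
    ds: ExpressionDataset, female_marker: str, male_markers: tuple[str, ...]
) -> list[str]:
    """Samples whose expression-predicted sex conflicts with metadata sex.

    Predicted female: female-marker expression above the cohort midpoint
    and mean male-marker expression below its midpoint; male for the
    reverse; otherwise unknown (never flagged).
    """
    for marker in (female_marker, *male_markers):
        if marker not in ds.values.index:
            raise ValueError(f"sex marker gene {marker!r} absent from dataset")
    f_expr = ds.values.loc[female_marker]
    m_expr = ds.values.loc[list(male_markers)].mean(axis=0)
    f_mid = (f_expr.max() + f_expr.min()) / 2.0
    m_mid = (m_expr.max() + m_expr.min()) / 2.0
    flagged = []
    for sample in ds.values.columns:
        if f_expr[sample] > f_mid and m_expr[sample] < m_mid:
            predicted = "F"
        elif f_expr[sample] < f_mid and m_expr[sample] > m_mid:
            predicted = "M"
        else:
            predicted = "unknown"
        recorded = ds.samples.loc[sample, "sex"]
        if predicted != "unknown" and recorded != "unknown" and predicted != recorded:
            flagged.append(sample)
    return flagged


def detect_outlier_samples(ds: ExpressionDataset, z_cut: float = -2.5) -> list[str]:
    """Low-connectivity samples in the sample–sample correlation network.

    Sample adjacency ((1 + cor)/2)^2, connectivity k = row sum, flagged
    when standardized Z.k falls below `z_cut`.
    """
    ds.require_stage("normalized", "residualized")
    if ds.n_samples < 4:
        raise ValueError("outlier detection needs at least 4 samples")
    cor = np.corrcoef(ds.values.to_numpy(float).T)
    A = ((1.0 + cor) / 2.0) ** 2
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    sd = k.std(ddof=1)
    if sd == 0:
        return []
    z = (k - k.mean()) / sd
    return [s for s, zi in zip(ds.values.columns, z) if zi < z_cut]
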