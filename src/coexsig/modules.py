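"""Module eigengenes, disease association and gene-set overlap statistics.

The module eigengene (ME) is the first principal component of a module's
standardized expression — one value per sample per module — with its sign
aligned to the module's mean standardized expression so results do not
depend on the arbitrary SVD sign.  Disease association is the Pearson
correlation of each eigengene with the 0/1 case indicator; a module is
disease-associated at unadjusted p < 0.05.  Overlap between module
catalogs from two networks uses the upper-tail hypergeometric probability
(observed count included).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

GREY = 0


@dataclass
class EigengeneSet:
    """Samples × modules eigengene matrix with projection metadata.

    ``values`` columns are module labels; each column has zero mean and
    unit variance over samples.  ``loadings`` (per module: gene ids,
    training means/sds, left singular vector, scale factors) support
    projecting new samples onto the training eigengenes.
    """

    values: pd.DataFrame
    variance_explained: pd.Series
    loadings: dict = field(default_factory=dict, repr=False)
    sign_convention: str = "mean-expression-aligned"

    @property
    def modules(self) -> list[int]:
        return list(self.values.columns)


def _standardize_rows(sub: pd.DataFrame) -> np.ndarray:
    arr = sub.to_numpy(float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    if (sd == 0).any():
        bad = sub.index[(sd == 0).ravel()].tolist()
        raise ValueError(f"zero-variance genes: {bad[:10]}")
    return (arr - mean) / sd


def compute_eigengenes(values: pd.DataFrame, labels) -> EigengeneSet:
    """First principal component per module, unit variance, sign-aligned.

    Parameters
    ----------
    values : genes × samples expression (any post-count stage).
    labels : per-gene module ids aligned with `values` rows; 0 = grey.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != values.shape[0]:
        raise ValueError("labels are not aligned with expression rows")
    out = {}
    var_exp = {}
    loadings = {}
    for k in sorted(set(labels) - {GREY}):
        members = values.index[labels == k]
        if len(members) < 2:
            raise ValueError(f"module {k} has fewer than 2 genes")
        sub = values.loc[members]
        X = _standardize_rows(sub)
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        me = Vt[0]
        mean_profile = X.mean(axis=0)
        sign = 1.0
        if np.corrcoef(me, mean_profile)[0, 1] < 0:
            sign = -1.0
        me = sign * me
        scale = me.std(ddof=1)
        out[k] = me / scale
        var_exp[k] = float(s[0] ** 2 / (s**2).sum())
        loadings[k] = {
            "gene_ids": list(members),
            "gene_mean": sub.to_numpy(float).mean(axis=1),
            "gene_sd": sub.to_numpy(float).std(axis=1, ddof=1),
            "u1": sign * U[:, 0],
            "s1": float(s[0]),
            "me_scale": float(scale),
        }
    me_df = pd.DataFrame(out, index=values.columns)
    return EigengeneSet(
        values=me_df,
        variance_explained=pd.Series(var_exp, dtype=float),
        loadings=loadings,
    )


def module_trait_association(mes: EigengeneSet | pd.DataFrame, status) -> pd.DataFrame:
    """Pearson r of each eigengene with the 0/1 case indicator.

    p-values come from t = r sqrt((n-2)/(1-r^2)) on n-2 degrees of
    freedom (two-sided); ``disease_associated`` flags unadjusted p < 0.05.
    """
    me = mes.values if isinstance(mes, EigengeneSet) else mes
    y = _status_indicator(status, me.index)
    if y.nunique() < 2:
        raise ValueError("both status levels are required")
    if y.value_counts().min() < 3:
        raise ValueError("need at least 3 samples per status group")
    n = len(y)
    rows = []
    for k in me.columns:
        r = float(np.corrcoef(me[k], y)[0, 1])
        r_ = min(max(r, -1 + 1e-15), 1 - 1e-15)
        t = r_ * np.sqrt((n - 2) / (1 - r_**2))
        p = 2 * stats.t.sf(abs(t), df=n - 2)
        rows.append({"module": k, "r": r, "p": p, "disease_associated": p < 0.05})
    return pd.DataFrame(rows).set_index("module")


def _status_indicator(status, index) -> pd.Series:
    s = pd.Series(status)
    if not s.index.equals(pd.Index(index)):
        s = pd.Series(np.asarray(status), index=index)
    if s.dtype == object or str(s.dtype) == "category":
        s = (s == "case").astype(float)
    return s.astype(float)


# ---------------------------------------------------------------------------
# hypergeometric overlap


@dataclass
class OverlapResult:
    """Pairwise module overlap between two networks."""

    table: pd.DataFrame            # module_a, module_b, overlap, p
    best_match: pd.Series          # module_a -> module_b with minimal p

    def p(self, a, b) -> float:
        sel = self.table[(self.table["module_a"] == a) & (self.table["module_b"] == b)]
        return float(sel["p"].iloc[0])


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n); observed count included."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def hypergeometric_overlap(
    modules_a: dict, modules_b: dict, universe: int | set
) -> OverlapResult:
    """Upper-tail hypergeometric overlap p for every module pair.

    ``universe`` is either the shared-universe size or the explicit gene
    universe (membership is then validated).  Best match per module of
    network A is the partner with minimal p (ties to the smaller p then
    the first label).
    """
    if isinstance(universe, (int, np.integer)):
        N = int(universe)
        uni = None
    else:
        uni = set(universe)
        N = len(uni)
    rows = []
    for a, genes_a in modules_a.items():
        sa = set(genes_a)
        if uni is not None and not sa <= uni:
            raise ValueError(f"module {a} of network A is not within the universe")
        if len(sa) > N:
            raise ValueError(f"module {a} larger than the universe")
        for b, genes_b in modules_b.items():
            sb = set(genes_b)
            if uni is not None and not sb <= uni:
                raise ValueError(f"module {b} of network B is not within the universe")
            if len(sb) > N:
                raise ValueError(f"module {b} larger than the universe")
            k = len(sa & sb)
            rows.append(
                {
                    "module_a": a,
                    "module_b": b,
                    "overlap": k,
                    "size_a": len(sa),
                    "size_b": len(sb),
                    "p": hypergeom_upper_tail(k, N, len(sa), len(sb)),
                }
            )
    table = pd.DataFrame(rows)
    best = (
        table.sort_values(["module_a", "p", "module_b"])
        .groupby("module_a", sort=False)
        .first()["module_b"]
    )
    return OverlapResult(table=table, best_match=best)


# ---------------------------------------------------------------------------
# differential expression stand-in and enrichment


def simple_de_test(
    values: pd.DataFrame, status, q_threshold: float = 0.05
) -> pd.DataFrame:
    """Per-gene Welch t-test on log2 expression with BH correction.

    A deliberately simple differential-expression screen whose only
    pipeline role is to provide a DE flag for enrichment statistics.
    Genes constant in both groups get p = 1 with a warning.
    """
    y = _status_indicator(status, values.columns).to_numpy() > 0.5
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("need at least 2 samples per group")
    a = values.to_numpy(float)[:, y]
    b = values.to_numpy(float)[:, ~y]
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    degenerate = np.isnan(p)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} genes constant in both groups; p set to 1"
        )
        p = np.where(degenerate, 1.0, p)
        t = np.where(degenerate, 0.0, t)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame(
        {"t": t, "p": p, "q": q, "de": q < q_threshold}, index=values.index
    )


def de_enrichment(module_genes, de_genes, universe) -> tuple[int, int, float]:
    """(overlap k, module size K tested, upper-tail hypergeometric p).

    The universe is parameterized (all expressed genes or all network
    genes) since enrichment depends on that choice.
    """
    if isinstance(universe, (int, np.integer)):
        N = int(universe)
        module = set(module_genes)
        de = set(de_genes)
    else:
        uni = set(universe)
        N = len(uni)
        module = set(module_genes)
        de = set(de_genes)
        if not module <= uni or not de <= uni:
            raise ValueError("module or DE genes fall outside the universe")
    k = len(module & de)
    p = hypergeom_upper_tail(k, N, len(de), len(module))
    return k, len(module), p
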