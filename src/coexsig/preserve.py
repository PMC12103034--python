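"""Permutation-based module preservation between two expression datasets.

For each reference module, three statistics are evaluated in the test
data over the module's genes: mean intra-module adjacency (density), the
correlation of intra-module connectivity profiles between datasets
(cor.kIM), and the correlation of the gene–gene correlation patterns
(cor.cor).  A permutation null redraws gene sets of identical size from
the shared universe; each statistic is standardized against its null to a
Z score, the two connectivity Zs are averaged into Z_connectivity, and

    Zsummary = (Z_density + Z_connectivity) / 2,

with Zsummary >= 2 taken as preserved.  The composite biomarker rule
declares a reference module positive in a test dataset only when it is
preserved there AND its most-equivalent test module (minimal
hypergeometric overlap p) is disease-associated in the test data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .modules import OverlapResult

GREY = 0
PRESERVED_Z = 2.0


@dataclass
class PreservationReport:
    """Per-module observed statistics, permutation nulls and Z scores."""

    table: pd.DataFrame          # indexed by module
    n_permutations: int
    seed: int
    power: int

    def zsummary(self, module) -> float:
        return float(self.table.loc[module, "z_summary"])

    def preserved(self, module) -> bool:
        return bool(self.table.loc[module, "preserved"])


def _stats_for_set(
    idx: np.ndarray,
    adj_test: np.ndarray,
    cor_ref: np.ndarray,
    cor_test: np.ndarray,
) -> tuple[float, float, float]:
    """(density, cor.kIM, cor.cor) for one gene set."""
    a = adj_test[np.ix_(idx, idx)].copy()
    np.fill_diagonal(a, 0.0)
    m = len(idx)
    density = a.sum() / (m * (m - 1))

    cr = cor_ref[np.ix_(idx, idx)].copy()
    ct = cor_test[np.ix_(idx, idx)].copy()
    np.fill_diagonal(cr, 0.0)
    np.fill_diagonal(ct, 0.0)
    k_ref = np.abs(cr).sum(axis=1)
    k_test = np.abs(ct).sum(axis=1)
    cor_kim = _safe_cor(k_ref, k_test)

    iu = np.triu_indices(m, k=1)
    cor_cor = _safe_cor(cr[iu], ct[iu])
    return float(density), cor_kim, cor_cor


def _safe_cor(x: np.ndarray, y: np.ndarray) -> float:
    # guard numerically-constant vectors (float noise around a constant
    # would otherwise turn into an arbitrary correlation)
    if x.std() <= 1e-9 * (1.0 + np.abs(x).max()) or y.std() <= 1e-9 * (1.0 + np.abs(y).max()):
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def module_preservation(
    ref_values: pd.DataFrame,
    labels,
    test_values: pd.DataFrame,
    n_perm: int = 50,
    seed: int = 1,
    power: int = 4,
) -> PreservationReport:
    """Preservation Z statistics of reference modules in a test dataset.

    ``ref_values`` and ``test_values`` are genes × samples matrices over a
    (pre-mapped) shared gene universe; ``labels`` assigns reference module
    ids (0 = grey, excluded).  Modules missing more than 10% of their
    genes from the test data are an error.  With the seed fixed the
    report is bit-identical across runs.
    """
    if test_values.shape[1] < 10:
        raise ValueError("test dataset needs at least 10 samples")
    labels = pd.Series(np.asarray(labels), index=ref_values.index)
    shared = ref_values.index.intersection(test_values.index)
    modules = sorted(set(labels) - {GREY})
    if not modules:
        raise ValueError("no non-grey reference modules")
    for k in modules:
        genes = labels.index[labels == k]
        missing = 1.0 - genes.isin(shared).mean()
        if missing > 0.10:
            raise ValueError(
                f"module {k}: {missing:.0%} of genes absent from the test data"
            )
    ref = ref_values.loc[shared]
    test = test_values.loc[shared]
    pos = pd.Series(np.arange(len(shared)), index=shared)

    cor_ref = np.corrcoef(ref.to_numpy(float))
    cor_test = np.corrcoef(test.to_numpy(float))
    adj_test = np.abs(cor_test) ** power

    rng = np.random.default_rng(seed)
    stat_names = ("density", "cor_kim", "cor_cor")
    rows = []
    for k in modules:
        genes = labels.index[labels == k]
        idx = pos[genes[genes.isin(shared)]].to_numpy()
        obs = _stats_for_set(idx, adj_test, cor_ref, cor_test)
        null = np.empty((n_perm, 3))
        for p in range(n_perm):
            rand_idx = rng.choice(len(shared), size=len(idx), replace=False)
            null[p] = _stats_for_set(rand_idx, adj_test, cor_ref, cor_test)
        mean, sd = null.mean(axis=0), null.std(axis=0, ddof=1)
        # a statistic whose permutation distribution is a constant carries no
        # information (e.g. every connectivity correlation is exactly 1 when
        # the test data ARE the reference data); exclude it from the
        # composite, and error only when nothing informative remains
        degenerate = sd <= 1e-9 * np.maximum(1.0, np.abs(mean))
        if degenerate.all():
            names = ", ".join(stat_names)
            raise ValueError(
                f"module {k}: permutation sd of every statistic ({names}) is zero"
            )
        z = np.full(3, np.nan)
        ok = ~degenerate
        z[ok] = (np.asarray(obs)[ok] - mean[ok]) / sd[ok]
        conn = [z[i] for i in (1, 2) if not degenerate[i]]
        z_connectivity = float(np.mean(conn)) if conn else np.nan
        parts = [v for v in (z[0], z_connectivity) if np.isfinite(v)]
        z_summary = float(np.mean(parts))
        rows.append(
            {
                "module": k,
                "size": len(idx),
                "density": obs[0],
                "cor_kim": obs[1],
                "cor_cor": obs[2],
                "null_mean_density": mean[0],
                "null_mean_cor_kim": mean[1],
                "null_mean_cor_cor": mean[2],
                "null_sd_density": sd[0],
                "null_sd_cor_kim": sd[1],
                "null_sd_cor_cor": sd[2],
                "z_density": z[0],
                "z_cor_kim": z[1],
                "z_cor_cor": z[2],
                "z_connectivity": z_connectivity,
                "z_summary": z_summary,
                "preserved": z_summary >= PRESERVED_Z,
            }
        )
    table = pd.DataFrame(rows).set_index("module")
    return PreservationReport(table=table, n_permutations=n_perm, seed=seed, power=power)


def biomarker_positive(
    preservation: PreservationReport,
    overlap: OverlapResult,
    test_association: pd.DataFrame,
) -> pd.Series:
    """Composite positivity rule per reference module.

    Positive iff Zsummary >= 2 in the test data AND the best-match test
    module is disease-associated there.  A module without a best match is
    negative with a warning.
    """
    out = {}
    for module in preservation.table.index:
        preserved = preservation.preserved(module)
        if module not in overlap.best_match.index:
            warnings.warn(f"module {module}: no best-match test module; negative")
            out[module] = False
            continue
        partner = overlap.best_match[module]
        if partner not in test_association.index:
            warnings.warn(f"module {module}: best match {partner} has no association; negative")
            out[module] = False
            continue
        associated = bool(test_association.loc[partner, "disease_associated"])
        out[module] = bool(preserved and associated)
    return pd.Series(out, name="biomarker_positive")
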