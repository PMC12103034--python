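"""Module-eigengene disease classifiers with exact binomial performance.

The classifier treats each disease-associated module's eigengene (ME) as a
one-dimensional test statistic.  For a sample s and module m, a one-sample
two-sided t-test compares the training controls' ME distribution against
the hypothesized mean mu0 = ME_s:

    t = (control_mean - ME_s) / (control_sd / sqrt(n)),  df = n - 1.

The sample is called positive for m when p < alpha AND its ME lies on the
patient side of the control mean (direction gate).  Module combinations
use an OR rule (any positive member module makes the sample positive), and
a shallow CART-style decision tree over two module MEs is available as an
independent rule.  Performance (sensitivity/specificity at individual or
family level) is reported with exact Clopper–Pearson 95% intervals, and
classifiers are compared with Fisher's exact test.

The API follows the model/results convention: build an
:class:`EigengeneClassifier` from eigengenes + status, call ``fit`` to get
:class:`ClassifierResults`, then ``classify`` / ``performance`` /
``summary`` on the results object.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .modules import EigengeneSet


# ---------------------------------------------------------------------------
# exact binomial machinery


def clopper_pearson(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact two-sided binomial confidence interval (Beta quantiles)."""
    if n < 1 or not 0 <= k <= n:
        raise ValueError(f"invalid counts k={k}, n={n}")
    alpha = 1.0 - conf
    lower = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lower, upper


def percent(x: float) -> int:
    """Integer percent, rounding half away from zero (reporting convention)."""
    return int(math.floor(abs(x) * 100 + 0.5)) * (1 if x >= 0 else -1)


def compare_classifiers(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided Fisher exact p for detection counts of two classifiers."""
    for k, n in ((k1, n1), (k2, n2)):
        if n < 0 or not 0 <= k <= n:
            raise ValueError(f"invalid counts k={k}, n={n}")
    table = [[k1, n1 - k1], [k2, n2 - k2]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


# ---------------------------------------------------------------------------
# model containers


@dataclass
class ModuleProfile:
    """Training summary of one module's eigengene distribution."""

    control_mean: float
    control_sd: float
    control_n: int
    patient_mean: float

    @property
    def direction(self) -> float:
        """Sign of the patient shift relative to controls."""
        return float(np.sign(self.patient_mean - self.control_mean))


@dataclass
class TreeSplit:
    """One binary split of a shallow decision tree; left = ME <= threshold."""

    module: object
    threshold: float
    left: "TreeSplit | bool"
    right: "TreeSplit | bool"

    def predict(self, me_row: Mapping) -> bool:
        branch = self.left if me_row[self.module] <= self.threshold else self.right
        return branch.predict(me_row) if isinstance(branch, TreeSplit) else bool(branch)

    def nodes(self) -> list[tuple]:
        out = [(self.module, self.threshold)]
        for branch in (self.left, self.right):
            if isinstance(branch, TreeSplit):
                out.extend(branch.nodes())
        return out


@dataclass
class ClassificationResult:
    """Per-sample and per-family classification calls."""

    sample_table: pd.DataFrame       # per-module p_<m>/call_<m> columns + overall call
    family_calls: pd.Series          # family id -> OR over affected members

    @property
    def calls(self) -> pd.Series:
        return self.sample_table["call"]


@dataclass
class PerformanceReport:
    """Sensitivity/specificity with exact 95% binomial intervals."""

    level: str
    k_sens: int
    n_sens: int
    k_spec: int | None = None
    n_spec: int | None = None
    conf: float = 0.95
    ci_method: str = "clopper-pearson"

    @property
    def sensitivity(self) -> float:
        return self.k_sens / self.n_sens

    @property
    def specificity(self) -> float | None:
        if self.n_spec is None:
            return None
        return self.k_spec / self.n_spec

    @property
    def sensitivity_ci(self) -> tuple[float, float]:
        return clopper_pearson(self.k_sens, self.n_sens, self.conf)

    @property
    def specificity_ci(self) -> tuple[float, float] | None:
        if self.n_spec is None:
            return None
        return clopper_pearson(self.k_spec, self.n_spec, self.conf)

    def summary(self) -> str:
        lo, hi = self.sensitivity_ci
        lines = [
            f"{self.level}-level performance (95% CI, {self.ci_method})",
            f"  sensitivity {percent(self.sensitivity)}% "
            f"[{percent(lo)}%-{percent(hi)}%]  ({self.k_sens}/{self.n_sens})",
        ]
        if self.n_spec is not None:
            slo, shi = self.specificity_ci
            lines.append(
                f"  specificity {percent(self.specificity)}% "
                f"[{percent(slo)}%-{percent(shi)}%]  ({self.k_spec}/{self.n_spec})"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = {
            "level": self.level,
            "k_sens": self.k_sens,
            "n_sens": self.n_sens,
            "sensitivity": self.sensitivity,
            "sensitivity_ci": list(self.sensitivity_ci),
        }
        if self.n_spec is not None:
            d.update(
                k_spec=self.k_spec,
                n_spec=self.n_spec,
                specificity=self.specificity,
                specificity_ci=list(self.specificity_ci),
            )
        return d


# ---------------------------------------------------------------------------
# fitting


def _me_frame(mes) -> pd.DataFrame:
    return mes.values if isinstance(mes, EigengeneSet) else mes


def fit_disease_profile(
    mes, status, disease_modules: Sequence, alpha: float = 0.05
) -> dict:
    """Per-module control mean/sd/n and patient mean (direction anchor).

    Training samples are those with status case/control; a degenerate
    control sd of zero is an error.
    """
    me = _me_frame(mes)
    status = pd.Series(status, index=me.index) if not isinstance(status, pd.Series) else status
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    controls = me.loc[status == "control"]
    patients = me.loc[status == "case"]
    if len(controls) < 3:
        raise ValueError("need at least 3 training controls")
    if len(patients) < 1:
        raise ValueError("need at least 1 training patient")
    profiles = {}
    for m in disease_modules:
        if m not in me.columns:
            raise ValueError(f"module {m!r} absent from the eigengene matrix")
        sd = float(controls[m].std(ddof=1))
        if sd == 0:
            raise ValueError(f"degenerate control eigengene (sd = 0) for module {m!r}")
        profiles[m] = ModuleProfile(
            control_mean=float(controls[m].mean()),
            control_sd=sd,
            control_n=int(len(controls)),
            patient_mean=float(patients[m].mean()),
        )
    return profiles


def classify_sample_single(profile: ModuleProfile, me_value: float, alpha: float = 0.05) -> tuple[float, bool]:
    """One-sample t-test of the control ME distribution against mu0 = ME_s.

    Positive requires p < alpha AND the sample lying on the patient side
    of the control mean.
    """
    if profile.control_sd == 0:
        raise ValueError("degenerate control sd")
    t = (profile.control_mean - me_value) / (
        profile.control_sd / math.sqrt(profile.control_n)
    )
    p = float(2 * stats.t.sf(abs(t), df=profile.control_n - 1))
    on_patient_side = (
        np.sign(me_value - profile.control_mean) == profile.direction
        and profile.direction != 0
    )
    return p, bool(p < alpha and on_patient_side)


def classify_combination(
    profiles: Mapping, me_row: Mapping, modules: Sequence, alpha: float = 0.05
) -> bool:
    """OR rule: positive iff any member module's single call is positive."""
    if not modules:
        raise ValueError("empty module list")
    return any(
        classify_sample_single(profiles[m], me_row[m], alpha)[1] for m in modules
    )


# -- decision tree ----------------------------------------------------------


def _gini(labels: np.ndarray) -> float:
    if labels.size == 0:
        return 0.0
    p = labels.mean()
    return 2 * p * (1 - p)


def _best_split(x: np.ndarray, y: np.ndarray) -> tuple[float, float] | None:
    """Midpoint threshold minimizing weighted Gini impurity, or None."""
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    uniq = np.unique(xs)
    if uniq.size < 2:
        return None
    best = None
    for a, b in zip(uniq[:-1], uniq[1:]):
        thr = (a + b) / 2.0
        left = ys[xs <= thr]
        right = ys[xs > thr]
        imp = (left.size * _gini(left) + right.size * _gini(right)) / ys.size
        if best is None or imp < best[0] - 1e-12:
            best = (imp, thr)
    return (best[1], best[0]) if best is not None else None


def _leaf(y: np.ndarray) -> bool:
    """Majority label; ties toward control (negative)."""
    return bool(y.mean() > 0.5)


def fit_decision_tree(mes, status, max_depth: int = 2) -> TreeSplit:
    """Greedy Gini tree over two module MEs, at most one split per module.

    Thresholds are deterministic midpoints between consecutive observed
    values; leaves carry the training majority call with ties toward
    control.  Refitting identical data reproduces identical thresholds.
    """
    me = _me_frame(mes)
    status = pd.Series(status, index=me.index) if not isinstance(status, pd.Series) else status
    train = status.isin(["case", "control"])
    me = me.loc[train]
    y = (status.loc[train] == "case").to_numpy(float)
    if y.min() == y.max():
        raise ValueError("decision tree needs both classes in training data")
    modules = list(me.columns)

    # root: best split over all modules (first module wins ties)
    root_choice = None
    for m in modules:
        res = _best_split(me[m].to_numpy(float), y)
        if res is None:
            continue
        thr, imp = res
        if root_choice is None or imp < root_choice[0] - 1e-12:
            root_choice = (imp, m, thr)
    if root_choice is None:
        raise ValueError("no usable split (constant eigengenes)")
    _, root_m, root_thr = root_choice
    mask_left = me[root_m].to_numpy(float) <= root_thr
    tree = TreeSplit(root_m, root_thr, _leaf(y[mask_left]), _leaf(y[~mask_left]))

    if max_depth >= 2:
        remaining = [m for m in modules if m != root_m]
        best_child = None   # (impurity_gain, side, module, thr, mask)
        for side, mask in (("left", mask_left), ("right", ~mask_left)):
            base = _gini(y[mask]) * mask.sum()
            for m in remaining:
                res = _best_split(me[m].to_numpy(float)[mask], y[mask])
                if res is None:
                    continue
                thr, imp = res
                gain = base - imp * mask.sum()
                if gain > 1e-12 and (best_child is None or gain > best_child[0] + 1e-12):
                    best_child = (gain, side, m, thr, mask)
        if best_child is not None:
            _, side, m, thr, mask = best_child
            sub_x = me[m].to_numpy(float)[mask]
            sub_y = y[mask]
            child = TreeSplit(m, thr, _leaf(sub_y[sub_x <= thr]), _leaf(sub_y[sub_x > thr]))
            if side == "left":
                tree.left = child
            else:
                tree.right = child
    return tree


# ---------------------------------------------------------------------------
# performance


def performance(
    calls: pd.Series,
    truth: pd.Series,
    level: str = "individual",
    family_id: pd.Series | None = None,
    conf: float = 0.95,
    sides: Sequence[str] = ("sensitivity", "specificity"),
) -> PerformanceReport:
    """Sensitivity/specificity with exact binomial CIs.

    At ``level="family"`` the affected units are families with at least
    one affected member (a family is positive iff any affected member is
    positive) and the control units are families with no affected member.
    A zero denominator for a requested side is an error.
    """
    calls = calls.astype(bool)
    truth = truth.astype(bool)
    if level == "family":
        if family_id is None:
            raise ValueError("family-level performance needs family ids")
        fam = pd.DataFrame({"call": calls, "truth": truth, "family": family_id})
        affected = fam[fam["truth"]].groupby("family")["call"].any()
        control = fam.groupby("family").filter(lambda g: not g["truth"].any())
        control_calls = control.groupby("family")["call"].any() if len(control) else pd.Series(dtype=bool)
        pos_units, neg_units = affected, control_calls
    else:
        pos_units, neg_units = calls[truth], calls[~truth]

    want_sens = "sensitivity" in sides
    want_spec = "specificity" in sides
    if want_sens and len(pos_units) == 0:
        raise ValueError("no affected units: sensitivity undefined")
    if want_spec and len(neg_units) == 0:
        raise ValueError("no control units: specificity undefined")
    k_sens, n_sens = int(pos_units.sum()), int(len(pos_units))
    report = PerformanceReport(level=level, k_sens=k_sens, n_sens=n_sens, conf=conf)
    if want_spec:
        report.k_spec = int((~neg_units).sum())
        report.n_spec = int(len(neg_units))
    return report


# ---------------------------------------------------------------------------
# combination search


def search_combinations(
    mes,
    status,
    candidate_modules: Sequence,
    max_k: int = 3,
    alpha: float = 0.05,
    conf: float = 0.95,
) -> pd.DataFrame:
    """Exhaustive OR-rule evaluation of module subsets of size 1..max_k.

    Each subset is scored on the training cohort (sensitivity,
    specificity, exact CIs) and ranked by specificity desc, sensitivity
    desc, subset size asc.
    """
    if not candidate_modules:
        raise ValueError("need at least one candidate module")
    me = _me_frame(mes)
    status = pd.Series(status, index=me.index) if not isinstance(status, pd.Series) else status
    profiles = fit_disease_profile(me, status, list(candidate_modules), alpha)
    train = status.isin(["case", "control"])
    truth = (status.loc[train] == "case")
    rows = []
    for k in range(1, max_k + 1):
        for subset in itertools.combinations(candidate_modules, k):
            calls = pd.Series(
                [
                    classify_combination(profiles, me.loc[s], subset, alpha)
                    for s in me.index[train]
                ],
                index=me.index[train],
            )
            rep = performance(calls, truth, "individual", conf=conf)
            slo, shi = rep.sensitivity_ci
            plo, phi = rep.specificity_ci
            rows.append(
                {
                    "modules": subset,
                    "size": k,
                    "sensitivity": rep.sensitivity,
                    "sens_ci_low": slo,
                    "sens_ci_high": shi,
                    "specificity": rep.specificity,
                    "spec_ci_low": plo,
                    "spec_ci_high": phi,
                }
            )
    table = pd.DataFrame(rows)
    return table.sort_values(
        ["specificity", "sensitivity", "size"], ascending=[False, False, True]
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# projection of out-of-cohort samples


def project_sample_me(eigengenes: EigengeneSet, new_expr: pd.DataFrame) -> pd.DataFrame:
    """Project new samples onto training eigengenes.

    New expression (genes × samples) is standardized with the training
    gene means/SDs and dotted with the stored gene loadings; more than 5%
    missing module genes is an error, smaller gaps are renormalized.
    """
    cols = new_expr.columns
    out = {}
    for m, load in eigengenes.loadings.items():
        genes = pd.Index(load["gene_ids"])
        present = genes.isin(new_expr.index)
        if present.mean() < 0.95:
            raise ValueError(
                f"module {m!r}: {(~present).sum()} of {len(genes)} genes missing (> 5%)"
            )
        idx = np.flatnonzero(present)
        sub = new_expr.loc[genes[present]].to_numpy(float)
        x = (sub - load["gene_mean"][idx][:, None]) / load["gene_sd"][idx][:, None]
        u = load["u1"][idx]
        raw = u @ x / (u @ u)
        out[m] = raw / (load["s1"] * load["me_scale"])
    return pd.DataFrame(out, index=cols)


# ---------------------------------------------------------------------------
# model / results objects


class EigengeneClassifier:
    """Module-eigengene classifier model.

    Parameters
    ----------
    mes : EigengeneSet or samples × modules DataFrame
    status : per-sample status (case / control / validation)
    disease_modules : modules available to the classifier (default: all)
    family_id : optional per-sample family ids for family-level rollups
    alpha : significance level of the per-module t-test calls
    """

    def __init__(self, mes, status, disease_modules=None, family_id=None, alpha=0.05):
        self.me = _me_frame(mes).copy()
        self.eigengenes = mes if isinstance(mes, EigengeneSet) else None
        self.status = (
            status.copy() if isinstance(status, pd.Series)
            else pd.Series(np.asarray(status), index=self.me.index)
        )
        self.family_id = family_id if family_id is None else pd.Series(family_id, index=self.me.index)
        self.disease_modules = (
            list(self.me.columns) if disease_modules is None else list(disease_modules)
        )
        self.alpha = float(alpha)

    def fit(self, rule: str = "single", modules=None, max_depth: int = 2) -> "ClassifierResults":
        """Fit the training profiles (and, for ``rule='tree'``, the tree)."""
        if rule not in ("single", "or_combination", "tree"):
            raise ValueError("rule must be single, or_combination, or tree")
        modules = list(self.disease_modules if modules is None else modules)
        profiles = fit_disease_profile(self.me, self.status, modules, self.alpha)
        tree = None
        if rule == "tree":
            if len(modules) != 2:
                raise ValueError("tree rule uses exactly 2 modules")
            tree = fit_decision_tree(self.me[modules], self.status, max_depth=max_depth)
        return ClassifierResults(self, rule, modules, profiles, tree)


@dataclass
class ClassifierResults:
    """Fitted eigengene classifier with classification and reporting."""

    model: EigengeneClassifier
    rule: str
    modules: list
    profiles: dict
    tree: TreeSplit | None = None

    def classify(self, me: pd.DataFrame | None = None, affected=None) -> ClassificationResult:
        """Call every sample; roll calls up to families over affected members."""
        me = self.model.me if me is None else _me_frame(me)
        table = pd.DataFrame(index=me.index)
        for m in self.modules:
            pc = [classify_sample_single(self.profiles[m], v, self.model.alpha) for v in me[m]]
            table[f"p_{m}"] = [p for p, _ in pc]
            table[f"call_{m}"] = [c for _, c in pc]
        if self.rule == "tree":
            table["call"] = [self.tree.predict(me.loc[s]) for s in me.index]
        elif self.rule == "or_combination" or len(self.modules) > 1:
            table["call"] = table[[f"call_{m}" for m in self.modules]].any(axis=1)
        else:
            table["call"] = table[f"call_{self.modules[0]}"]

        family_calls = pd.Series(dtype=bool)
        if self.model.family_id is not None:
            if affected is None:
                affected = self.model.status.reindex(me.index) != "control"
            aff_idx = me.index[affected.reindex(me.index).fillna(True).astype(bool)]
            fam = self.model.family_id.reindex(aff_idx)
            family_calls = table.loc[aff_idx, "call"].groupby(fam).any()
        return ClassificationResult(sample_table=table, family_calls=family_calls)

    def performance(self, level: str = "individual", conf: float = 0.95, **kw) -> PerformanceReport:
        """Training-cohort performance (case vs control samples only)."""
        train = self.model.status.isin(["case", "control"])
        calls = self.classify().calls[train]
        truth = self.model.status[train] == "case"
        fam = self.model.family_id[train] if self.model.family_id is not None else None
        return performance(calls, truth, level=level, family_id=fam, conf=conf, **kw)

    def summary(self) -> str:
        lines = [
            "EigengeneClassifier results",
            f"  rule: {self.rule}   modules: {list(self.modules)}   alpha: {self.model.alpha}",
        ]
        for m, pr in self.profiles.items():
            lines.append(
                f"  module {m}: control {pr.control_mean:+.3f} ± {pr.control_sd:.3f} "
                f"(n={pr.control_n}), patient mean {pr.patient_mean:+.3f}"
            )
        if self.tree is not None:
            for mod, thr in self.tree.nodes():
                lines.append(f"  tree split: ME[{mod}] <= {thr:.4f}")
        try:
            lines.append(self.performance().summary())
        except ValueError:
            pass
        return "\n".join(lines)
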