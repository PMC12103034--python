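"""Synthetic RNA-seq cohorts with known co-expression module structure.

The generator follows a latent single-factor model per module: each module
m has one eigengene value e_{m,s} per sample s, drawn standard normal,
with a configurable mean shift added for affected samples when m is a
disease module.  A member gene g with loading a_g contributes the log-scale
signal ``a_g * e_{m,s} + sqrt(1 - a_g^2) * noise`` so that the latent
gene–eigengene correlation is exactly a_g.  Grey (unassigned) genes are
pure noise.  On top of the signal, the expected count receives gene length,
a per-sample quadratic GC bias, sex/batch covariate offsets and a
log-normal library size; counts are negative binomial with mean mu and
variance ``mu + mu^2 * dispersion``.

Sex-marker genes (one XIST-like female-high gene and a small Y-like
male-high set) are appended so the sex QC check has something to look at.
Affected samples are partitioned into families so family-level performance
rollups can be exercised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset

N_Y_MARKERS = 4
FEMALE_MARKER = "XIST_LIKE"
MALE_MARKERS = tuple(f"Y_LIKE_{i}" for i in range(1, N_Y_MARKERS + 1))
MARKER_SHIFT = 4.0  # log2 offset of sex markers in the concordant sex


class ConfigurationError(ValueError):
    """A simulation configuration violates one of its invariants."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design and noise parameters of a synthetic cohort.

    Defaults mirror the blood training cohort the pipeline is designed
    around: 11 affected subjects from 7 families versus 35 controls, a few
    modules of 50+ genes, one of which carries the disease signal, and a
    negative-binomial count layer with realistic GC/length/depth biases.
    """

    module_sizes: Sequence[int] = (120, 100, 80)
    n_genes: int | None = None          # defaults to modules + grey from frac_grey
    frac_grey: float = 0.4
    disease_modules: Sequence[int] = (1,)   # 1-based module labels
    effect_delta: float = 2.0           # case shift of disease eigengenes, latent SD units
    loading_range: tuple[float, float] = (0.6, 0.9)
    n_cases: int = 11
    n_controls: int = 35
    n_families: int = 7
    family_sizes: Sequence[int] | None = None   # affected members per family
    nb_dispersion: float = 0.01
    gc_range: tuple[float, float] = (0.35, 0.65)
    length_range: tuple[float, float] = (300.0, 10_000.0)
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: {"sex": 0.2, "batch": 0.3}
    )
    gc_bias_sd: float = 0.5             # sd of per-sample quadratic GC coefficients (log2)
    signal_sd: float = 1.0              # log2 sd of the latent signal component
    base_log2_sd: float = 1.5           # spread of baseline gene abundances (log2)
    # expected fraction of the library carried jointly by module genes; grey
    # genes stand in for the large background transcriptome that dominates
    # sequencing depth in real data, so they carry the rest
    module_library_share: float = 0.10
    mean_library_size: float = 2e6
    library_size_sigma: float = 0.2     # log-normal sigma of depth variation
    n_batches: int = 2
    seed: int = 0

    # -- derived -------------------------------------------------------

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    @property
    def n_grey(self) -> int:
        return self.resolved_n_genes() - int(sum(self.module_sizes))

    def resolved_n_genes(self) -> int:
        if self.n_genes is not None:
            return int(self.n_genes)
        total = int(sum(self.module_sizes))
        return total + int(round(total * self.frac_grey / (1.0 - self.frac_grey)))

    def resolved_family_sizes(self) -> list[int]:
        if self.family_sizes is not None:
            return [int(x) for x in self.family_sizes]
        base, extra = divmod(self.n_cases, self.n_families)
        return [base + (1 if i < extra else 0) for i in range(self.n_families)]

    def validate(self) -> None:
        if not self.module_sizes or any(int(s) < 2 for s in self.module_sizes):
            raise ConfigurationError("module_sizes must be non-empty with sizes >= 2")
        n_genes = self.resolved_n_genes()
        if n_genes < sum(self.module_sizes):
            raise ConfigurationError(
                "n_genes smaller than the sum of module sizes (grey count negative)"
            )
        if not 0 <= self.frac_grey < 1:
            raise ConfigurationError("frac_grey must lie in [0, 1)")
        for m in self.disease_modules:
            if not 1 <= int(m) <= self.n_modules:
                raise ConfigurationError(f"disease module index {m} out of range 1..{self.n_modules}")
        if self.effect_delta < 0:
            raise ConfigurationError("effect_delta must be >= 0")
        lo, hi = self.loading_range
        if not (0 < lo <= hi <= 1):
            raise ConfigurationError("loading_range must satisfy 0 < lo <= hi <= 1")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be > 0")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ConfigurationError("need at least one case and one control")
        fams = self.resolved_family_sizes()
        if len(fams) != self.n_families or any(f < 0 for f in fams):
            raise ConfigurationError("family_sizes must list one non-negative count per family")
        if sum(fams) != self.n_cases:
            raise ConfigurationError(
                f"family sizes sum to {sum(fams)}, expected n_cases = {self.n_cases}"
            )
        glo, ghi = self.gc_range
        if not (0 <= glo <= ghi <= 1):
            raise ConfigurationError("gc_range must lie within [0, 1]")
        llo, lhi = self.length_range
        if not (0 < llo <= lhi):
            raise ConfigurationError("length_range must be positive")


@dataclass
class SimulationTruth:
    """Ground truth behind a generated dataset."""

    gene_modules: pd.Series        # gene id -> module label (0 = grey)
    loadings: pd.Series            # gene id -> latent loading (0 for grey/markers)
    eigengenes: pd.DataFrame       # samples x module labels (1..K), latent values
    disease_modules: tuple[int, ...]
    families: pd.Series            # case sample id -> family id
    config: SimulationConfig

    def module_genes(self, label: int) -> list[str]:
        return list(self.gene_modules.index[self.gene_modules == label])


# ---------------------------------------------------------------------------


def _gene_table(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Gene ids, module labels, loadings, lengths and GC for the core genes."""
    n_genes = config.resolved_n_genes()
    labels = np.zeros(n_genes, dtype=int)
    pos = 0
    for k, size in enumerate(config.module_sizes, start=1):
        labels[pos:pos + int(size)] = k
        pos += int(size)
    gene_ids = [f"G{i + 1:05d}" for i in range(n_genes)]
    lo, hi = config.loading_range
    loadings = rng.uniform(lo, hi, size=n_genes)
    loadings[labels == 0] = 0.0
    llo, lhi = config.length_range
    lengths = np.exp(rng.uniform(np.log(llo), np.log(lhi), size=n_genes))
    glo, ghi = config.gc_range
    gc = rng.uniform(glo, ghi, size=n_genes)
    return pd.DataFrame(
        {
            "module": labels,
            "loading": loadings,
            "length_bp": np.round(lengths).astype(int),
            "gc_frac": gc,
            "chrom": [f"chr{1 + i % 22}" for i in range(n_genes)],
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )


def _sample_table(
    config: SimulationConfig,
    rng: np.random.Generator,
    prefix: str = "",
) -> pd.DataFrame:
    n = config.n_cases + config.n_controls
    ids = [f"{prefix}CASE{i + 1:03d}" for i in range(config.n_cases)] + [
        f"{prefix}CTRL{i + 1:03d}" for i in range(config.n_controls)
    ]
    status = ["case"] * config.n_cases + ["control"] * config.n_controls
    fam_sizes = config.resolved_family_sizes()
    fam_ids: list[str] = []
    for f, size in enumerate(fam_sizes, start=1):
        fam_ids.extend([f"{prefix}FAM{f:02d}"] * size)
    # controls are assigned to the case families cyclically (unaffected relatives)
    for i in range(config.n_controls):
        fam_ids.append(f"{prefix}FAM{1 + i % config.n_families:02d}")
    sex = np.where(rng.random(n) < 0.5, "F", "M").tolist()
    if "F" not in sex:
        sex[0] = "F"
    if "M" not in sex:
        sex[-1] = "M"
    batch = [f"B{1 + i % config.n_batches}" for i in range(n)]
    return pd.DataFrame(
        {"family_id": fam_ids, "status": status, "sex": sex, "batch": batch},
        index=pd.Index(ids, name="sample_id"),
    )


def _latent_eigengenes(
    config: SimulationConfig,
    samples: pd.DataFrame,
    rng: np.random.Generator,
    disease_active: Sequence[int],
) -> pd.DataFrame:
    n = len(samples)
    e = rng.standard_normal((n, config.n_modules))
    case = (samples["status"] == "case").to_numpy()
    for m in disease_active:
        e[case, m - 1] += config.effect_delta
    return pd.DataFrame(
        e, index=samples.index, columns=pd.RangeIndex(1, config.n_modules + 1)
    )


def _signal_matrix(
    genes: pd.DataFrame,
    eig: pd.DataFrame,
    rng: np.random.Generator,
    signal_sd: float,
) -> np.ndarray:
    """Latent log2-scale signal, genes x samples, unit variance per gene."""
    n_genes, n_samples = len(genes), len(eig)
    z = rng.standard_normal((n_genes, n_samples))
    labels = genes["module"].to_numpy()
    loadings = genes["loading"].to_numpy()
    for k in np.unique(labels):
        if k == 0:
            continue
        rows = labels == k
        a = loadings[rows][:, None]
        z[rows] = a * eig[k].to_numpy()[None, :] + np.sqrt(1.0 - a**2) * z[rows]
    return signal_sd * z


def _counts_from_signal(
    genes: pd.DataFrame,
    samples: pd.DataFrame,
    signal: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    n_genes, n_samples = signal.shape
    base = rng.normal(0.0, config.base_log2_sd, size=n_genes)
    base = base + np.log2(genes["length_bp"].to_numpy() / 1000.0)
    libsize = config.mean_library_size * np.exp(
        rng.normal(0.0, config.library_size_sigma, size=n_samples)
    )
    depth = np.log2(libsize / config.mean_library_size)

    # per-sample quadratic GC bias (what the CQN-style correction removes)
    glo, ghi = config.gc_range
    mid, half = (glo + ghi) / 2.0, max((ghi - glo) / 2.0, 1e-9)
    u = (genes["gc_frac"].to_numpy() - mid) / half
    c1 = rng.normal(0.0, config.gc_bias_sd, size=n_samples)
    c2 = rng.normal(0.0, config.gc_bias_sd, size=n_samples)
    gc_eff = np.outer(u, c1) + np.outer(u**2 - 1.0 / 3.0, c2)

    # gene-specific covariate offsets
    sex_sd = float(config.covariate_effects.get("sex", 0.0))
    batch_sd = float(config.covariate_effects.get("batch", 0.0))
    female = (samples["sex"] == "F").to_numpy(float)
    cov = np.outer(rng.normal(0.0, sex_sd, size=n_genes), female)
    for b in sorted(samples["batch"].unique())[1:]:
        in_batch = (samples["batch"] == b).to_numpy(float)
        cov += np.outer(rng.normal(0.0, batch_sd, size=n_genes), in_batch)

    # sex-marker contrasts
    male = 1.0 - female
    is_f_marker = (genes.index == FEMALE_MARKER).astype(float)
    is_m_marker = genes.index.isin(MALE_MARKERS).astype(float)
    cov += MARKER_SHIFT * (np.outer(is_f_marker, female) + np.outer(is_m_marker, male))

    # relative abundances normalized per sample so expected totals match the
    # drawn library sizes; module genes jointly carry module_library_share of
    # the depth, grey genes (the background transcriptome) the rest
    log2_rel = base[:, None] + gc_eff + cov + signal
    rel = np.exp2(np.clip(log2_rel, -20, 30))
    in_module = (genes["module"].to_numpy() != 0)
    share = float(config.module_library_share)
    if in_module.any() and (~in_module).any() and 0 < share < 1:
        # scale by cohort-average sums (constants) so per-sample composition
        # fluctuations survive but are damped by the grey-dominated total
        mod_sum = rel[in_module].sum(axis=0).mean()
        grey_sum = rel[~in_module].sum(axis=0).mean()
        rel[in_module] *= share / mod_sum
        rel[~in_module] *= (1.0 - share) / grey_sum
    mu = rel / rel.sum(axis=0, keepdims=True) * (
        config.mean_library_size * np.exp2(depth)
    )[None, :]
    size = 1.0 / config.nb_dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p).astype(np.int64)


def _append_markers(genes: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    marker_ids = [FEMALE_MARKER, *MALE_MARKERS]
    markers = pd.DataFrame(
        {
            "module": 0,
            "loading": 0.0,
            "length_bp": rng.integers(800, 4000, size=len(marker_ids)),
            "gc_frac": rng.uniform(0.4, 0.6, size=len(marker_ids)),
            "chrom": ["chrX"] + ["chrY"] * N_Y_MARKERS,
        },
        index=pd.Index(marker_ids, name="gene_id"),
    )
    return pd.concat([genes, markers])


def generate_dataset(config: SimulationConfig) -> tuple[ExpressionDataset, SimulationTruth]:
    """Draw a case/control count cohort with known module structure.

    Returns the raw-count :class:`ExpressionDataset` and the
    :class:`SimulationTruth` (gene→module map, loadings, latent eigengenes,
    disease flags, family assignment).  The same configuration, including
    its seed, always yields bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _gene_table(config, rng)
    genes = _append_markers(genes, rng)
    samples = _sample_table(config, rng)
    eig = _latent_eigengenes(config, samples, rng, config.disease_modules)
    signal = _signal_matrix(genes, eig, rng, config.signal_sd)
    counts = _counts_from_signal(genes, samples, signal, config, rng)

    values = pd.DataFrame(counts, index=genes.index, columns=samples.index)
    ds = ExpressionDataset(
        values=values,
        genes=genes[["length_bp", "gc_frac", "chrom"]],
        samples=samples,
        stage="raw",
    )
    case_ids = samples.index[samples["status"] == "case"]
    truth = SimulationTruth(
        gene_modules=genes["module"].copy(),
        loadings=genes["loading"].copy(),
        eigengenes=eig,
        disease_modules=tuple(int(m) for m in config.disease_modules),
        families=samples.loc[case_ids, "family_id"].copy(),
        config=config,
    )
    return ds, truth


def generate_companion_dataset(
    truth: SimulationTruth,
    preserve: set[int] | Sequence[int],
    config: SimulationConfig | None = None,
) -> ExpressionDataset:
    """New-sample dataset in which only ``preserve`` modules keep their structure.

    Preserved modules reuse the original gene→module map and loadings with
    freshly drawn eigengenes; every other module's genes become independent
    noise (their co-expression is destroyed), which is exactly the
    situation module-preservation statistics are meant to detect.
    """
    config = truth.config if config is None else config
    config.validate()
    preserve = {int(m) for m in preserve}
    unknown = preserve - set(range(1, config.n_modules + 1))
    if unknown:
        raise ConfigurationError(f"unknown module indices in preserve: {sorted(unknown)}")

    rng = np.random.default_rng([config.seed, 7919])
    genes = truth.gene_modules.copy().to_frame("module")
    genes["loading"] = truth.loadings.copy()
    # scrambled modules lose both membership and loading
    scrambled = ~genes["module"].isin([0, *preserve])
    genes.loc[scrambled, "module"] = 0
    genes.loc[scrambled, "loading"] = 0.0

    base = _gene_table(config, np.random.default_rng(config.seed))
    base = _append_markers(base, np.random.default_rng(config.seed))
    genes["length_bp"] = base["length_bp"]
    genes["gc_frac"] = base["gc_frac"]
    genes["chrom"] = base["chrom"]

    samples = _sample_table(config, rng, prefix="V")
    disease_active = [m for m in config.disease_modules if m in preserve]
    eig = _latent_eigengenes(config, samples, rng, disease_active)
    signal = _signal_matrix(genes, eig, rng, config.signal_sd)
    counts = _counts_from_signal(genes, samples, signal, config, rng)
    values = pd.DataFrame(counts, index=genes.index, columns=samples.index)
    return ExpressionDataset(
        values=values,
        genes=genes[["length_bp", "gc_frac", "chrom"]],
        samples=samples,
        stage="raw",
    )
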