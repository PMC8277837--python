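"""Two-condition RNA-seq count simulator with planted structure.

The generator emulates the design of a small case/control bulk RNA-seq study
(two groups of N samples each) and plants three kinds of signal with a known
answer sheet:

* differential expression — a fraction of genes get a log2 fold change of
  ``±lfc_magnitude`` in the case condition;
* co-expression modules — each module is a transcription-factor (TF)
  regulator plus ``module_size`` target genes sharing a latent Gaussian
  factor, giving within-module correlation ``rho_within``;
* rewiring — in a chosen fraction of modules the regulator's coupling to the
  shared factor is removed (or sign-flipped) in case samples only, so the
  TF–target correlations present in controls are destroyed in cases.

Counts are produced by a latent Gaussian copula: the structured latent value
of gene g in sample s is mapped through the standard normal CDF and then
through the inverse CDF of a negative-binomial marginal whose mean carries
the baseline abundance, the planted fold change and a log-normal library-size
factor. This preserves the target rank correlations under a realistic count
likelihood (overdispersion: var = mu + dispersion * mu^2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ConfigurationError, CountMatrix, SimTruth

logger = logging.getLogger(__name__)

# scale (in log2 units) of baseline abundance spread across genes
_BASELINE_LOG_SD = 1.0
_BASELINE_MEAN = 200.0  # counts at a 1e6 library
_LIBSIZE_SIGMA = 0.2  # log-normal spread of library-size factors


@dataclass
class SimConfig:
    """Parameters of the synthetic study; defaults mirror a 5 vs 5 design."""

    n_genes: int = 1000
    n_tfs: int = 50
    n_per_group: int = 5
    n_modules: int = 10
    module_size: int = 10
    rho_within: float = 0.9
    rewired_fraction: float = 0.3
    de_fraction: float = 0.1
    lfc_magnitude: float = 2.0
    nb_dispersion: float = 0.2
    lib_size_mean: float = 1e6
    seed: int = 0
    sign_flip: bool = False  # rewire by inverting, not destroying, the coupling
    de_from_rewired: bool = True  # plant DE preferentially on rewired targets

    def validate(self) -> None:
        for name in ("n_genes", "n_tfs", "n_per_group", "module_size"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise ConfigurationError(f"{name} must be a positive integer, got {v!r}")
        if not isinstance(self.n_modules, (int, np.integer)) or self.n_modules < 0:
            raise ConfigurationError(f"n_modules must be a non-negative integer, got {self.n_modules!r}")
        if self.n_modules * self.module_size > self.n_genes:
            raise ConfigurationError("n_modules * module_size exceeds n_genes")
        if self.n_tfs < self.n_modules:
            raise ConfigurationError("need at least one TF per module (n_tfs >= n_modules)")
        if self.n_tfs + self.n_modules * self.module_size > self.n_genes:
            raise ConfigurationError("TF block plus module targets exceed n_genes")
        if not 0 < self.rho_within < 1:
            raise ConfigurationError("rho_within must lie in (0, 1)")
        for name in ("rewired_fraction", "de_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v!r}")
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be >= 0")
        if self.lib_size_mean <= 0:
            raise ConfigurationError("lib_size_mean must be positive")


def gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def _nb_quantile(u: np.ndarray, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Inverse CDF of NB(mean=mu, var=mu+dispersion*mu^2); Poisson at dispersion 0."""
    if dispersion == 0:
        return stats.poisson.ppf(u, mu)
    size = 1.0 / dispersion
    p = size / (size + mu)
    return stats.nbinom.ppf(u, size, p)


def simulate_counts(config: SimConfig) -> tuple[CountMatrix, SimTruth]:
    """Draw a seeded count matrix and its ground-truth answer sheet.

    Samples are laid out control first, then case. Deterministic given
    ``config.seed`` (byte-identical matrices on re-run).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_genes, n = config.n_genes, 2 * config.n_per_group
    genes = gene_ids(n_genes)
    conditions = np.array(["control"] * config.n_per_group + ["case"] * config.n_per_group)
    is_case = conditions == "case"

    # module layout: regulators are the first n_modules TFs; targets follow the TF block
    truth = SimTruth()
    tf_ids = genes[: config.n_tfs]
    target_start = config.n_tfs
    module_targets: dict[int, np.ndarray] = {}
    for m in range(config.n_modules):
        reg = genes[m]
        lo = target_start + m * config.module_size
        tgt_idx = np.arange(lo, lo + config.module_size)
        module_targets[m] = tgt_idx
        truth.regulator_of[m] = reg
        truth.module_map[reg] = m
        for i in tgt_idx:
            truth.module_map[genes[i]] = m

    n_rewired = int(round(config.rewired_fraction * config.n_modules))
    rewired = sorted(rng.choice(config.n_modules, size=n_rewired, replace=False)) if n_rewired else []
    truth.rewired_modules = set(int(m) for m in rewired)

    # planted differential expression; targets of one rewired module shift
    # coherently (a lost regulator moves all its targets the same way)
    n_de = int(round(config.de_fraction * n_genes))
    de_order: list[int] = []
    module_of_idx: dict[int, int] = {}
    if config.de_from_rewired:
        for m in rewired:
            for i in module_targets[m]:
                de_order.append(int(i))
                module_of_idx[int(i)] = m
    rest = np.setdiff1d(np.arange(n_genes), np.array(de_order, dtype=int), assume_unique=False)
    de_order.extend(int(i) for i in rng.permutation(rest))
    de_idx = np.array(de_order[:n_de], dtype=int)
    lfc = np.zeros(n_genes)
    if n_de:
        module_sign = {m: float(rng.choice([-1.0, 1.0])) for m in rewired}
        signs = rng.choice([-1.0, 1.0], size=n_de)
        for pos, i in enumerate(de_idx):
            if int(i) in module_of_idx:
                signs[pos] = module_sign[module_of_idx[int(i)]]
        lfc[de_idx] = signs * config.lfc_magnitude
        for i, s in zip(de_idx, signs):
            truth.de_genes[genes[i]] = int(s)

    # latent Gaussian layer
    z = rng.standard_normal((n_genes, n))
    factors = rng.standard_normal((config.n_modules, n))
    rew_noise = rng.standard_normal((config.n_modules, n))
    sq, sq1 = np.sqrt(config.rho_within), np.sqrt(1.0 - config.rho_within)
    for m in range(config.n_modules):
        z[module_targets[m]] = sq * factors[m] + sq1 * z[module_targets[m]]
        reg_row = factors[m].copy()
        if m in truth.rewired_modules:
            if config.sign_flip:
                reg_row[is_case] = -factors[m][is_case]
            else:
                reg_row[is_case] = rew_noise[m][is_case]
        z[genes.index(truth.regulator_of[m])] = reg_row

    # negative-binomial marginals through the copula
    baseline = _BASELINE_MEAN * np.exp(_BASELINE_LOG_SD * rng.standard_normal(n_genes))
    baseline = np.maximum(baseline, 5.0)
    rel = baseline / baseline.sum()
    lib = np.exp(rng.normal(0.0, _LIBSIZE_SIGMA, size=n))
    mu = rel[:, None] * config.lib_size_mean * lib[None, :]
    mu = mu * np.power(2.0, lfc[:, None] * is_case[None, :])
    u = np.clip(stats.norm.cdf(z), 1e-12, 1.0 - 1e-12)
    counts = _nb_quantile(u, mu, config.nb_dispersion).astype(np.int64)

    sample_ids = [f"{c}_{i + 1}" for c in ("control", "case") for i in range(config.n_per_group)]
    counts_df = pd.DataFrame(counts, index=genes, columns=sample_ids)
    counts_df.index.name = "gene_id"
    samples = pd.DataFrame(
        {
            "condition": conditions,
            "age": rng.integers(30, 70, size=n),
            "sex": rng.choice(["M", "F"], size=n),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    logger.info(
        "simulated %d genes x %d samples (%d DE, %d modules, %d rewired)",
        n_genes, n, n_de, config.n_modules, len(truth.rewired_modules),
    )
    return CountMatrix(counts=counts_df, samples=samples), truth


def tf_list(config: SimConfig) -> list[str]:
    """Gene ids flagged as transcription factors under this configuration."""
    return gene_ids(config.n_genes)[: config.n_tfs]


def write_outputs(cm: CountMatrix, truth: SimTruth, config: SimConfig, outdir: str) -> dict[str, str]:
    """Write counts, sample sheet, TF list and truth tables as plain text."""
    import os

    from . import io

    io.ensure_dir(outdir)
    paths = {
        "counts": os.path.join(outdir, "counts.tsv"),
        "samples": os.path.join(outdir, "samples.tsv"),
        "tfs": os.path.join(outdir, "tfs.txt"),
        "truth_de": os.path.join(outdir, "truth_de.tsv"),
        "truth_modules": os.path.join(outdir, "truth_modules.tsv"),
    }
    io.write_matrix(cm.counts, paths["counts"])
    cm.samples.to_csv(paths["samples"], sep="\t", index_label="sample_id")
    io.write_gene_list(tf_list(config), paths["tfs"])
    pd.DataFrame(
        {"gene_id": list(truth.de_genes), "sign": [truth.de_genes[g] for g in truth.de_genes]}
    ).to_csv(paths["truth_de"], sep="\t", index=False)
    rows = [
        {
            "gene_id": g,
            "module": m,
            "is_regulator": int(truth.regulator_of[m] == g),
            "rewired": int(m in truth.rewired_modules),
        }
        for g, m in truth.module_map.items()
    ]
    pd.DataFrame(rows, columns=["gene_id", "module", "is_regulator", "rewired"]).to_csv(
        paths["truth_modules"], sep="\t", index=False
    )
    return paths
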