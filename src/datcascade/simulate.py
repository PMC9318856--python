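"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the data the analysis consumes, not the assay that
produced it: gene-level negative-binomial count matrices for two
sensitive/resistant cell-line pairs, a proportional-hazards survival
cohort, qPCR Ct plates consistent with the planted fold changes, colony
counts for the siRNA screen, and a three-arm knockdown experiment
(untreated / control-siRNA / target-siRNA) with shared off-target genes
and a two-batch structure.

Planted effects are organised as a truth table: every gene carries its
class (concordant up/down across pairs, discordant, single-pair, null),
its true log2 fold change per pair, an NB baseline mean and dispersion, a
survival hazard ratio (high- vs low-expression group) and a screen colony
reduction.  Concordant genes are laid out on a 4 x 4 grid of baseline-mean
and |log2FC| strata so the quartile-rank filter downstream has
discriminating work to do.  One concordant-up gene in the top stratum of
both axes is designated the "driver": it additionally carries a hazard
ratio of 1.78 and a 54% colony reduction, the profile the full pipeline
should single out.

Everything is a pure function of the configured seed: the same
configuration reproduces byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .experiment import CountExperiment

__all__ = [
    "SimConfig",
    "make_truth",
    "make_knockdown_truth",
    "generate_pair_experiment",
    "generate_survival_cohort",
    "generate_qpcr_plate",
    "generate_screen_table",
    "generate_knockdown_experiment",
    "DRIVER_GENE",
]

#: gene id reserved for the planted pipeline-positive candidate
DRIVER_GENE = "G000001"

# stratum levels for planted concordant genes (baseline mean, |log2FC|)
_BM_LEVELS = (30.0, 120.0, 500.0, 2000.0)
_FC_LEVELS = (1.3, 1.9, 2.7, 3.6)

_DRIVER_HR = 1.78
_DRIVER_REDUCTION = 0.54


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Study-scale defaults: two cell-line pairs with 3 replicates per
    condition, a 200-patient cohort with 20% censoring, triplicate qPCR
    wells with 0.2-cycle noise, triplicate screen wells around 200
    colonies."""

    n_genes: int = 2000
    n_reps_per_condition: int = 3
    class_counts: dict[str, int] = field(
        default_factory=lambda: {
            "concordant_up": 160,
            "concordant_down": 160,
            "discordant": 40,
            "pair1_only": 40,
            "pair2_only": 40,
        }
    )
    n_patients: int = 200
    censoring_fraction: float = 0.2
    ct_noise_sd: float = 0.2
    seed: int = 0
    dispersion: float = 0.05
    baseline_colonies: int = 200
    n_screen_replicates: int = 3
    n_qpcr_replicates: int = 3
    depth_factor_range: tuple[float, float] = (0.5, 2.0)
    batch_factors: tuple[float, float] = (1.0, 1.15)
    # knockdown experiment
    n_offtarget: int = 40
    n_specific: int = 200
    kd_effect_lfc: float = 2.0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_reps_per_condition <= 0:
            raise ConfigError("n_genes and n_reps_per_condition must be positive")
        if any(v < 0 for v in self.class_counts.values()):
            raise ConfigError("planted class counts must be non-negative")
        if sum(self.class_counts.values()) > self.n_genes:
            raise ConfigError("planted class counts exceed n_genes")
        if not 0.0 <= self.censoring_fraction <= 1.0:
            raise ConfigError("censoring_fraction must lie in [0, 1]")
        if self.ct_noise_sd < 0:
            raise ConfigError("ct_noise_sd must be non-negative")
        if self.baseline_colonies <= 0:
            raise ConfigError("baseline colony count must be positive")
        if self.n_offtarget + self.n_specific > self.n_genes:
            raise ConfigError("knockdown planted counts exceed n_genes")


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # independent substream per generator so adding one stage never
    # perturbs the draws of another
    return np.random.default_rng([config.seed, stream])


def _gene_ids(n: int) -> list[str]:
    return [f"G{i + 1:06d}" for i in range(n)]


def make_truth(config: SimConfig) -> pd.DataFrame:
    """Planted ground truth for the sensitive/resistant pair experiment.

    Concordant genes cycle through all 16 (baseline stratum, |log2FC|
    stratum) combinations with mild multiplicative jitter; discordant and
    single-pair genes get mid-grid effects; null genes draw a log-normal
    baseline and have every effect at its neutral value.
    """
    config.validate()
    rng = _rng(config, 0)
    n = config.n_genes
    ids = _gene_ids(n)
    classes = []
    for cls in ("concordant_up", "concordant_down", "discordant",
                "pair1_only", "pair2_only"):
        classes += [cls] * config.class_counts.get(cls, 0)
    classes += ["null"] * (n - len(classes))

    truth = pd.DataFrame({"gene_id": ids, "class": classes})
    truth["baseline_mean"] = np.exp(rng.normal(np.log(150.0), 1.0, n))
    truth["dispersion"] = config.dispersion
    truth["true_log2fc_pair1"] = 0.0
    truth["true_log2fc_pair2"] = 0.0
    truth["survival_hr"] = 1.0
    truth["screen_reduction"] = 0.0
    truth["bm_stratum"] = 0
    truth["fc_stratum"] = 0

    stratum = 0
    for i, cls in enumerate(classes):
        if cls == "null":
            continue
        bm_q, fc_q = divmod(stratum, 4)
        stratum = (stratum + 1) % 16
        bm = _BM_LEVELS[bm_q] * np.exp(rng.normal(0.0, 0.08))
        fc = _FC_LEVELS[fc_q] * (1.0 + rng.normal(0.0, 0.03))
        # bm is the target *cross-condition* mean (the quantity the rank
        # filter sees); back out the sensitive-condition baseline so that
        # (baseline + baseline * 2^lfc) / 2 == bm
        signed = -fc if cls == "concordant_down" else fc
        truth.loc[i, "baseline_mean"] = 2.0 * bm / (1.0 + 2.0**signed)
        truth.loc[i, "bm_stratum"] = bm_q + 1
        truth.loc[i, "fc_stratum"] = fc_q + 1
        if cls == "concordant_up":
            truth.loc[i, ["true_log2fc_pair1", "true_log2fc_pair2"]] = fc, fc
        elif cls == "concordant_down":
            truth.loc[i, ["true_log2fc_pair1", "true_log2fc_pair2"]] = -fc, -fc
        elif cls == "discordant":
            truth.loc[i, ["true_log2fc_pair1", "true_log2fc_pair2"]] = fc, -fc
        elif cls == "pair1_only":
            truth.loc[i, "true_log2fc_pair1"] = fc
        elif cls == "pair2_only":
            truth.loc[i, "true_log2fc_pair2"] = fc
        # modest colony reductions for planted up-genes, below hit level
        if cls == "concordant_up":
            truth.loc[i, "screen_reduction"] = float(rng.uniform(0.05, 0.40))

    # the driver: concordant up, top stratum on both axes, prognostic and
    # a strong screen hit
    if config.class_counts.get("concordant_up", 0) > 0:
        up_idx = [i for i, c in enumerate(classes) if c == "concordant_up"]
        top = [
            i for i in up_idx
            if truth.loc[i, "bm_stratum"] == 4 and truth.loc[i, "fc_stratum"] == 4
        ]
        driver = top[0] if top else up_idx[0]
        driver_id = truth.loc[driver, "gene_id"]
        truth.loc[driver, "survival_hr"] = _DRIVER_HR
        truth.loc[driver, "screen_reduction"] = _DRIVER_REDUCTION
        # keep the reserved id on the driver row for easy reference
        truth.loc[truth["gene_id"] == DRIVER_GENE, "gene_id"] = driver_id
        truth.loc[driver, "gene_id"] = DRIVER_GENE
    return truth


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, alpha: np.ndarray
) -> np.ndarray:
    """NB(mu, var = mu + alpha mu^2) via gamma-Poisson; alpha = 0 is Poisson."""
    mean = np.asarray(mean, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    over = alpha > 0
    if over.any():
        shape = 1.0 / alpha[over]
        lam = rng.gamma(shape, alpha[over] * mean[over])
        out[over] = rng.poisson(lam)
    if (~over).any():
        out[~over] = rng.poisson(mean[~over])
    return out


def generate_pair_experiment(config: SimConfig, truth: pd.DataFrame) -> CountExperiment:
    """Counts for two sensitive/resistant cell-line pairs.

    Gene g in pair k: sensitive mean = baseline, resistant mean =
    baseline * 2^true_log2fc_pairk, both scaled by a per-sample depth
    factor drawn log-uniform within ``depth_factor_range``.
    """
    config.validate()
    rng = _rng(config, 1)
    baseline = truth["baseline_mean"].to_numpy(dtype=float)
    alpha = truth["dispersion"].to_numpy(dtype=float)
    lo, hi = config.depth_factor_range
    columns = {}
    rows = []
    for pair in ("pair1", "pair2"):
        lfc = truth[f"true_log2fc_{pair}"].to_numpy(dtype=float)
        for condition in ("sensitive", "resistant"):
            mu_gene = baseline * np.where(condition == "resistant", 2.0**lfc, 1.0)
            for rep in range(1, config.n_reps_per_condition + 1):
                depth = np.exp(rng.uniform(np.log(lo), np.log(hi)))
                sample_id = f"{pair}_{condition}_{rep}"
                columns[sample_id] = _nb_draw(rng, mu_gene * depth, alpha)
                rows.append(
                    {"sample_id": sample_id, "pair": pair, "condition": condition,
                     "replicate": rep, "batch": "b1"}
                )
    counts = pd.DataFrame(columns, index=pd.Index(truth["gene_id"], name="gene_id"))
    samples = pd.DataFrame(rows).set_index("sample_id")
    return CountExperiment(counts, samples)


def split_pair(experiment: CountExperiment, pair: str) -> CountExperiment:
    """One cell-line pair's sensitive/resistant samples."""
    return experiment.subset_samples(experiment.samples["pair"] == pair)


def generate_survival_cohort(truth: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Per-patient gene expression with OS and PFS endpoints.

    Expression is standard normal per gene.  Event times are exponential;
    a patient's hazard is the baseline rate times the product, over genes
    with a non-unit hazard ratio, of HR^(expression above that gene's
    median).  The configured fraction of patients is censored uniformly
    before their event time.  OS and PFS use the same mechanism with
    separate draws (PFS with twice the baseline rate).
    """
    config.validate()
    if config.n_patients < 20:
        raise ConfigError("survival cohort needs at least 20 patients")
    rng = _rng(config, 2)
    n = config.n_patients
    genes = truth["gene_id"].tolist()
    expr = rng.normal(0.0, 1.0, size=(n, len(genes)))
    hrs = truth["survival_hr"].to_numpy(dtype=float)
    log_hazard_shift = np.zeros(n)
    for j in np.nonzero(hrs != 1.0)[0]:
        above = expr[:, j] > np.median(expr[:, j])
        log_hazard_shift += above * np.log(hrs[j])

    data = {"patient_id": [f"P{i + 1:05d}" for i in range(n)]}
    for j, gene in enumerate(genes):
        data[gene] = expr[:, j]
    out = pd.DataFrame(data)

    for endpoint, base_rate in (("os", 1.0 / 24.0), ("pfs", 1.0 / 12.0)):
        hazard = base_rate * np.exp(log_hazard_shift)
        t_event = rng.exponential(1.0 / hazard)
        events = np.ones(n, dtype=int)
        k = int(round(config.censoring_fraction * n))
        censored = rng.choice(n, size=k, replace=False)
        t = t_event.copy()
        t[censored] = t_event[censored] * rng.uniform(0.0, 1.0, size=k)
        events[censored] = 0
        out[f"{endpoint}_time"] = np.maximum(t, 1e-6)
        out[f"{endpoint}_event"] = events
    return out


def generate_qpcr_plate(
    truth: pd.DataFrame,
    config: SimConfig,
    genes: list[str] | None = None,
    pair: str = "pair1",
) -> pd.DataFrame:
    """Ct wells whose expected 2^-ddCt equals 2^true_log2fc.

    The reference gene sits at 20 cycles in both conditions; the target
    sits at 25 cycles in the sensitive condition and 25 - log2FC in the
    resistant one.  Additive Gaussian noise per well on the cycle scale.
    """
    config.validate()
    rng = _rng(config, 3)
    t = truth.set_index("gene_id")
    if genes is None:
        genes = list(t.index)
    sd = config.ct_noise_sd
    rows = []
    for gene in genes:
        lfc = float(t.loc[gene, f"true_log2fc_{pair}"])
        for condition, target_base in (("sensitive", 25.0), ("resistant", 25.0 - lfc)):
            for rep in range(1, config.n_qpcr_replicates + 1):
                rows.append(
                    {
                        "gene_id": gene,
                        "condition": condition,
                        "replicate": rep,
                        "ct_target": target_base + rng.normal(0.0, sd),
                        "ct_reference": 20.0 + rng.normal(0.0, sd),
                    }
                )
    return pd.DataFrame(rows)


def generate_screen_table(
    truth: pd.DataFrame,
    config: SimConfig,
    genes: list[str] | None = None,
    exact: bool = False,
) -> pd.DataFrame:
    """Colony counts: NC wells Poisson around the configured baseline,
    gene-siRNA wells Poisson around baseline * (1 - screen_reduction).
    ``exact=True`` replaces the Poisson draws with their rounded means
    (noise-free mode)."""
    config.validate()
    rng = _rng(config, 4)
    t = truth.set_index("gene_id")
    if genes is None:
        genes = list(t.index)
    base = float(config.baseline_colonies)
    rows = []
    for gene in genes:
        reduction = float(t.loc[gene, "screen_reduction"])
        mu_sirna = base * (1.0 - reduction)
        for rep in range(1, config.n_screen_replicates + 1):
            if exact:
                nc, si = int(round(base)), int(round(mu_sirna))
            else:
                nc, si = int(rng.poisson(base)), int(rng.poisson(mu_sirna))
            rows.append(
                {"gene_id": gene, "replicate": rep,
                 "colonies_sirna": si, "colonies_nc": nc}
            )
    return pd.DataFrame(rows)


def make_knockdown_truth(config: SimConfig) -> pd.DataFrame:
    """Ground truth for the three-arm knockdown experiment.

    ``n_offtarget`` genes respond to any siRNA transfection (perturbed in
    both the control-siRNA and target-siRNA arms); ``n_specific`` genes
    respond only to the target siRNA.  Signs alternate so both directions
    are represented.
    """
    config.validate()
    rng = _rng(config, 5)
    n = config.n_genes
    ids = _gene_ids(n)
    classes = (
        ["offtarget"] * config.n_offtarget
        + ["specific"] * config.n_specific
        + ["null"] * (n - config.n_offtarget - config.n_specific)
    )
    signs = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
    lfc = np.where(
        np.isin(classes, ["offtarget", "specific"]),
        signs * config.kd_effect_lfc,
        0.0,
    )
    return pd.DataFrame(
        {
            "gene_id": ids,
            "kd_class": classes,
            "kd_log2fc": lfc,
            "baseline_mean": np.exp(rng.normal(np.log(200.0), 0.8, n)),
            "dispersion": config.dispersion,
        }
    )


def generate_knockdown_experiment(
    truth: pd.DataFrame, config: SimConfig
) -> CountExperiment:
    """Counts for untreated / control-siRNA / target-siRNA arms across two
    batches.

    The batch multiplies every gene's mean by a shared factor; off-target
    genes shift in both siRNA arms, specific genes only in the target arm.
    """
    config.validate()
    rng = _rng(config, 6)
    baseline = truth["baseline_mean"].to_numpy(dtype=float)
    alpha = truth["dispersion"].to_numpy(dtype=float)
    lfc = truth["kd_log2fc"].to_numpy(dtype=float)
    offtarget = (truth["kd_class"] == "offtarget").to_numpy()
    specific = (truth["kd_class"] == "specific").to_numpy()
    lo, hi = config.depth_factor_range
    columns = {}
    rows = []
    for condition in ("untreated", "nc_sirna", "target_sirna"):
        shift = np.zeros(len(truth))
        if condition in ("nc_sirna", "target_sirna"):
            shift = np.where(offtarget, lfc, shift)
        if condition == "target_sirna":
            shift = np.where(specific, lfc, shift)
        mu_gene = baseline * 2.0**shift
        for rep in range(1, config.n_reps_per_condition + 1):
            batch_ix = (rep - 1) % 2
            factor = config.batch_factors[batch_ix]
            depth = np.exp(rng.uniform(np.log(lo), np.log(hi)))
            sample_id = f"{condition}_{rep}"
            columns[sample_id] = _nb_draw(rng, mu_gene * factor * depth, alpha)
            rows.append(
                {"sample_id": sample_id, "pair": "kd", "condition": condition,
                 "replicate": rep, "batch": f"b{batch_ix + 1}"}
            )
    counts = pd.DataFrame(columns, index=pd.Index(truth["gene_id"], name="gene_id"))
    samples = pd.DataFrame(rows).set_index("sample_id")
    return CountExperiment(counts, samples)
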