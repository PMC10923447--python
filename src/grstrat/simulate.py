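"""Synthetic multi-cohort case-control data with latent phenotype clusters.

Genotypes are drawn under Hardy-Weinberg equilibrium, optionally with
within-block linkage disequilibrium generated from a Gaussian-copula latent
haplotype process calibrated so that the realized pairwise dosage r-squared
tracks the configured target.  Case phenotypes come from a mixture of latent
clusters; in "planted" mode each case's cluster is drawn with probability
tilted by its (weighted, centered) genotype score through a softmax with
per-cluster log-odds slope delta, which couples cluster membership to the
genetic risk score while leaving marginal allele frequencies exact.  In
"null" mode all deltas are zero and genotypes are independent of phenotype.

One root seed spawns an independent child stream per cohort so cohorts are
reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Sequence

import numpy as np
import yaml
from scipy import optimize
from scipy import stats as sps

from .panel import GenotypeMatrix, VariantPanel, VariantRecord

import pandas as pd

MODES = ("planted", "null")

PHENOTYPE_COLUMNS = (
    "sample_id", "cohort", "status", "sex", "age", "onset_age", "fev1_pct",
    "fev1_fvc", "bmi", "smoking_status", "smoking_index", "atopy", "log_ige",
    "eos_pct", "eosinophilic",
)


@dataclass(frozen=True)
class VariantSpec:
    """One simulated biallelic SNP; ``freq`` is the risk-allele frequency."""

    rsid: str
    gene: str
    freq: float
    chrom: str = "1"
    pos: int = 0
    risk_allele: str = "A"
    other_allele: str = "G"
    ld_block: str | None = None
    block_r2: float = 0.0
    tilt_weight: float = 1.0
    consequence: str = "missense"

    def __post_init__(self) -> None:
        if not 0.0 <= self.freq <= 1.0:
            raise ValueError(f"{self.rsid}: freq must lie in [0, 1], got {self.freq}")
        if not 0.0 <= self.block_r2 <= 1.0:
            raise ValueError(f"{self.rsid}: block_r2 must lie in [0, 1]")


@dataclass(frozen=True)
class ClusterSpec:
    """Latent case phenotype component.

    ``grs_delta`` is the log-odds slope coupling membership to the centered,
    standardized genotype score (positive enriches high-GRS cases).
    """

    name: str
    weight: float
    onset_mean: float
    onset_sd: float
    fev1_mean: float
    fev1_sd: float
    grs_delta: float = 0.0
    female_prob: float = 0.5
    atopy_prob: float = 0.5
    eos_prob: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError(f"{self.name}: weight must lie in [0, 1]")
        for pname in ("female_prob", "atopy_prob", "eos_prob"):
            v = getattr(self, pname)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.name}: {pname} must lie in [0, 1]")
        if self.onset_sd < 0 or self.fev1_sd < 0:
            raise ValueError(f"{self.name}: sds must be non-negative")


@dataclass(frozen=True)
class CohortSpec:
    name: str
    n_healthy: int
    n_case: int

    def __post_init__(self) -> None:
        if self.n_healthy < 0 or self.n_case < 0:
            raise ValueError(f"{self.name}: cohort sizes must be >= 0")


@dataclass
class SimulationConfig:
    seed: int
    cohorts: list[CohortSpec]
    variants: list[VariantSpec]
    clusters: list[ClusterSpec]
    mode: str = "planted"
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must lie in [0, 1]")
        if any(c.n_case > 0 for c in self.cohorts) and not self.clusters:
            raise ValueError("cohorts with cases require a nonempty cluster list")
        if self.clusters:
            total = sum(c.weight for c in self.clusters)
            if abs(total - 1.0) > 1e-8:
                raise ValueError(f"cluster weights must sum to 1, got {total}")

    def panel(self) -> VariantPanel:
        """Panel view of the simulated variants (risk alleles as configured)."""
        recs = [
            VariantRecord(rsid=v.rsid, chrom=v.chrom, pos=v.pos, gene=v.gene,
                          risk_allele=v.risk_allele, other_allele=v.other_allele,
                          consequence=v.consequence,
                          maf=min(v.freq, 1.0 - v.freq), genotyped=True)
            for v in self.variants
        ]
        return VariantPanel(recs)


@dataclass
class SyntheticDataset:
    """Genotypes + phenotypes + ground truth for one cohort."""

    cohort: str
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    truth: pd.DataFrame  # sample_id, latent_cluster

    @property
    def case_ids(self) -> np.ndarray:
        return self.phenotypes.loc[self.phenotypes["status"] == "case",
                                   "sample_id"].to_numpy()

    @property
    def control_ids(self) -> np.ndarray:
        return self.phenotypes.loc[self.phenotypes["status"] == "control",
                                   "sample_id"].to_numpy()


# ---------------------------------------------------------------------------
# LD copula calibration


def _binary_corr(rho: float, p1: float, p2: float) -> float:
    t1, t2 = sps.norm.ppf(p1), sps.norm.ppf(p2)
    p11 = sps.multivariate_normal(mean=[0.0, 0.0],
                                  cov=[[1.0, rho], [rho, 1.0]]).cdf([t1, t2])
    return (p11 - p1 * p2) / np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))


def latent_rho(r_target: float, p1: float, p2: float) -> float:
    """Latent Gaussian correlation giving allele-level correlation ``r_target``
    for thresholds at frequencies p1, p2."""
    if r_target <= 0.0:
        return 0.0
    if r_target >= 1.0:
        return 1.0
    return float(optimize.brentq(
        lambda rho: _binary_corr(rho, p1, p2) - r_target, 0.0, 1.0 - 1e-9,
        xtol=1e-6))


def _block_alleles(rng: np.random.Generator, n: int, freqs: Sequence[float],
                   block_r2: float) -> np.ndarray:
    """One haplotype's alleles (n x len(freqs)) with shared-factor LD."""
    freqs = np.asarray(freqs, dtype=float)
    r_target = float(np.sqrt(block_r2))
    pbar = float(freqs.mean())
    rho = latent_rho(r_target, pbar, pbar)
    f = rng.standard_normal(n)
    out = np.empty((n, len(freqs)), dtype=float)
    for j, p in enumerate(freqs):
        if rho >= 1.0:
            z = f
        else:
            z = np.sqrt(rho) * f + np.sqrt(1.0 - rho) * rng.standard_normal(n)
        out[:, j] = (z <= sps.norm.ppf(p)).astype(float) if 0.0 < p < 1.0 \
            else np.full(n, 1.0 if p >= 1.0 else 0.0)
    return out


# ---------------------------------------------------------------------------
# genotypes


def gen_genotypes(config: SimulationConfig, n: int,
                  rng: np.random.Generator | None = None,
                  sample_prefix: str = "S") -> GenotypeMatrix:
    """Draw an n x K dosage matrix under HWE with optional within-block LD."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    K = len(config.variants)
    dosage = np.zeros((n, K), dtype=float)

    blocks: dict[str, list[int]] = {}
    for j, v in enumerate(config.variants):
        if v.ld_block is not None:
            blocks.setdefault(str(v.ld_block), []).append(j)

    done = set()
    for j, v in enumerate(config.variants):
        if j in done:
            continue
        if v.ld_block is not None and len(blocks[str(v.ld_block)]) > 1:
            idx = blocks[str(v.ld_block)]
            freqs = [config.variants[i].freq for i in idx]
            hap1 = _block_alleles(rng, n, freqs, v.block_r2)
            hap2 = _block_alleles(rng, n, freqs, v.block_r2)
            dosage[:, idx] = hap1 + hap2
            done.update(idx)
        else:
            dosage[:, j] = rng.binomial(2, v.freq, size=n)
            done.add(j)

    if config.missing_rate > 0.0:
        mask = rng.random((n, K)) < config.missing_rate
        dosage[mask] = np.nan

    sample_ids = np.array([f"{sample_prefix}{i:05d}" for i in range(n)], dtype=object)
    rsids = np.array([v.rsid for v in config.variants], dtype=object)
    return GenotypeMatrix(sample_ids, rsids, dosage)


# ---------------------------------------------------------------------------
# phenotypes


def _tilt_score(config: SimulationConfig, dosage: np.ndarray) -> np.ndarray:
    """Centered, standardized weighted genotype score used for the cluster tilt."""
    w = np.array([v.tilt_weight for v in config.variants])
    p = np.array([v.freq for v in config.variants])
    centered = np.nan_to_num(dosage, nan=0.0) - 2.0 * p
    var = (w ** 2 * 2.0 * p * (1.0 - p)).sum()
    if var <= 0:
        return np.zeros(dosage.shape[0])
    return (centered * w).sum(axis=1) / np.sqrt(var)


def _draw_clusters(config: SimulationConfig, score: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    weights = np.array([c.weight for c in config.clusters])
    deltas = np.array([c.grs_delta for c in config.clusters])
    if config.mode == "null":
        deltas = np.zeros_like(deltas)
    logits = np.log(np.maximum(weights, 1e-300))[None, :] + score[:, None] * deltas[None, :]
    logits -= logits.max(axis=1, keepdims=True)
    probs = np.exp(logits)
    probs /= probs.sum(axis=1, keepdims=True)
    u = rng.random(score.shape[0])
    cum = probs.cumsum(axis=1)
    return (u[:, None] > cum).sum(axis=1)


def _case_phenotypes(config: SimulationConfig, cohort: str, ids: np.ndarray,
                     labels: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    n = len(ids)
    cl = [config.clusters[i] for i in labels]
    onset = np.clip(rng.normal([c.onset_mean for c in cl],
                               [max(c.onset_sd, 1e-9) for c in cl]), 0.0, 90.0)
    fev1 = np.clip(rng.normal([c.fev1_mean for c in cl],
                              [max(c.fev1_sd, 1e-9) for c in cl]), 10.0, 150.0)
    female = rng.random(n) < np.array([c.female_prob for c in cl])
    atopy = rng.random(n) < np.array([c.atopy_prob for c in cl])
    eos = rng.random(n) < np.array([c.eos_prob for c in cl])
    age = np.clip(onset + rng.uniform(2.0, 30.0, n), 16.0, 95.0)
    fev1_fvc = np.clip(0.25 * fev1 + 48.0 + rng.normal(0.0, 5.0, n), 25.0, 100.0)
    bmi = np.clip(rng.normal(23.5, 4.0, n), 14.0, 45.0)
    log_ige = np.clip(rng.normal(2.2, 0.65, n), 0.0, 5.0)
    smoking = rng.choice(["never", "ex", "current"], size=n, p=[0.55, 0.30, 0.15])
    smoking_index = np.where(smoking == "never", 0.0,
                             np.round(rng.gamma(2.0, 150.0, n)))
    eos_pct = np.where(eos, rng.uniform(5.0, 15.0, n), rng.uniform(0.0, 4.9, n))
    return pd.DataFrame({
        "sample_id": ids, "cohort": cohort, "status": "case",
        "sex": np.where(female, "F", "M"), "age": np.round(age, 1),
        "onset_age": np.round(onset, 1), "fev1_pct": np.round(fev1, 2),
        "fev1_fvc": np.round(fev1_fvc, 2), "bmi": np.round(bmi, 2),
        "smoking_status": smoking, "smoking_index": smoking_index,
        "atopy": atopy.astype(int), "log_ige": np.round(log_ige, 3),
        "eos_pct": np.round(eos_pct, 2), "eosinophilic": eos.astype(int),
    })


def _control_phenotypes(cohort: str, ids: np.ndarray,
                        rng: np.random.Generator) -> pd.DataFrame:
    n = len(ids)
    female = rng.random(n) < 0.5
    age = np.clip(rng.normal(50.0, 15.0, n), 18.0, 90.0)
    fev1 = np.clip(rng.normal(96.0, 12.0, n), 40.0, 150.0)
    smoking = rng.choice(["never", "ex", "current"], size=n, p=[0.6, 0.25, 0.15])
    eos = rng.random(n) < 0.1
    return pd.DataFrame({
        "sample_id": ids, "cohort": cohort, "status": "control",
        "sex": np.where(female, "F", "M"), "age": np.round(age, 1),
        "onset_age": np.nan, "fev1_pct": np.round(fev1, 2),
        "fev1_fvc": np.round(np.clip(0.25 * fev1 + 48.0 + rng.normal(0, 5, n),
                                     25, 100), 2),
        "bmi": np.round(np.clip(rng.normal(23.0, 3.5, n), 14, 45), 2),
        "smoking_status": smoking,
        "smoking_index": np.where(smoking == "never", 0.0,
                                  np.round(rng.gamma(2.0, 150.0, n))),
        "atopy": (rng.random(n) < 0.3).astype(int),
        "log_ige": np.round(np.clip(rng.normal(1.8, 0.6, n), 0, 5), 3),
        "eos_pct": np.round(np.where(eos, rng.uniform(5, 12, n),
                                     rng.uniform(0, 4.9, n)), 2),
        "eosinophilic": eos.astype(int),
    })


def simulate_cohort(config: SimulationConfig, cohort: CohortSpec,
                    rng: np.random.Generator | None = None) -> SyntheticDataset:
    """One cohort: controls first, then cases with latent cluster labels."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n = cohort.n_healthy + cohort.n_case
    genotypes = gen_genotypes(config, n, rng=rng, sample_prefix=f"{cohort.name}-")
    ctrl_ids = genotypes.sample_ids[: cohort.n_healthy]
    case_ids = genotypes.sample_ids[cohort.n_healthy:]

    frames = []
    truth_rows = []
    if cohort.n_healthy:
        frames.append(_control_phenotypes(cohort.name, ctrl_ids, rng))
        truth_rows.append(pd.DataFrame({"sample_id": ctrl_ids,
                                        "latent_cluster": "healthy"}))
    if cohort.n_case:
        if not config.clusters:
            raise ValueError("cohort with cases requires a nonempty cluster list")
        score = _tilt_score(config, genotypes.dosage[cohort.n_healthy:])
        labels = _draw_clusters(config, score, rng)
        frames.append(_case_phenotypes(config, cohort.name, case_ids, labels, rng))
        truth_rows.append(pd.DataFrame({
            "sample_id": case_ids,
            "latent_cluster": [config.clusters[i].name for i in labels]}))
    phenotypes = pd.concat(frames, ignore_index=True) if frames else \
        pd.DataFrame(columns=list(PHENOTYPE_COLUMNS))
    truth = pd.concat(truth_rows, ignore_index=True) if truth_rows else \
        pd.DataFrame(columns=["sample_id", "latent_cluster"])
    return SyntheticDataset(cohort=cohort.name, genotypes=genotypes,
                            phenotypes=phenotypes, truth=truth)


def simulate_all(config: SimulationConfig) -> dict[str, SyntheticDataset]:
    """All cohorts, each from its own child stream of the root seed."""
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(len(config.cohorts))
    out = {}
    for cohort, seq in zip(config.cohorts, children):
        out[cohort.name] = simulate_cohort(config, cohort,
                                           rng=np.random.default_rng(seq))
    return out


# ---------------------------------------------------------------------------
# configuration I/O


def config_from_dict(d: dict) -> SimulationConfig:
    return SimulationConfig(
        seed=int(d.get("seed", 0)),
        cohorts=[CohortSpec(**c) for c in d.get("cohorts", [])],
        variants=[VariantSpec(**v) for v in d.get("variants", [])],
        clusters=[ClusterSpec(**c) for c in d.get("clusters", [])],
        mode=d.get("mode", "planted"),
        missing_rate=float(d.get("missing_rate", 0.0)),
    )


def config_to_dict(config: SimulationConfig) -> dict:
    return {
        "seed": config.seed,
        "mode": config.mode,
        "missing_rate": config.missing_rate,
        "cohorts": [asdict(c) for c in config.cohorts],
        "variants": [asdict(v) for v in config.variants],
        "clusters": [asdict(c) for c in config.clusters],
    }


def load_config(path) -> SimulationConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def default_config(seed: int = 0, mode: str = "planted") -> SimulationConfig:
    """The packaged three-cohort default scenario."""
    with resources.files("grstrat.data").joinpath("default_config.yaml").open() as fh:
        d = yaml.safe_load(fh)
    d["seed"] = seed
    d["mode"] = mode
    return config_from_dict(d)
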