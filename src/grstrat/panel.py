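"""SNP panel filtering, genotype QC and allele-count genetic risk scores.

A :class:`VariantPanel` holds the variants whose risk-allele dosages are
summed into an unweighted genetic risk score (GRS).  The filter chain mirrors
a standard candidate-SNP workflow:

* common-variant screen (MAF >= threshold),
* imputation-quality screen (directly genotyped variants always pass),
* greedy LD pruning on pairwise dosage r-squared,
* chip-style genotype QC (sample/variant call rates, MAF, Hardy-Weinberg
  exact test evaluated in controls).

Dosages count copies of the *risk* allele (the molecular-consequence allele),
which need not be the minor allele.  Missing dosages are NaN.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

CONSEQUENCES = ("missense", "nonsense", "utr3")


@dataclass(frozen=True)
class VariantRecord:
    """One panel SNP with the allele whose copies are counted in the GRS."""

    rsid: str
    chrom: str
    pos: int
    gene: str
    risk_allele: str
    other_allele: str = "N"
    consequence: str = "missense"
    maf: float | None = None
    imputation_r2: float | None = None
    genotyped: bool = True

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCES:
            raise ValueError(
                f"{self.rsid}: consequence must be one of {CONSEQUENCES}, "
                f"got {self.consequence!r}"
            )
        if self.maf is not None and not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"{self.rsid}: maf must lie in [0, 0.5], got {self.maf}")
        if self.imputation_r2 is not None and not 0.0 <= self.imputation_r2 <= 1.0:
            raise ValueError(f"{self.rsid}: imputation_r2 must lie in [0, 1]")


@dataclass(frozen=True)
class FilterStage:
    """Provenance for one filter application."""

    name: str
    params: tuple[tuple[str, object], ...]
    n_in: int
    n_out: int


@dataclass
class VariantPanel:
    """Ordered SNP set plus the provenance of every filter applied to it."""

    records: list[VariantRecord]
    provenance: list[FilterStage] = field(default_factory=list)

    def __post_init__(self) -> None:
        rsids = [r.rsid for r in self.records]
        if len(set(rsids)) != len(rsids):
            raise ValueError("panel rsids must be unique")

    @property
    def rsids(self) -> list[str]:
        return [r.rsid for r in self.records]

    @property
    def K(self) -> int:
        return len(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def get(self, rsid: str) -> VariantRecord:
        for rec in self.records:
            if rec.rsid == rsid:
                return rec
        raise KeyError(rsid)

    def subset(self, rsids: Sequence[str], stage: FilterStage | None = None) -> "VariantPanel":
        keep = set(rsids)
        records = [r for r in self.records if r.rsid in keep]
        prov = list(self.provenance)
        if stage is not None:
            prov.append(stage)
        return VariantPanel(records, prov)

    # -- filter chain -------------------------------------------------------

    def filter_maf(self, threshold: float) -> "VariantPanel":
        kept = filter_by_maf(self.records, threshold)
        stage = FilterStage("maf", (("threshold", threshold),), len(self.records), len(kept))
        return VariantPanel(kept, self.provenance + [stage])

    def filter_imputation(self, r2_min: float) -> "VariantPanel":
        kept = filter_by_imputation(self.records, r2_min)
        stage = FilterStage("imputation_r2", (("r2_min", r2_min),), len(self.records), len(kept))
        return VariantPanel(kept, self.provenance + [stage])

    def prune_ld(self, genotypes: "GenotypeMatrix", r2_max: float) -> "VariantPanel":
        sub = genotypes.subset_variants([r for r in self.rsids if r in set(genotypes.rsids)])
        kept = ld_prune(sub, r2_max)
        stage = FilterStage("ld_prune", (("r2_max", r2_max),), len(self.records), len(kept))
        return self.subset(kept, stage)

    # -- serialisation ------------------------------------------------------

    PANEL_COLUMNS = (
        "rsid", "chrom", "pos", "gene", "risk_allele", "other_allele",
        "consequence", "maf", "imputation_r2", "genotyped",
    )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "rsid": r.rsid, "chrom": r.chrom, "pos": r.pos, "gene": r.gene,
                "risk_allele": r.risk_allele, "other_allele": r.other_allele,
                "consequence": r.consequence, "maf": r.maf,
                "imputation_r2": r.imputation_r2, "genotyped": int(r.genotyped),
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=list(self.PANEL_COLUMNS))

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "VariantPanel":
        records = []
        for row in df.itertuples(index=False):
            maf = getattr(row, "maf", None)
            r2 = getattr(row, "imputation_r2", None)
            records.append(
                VariantRecord(
                    rsid=str(row.rsid),
                    chrom=str(row.chrom),
                    pos=int(row.pos),
                    gene=str(row.gene),
                    risk_allele=str(row.risk_allele),
                    other_allele=str(getattr(row, "other_allele", "N")),
                    consequence=str(getattr(row, "consequence", "missense")),
                    maf=None if maf is None or pd.isna(maf) else float(maf),
                    imputation_r2=None if r2 is None or pd.isna(r2) else float(r2),
                    genotyped=bool(int(getattr(row, "genotyped", 1))),
                )
            )
        return cls(records)

    @classmethod
    def from_tsv(cls, path) -> "VariantPanel":
        return cls.from_frame(pd.read_csv(path, sep="\t", na_values=["NA"]))

    @classmethod
    def default(cls) -> "VariantPanel":
        """The packaged 12-SNP ciliary-gene panel."""
        with resources.files("grstrat.data").joinpath("default_panel.tsv").open("r") as fh:
            return cls.from_tsv(fh)


@dataclass
class GenotypeMatrix:
    """Individuals x variants risk-allele dosage matrix.

    ``dosage`` is float with values in {0, 1, 2} and NaN for missing calls.
    """

    sample_ids: np.ndarray
    rsids: np.ndarray
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.rsids = np.asarray(self.rsids, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.sample_ids), len(self.rsids)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.rsids)} variants"
            )
        finite = self.dosage[~np.isnan(self.dosage)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be 0, 1, 2 or NaN")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.rsids)

    def variant_index(self, rsid: str) -> int:
        idx = np.flatnonzero(self.rsids == rsid)
        if idx.size == 0:
            raise KeyError(f"variant {rsid!r} absent from genotype matrix")
        return int(idx[0])

    def column(self, rsid: str) -> np.ndarray:
        return self.dosage[:, self.variant_index(rsid)]

    def sample_call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosage).mean(axis=1)

    def variant_call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosage).mean(axis=0)

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        order = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [order[s] for s in sample_ids]
        return GenotypeMatrix(np.asarray(sample_ids, dtype=object), self.rsids.copy(),
                              self.dosage[idx])

    def subset_variants(self, rsids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.variant_index(r) for r in rsids]
        return GenotypeMatrix(self.sample_ids.copy(), np.asarray(rsids, dtype=object),
                              self.dosage[:, idx])

    @classmethod
    def concat(cls, matrices: Sequence["GenotypeMatrix"]) -> "GenotypeMatrix":
        if not matrices:
            raise ValueError("nothing to concatenate")
        rsids = matrices[0].rsids
        for m in matrices[1:]:
            if not np.array_equal(m.rsids, rsids):
                raise ValueError("variant sets differ between matrices")
        return cls(
            np.concatenate([m.sample_ids for m in matrices]),
            rsids.copy(),
            np.vstack([m.dosage for m in matrices]),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosage, index=pd.Index(self.sample_ids, name="sample_id"),
                            columns=list(self.rsids))

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", na_rep="NA", float_format="%.0f")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenotypeMatrix":
        return cls(df.index.to_numpy(dtype=object), df.columns.to_numpy(dtype=object),
                   df.to_numpy(dtype=float))

    @classmethod
    def from_tsv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        return cls.from_frame(df)


@dataclass
class GRSVector:
    """Per-individual risk-allele count plus the number of missing loci."""

    sample_ids: np.ndarray
    grs: np.ndarray
    n_missing_loci: np.ndarray

    def to_frame(self, cohort: str | None = None,
                 status: Sequence[str] | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"sample_id": self.sample_ids, "grs": self.grs,
                           "n_missing_loci": self.n_missing_loci})
        if cohort is not None:
            df.insert(1, "cohort", cohort)
        if status is not None:
            df.insert(2 if cohort is not None else 1, "status", list(status))
        return df


@dataclass
class QCReport:
    removed_samples: dict[str, str]
    removed_variants: dict[str, str]
    n_samples_in: int
    n_samples_out: int
    n_variants_in: int
    n_variants_out: int


# ---------------------------------------------------------------------------
# filters


def filter_by_maf(candidates: Iterable[VariantRecord], threshold: float) -> list[VariantRecord]:
    """Keep records with ``maf >= threshold`` (boundary inclusive).

    Records with no MAF annotation are rejected with a logged reason.
    """
    kept = []
    for rec in candidates:
        if rec.maf is None:
            logger.warning("%s rejected by MAF filter: no MAF annotation", rec.rsid)
            continue
        if rec.maf >= threshold:
            kept.append(rec)
    return kept


def filter_by_imputation(records: Iterable[VariantRecord], r2_min: float) -> list[VariantRecord]:
    """Keep directly genotyped records, and imputed ones with r2 >= ``r2_min``."""
    kept = []
    for rec in records:
        if rec.genotyped:
            kept.append(rec)
        elif rec.imputation_r2 is not None and rec.imputation_r2 >= r2_min:
            kept.append(rec)
        else:
            logger.warning("%s rejected by imputation filter (r2=%s)",
                           rec.rsid, rec.imputation_r2)
    return kept


def dosage_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage columns, pairwise complete.

    Monomorphic columns (zero variance among complete pairs) give 0 so they
    pass pruning trivially.
    """
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 2:
        return 0.0
    xv, yv = x[ok], y[ok]
    sx, sy = xv.std(), yv.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    r = float(np.corrcoef(xv, yv)[0, 1])
    return r * r


def ld_prune(genotypes: GenotypeMatrix, r2_max: float) -> list[str]:
    """Greedy LD pruning in matrix column order.

    A variant is dropped when its dosage r-squared with any already-retained
    variant exceeds ``r2_max``; the earlier variant of a correlated pair is
    kept.  Returns the retained rsids in their original order.
    """
    for j, rsid in enumerate(genotypes.rsids):
        if np.isnan(genotypes.dosage[:, j]).all():
            raise ValueError(f"variant {rsid!r} has no non-missing dosages")
    kept: list[int] = []
    for j in range(genotypes.n_variants):
        col = genotypes.dosage[:, j]
        if all(dosage_r2(genotypes.dosage[:, i], col) <= r2_max for i in kept):
            kept.append(j)
    return [genotypes.rsids[j] for j in kept]


# ---------------------------------------------------------------------------
# per-variant statistics


def compute_maf(genotypes: GenotypeMatrix, rsid: str) -> float:
    """Folded minor-allele frequency of one variant from its dosages."""
    col = genotypes.column(rsid)
    ok = ~np.isnan(col)
    if not ok.any():
        raise ValueError(f"variant {rsid!r} has no non-missing dosages")
    f = float(col[ok].sum() / (2.0 * ok.sum()))
    return min(f, 1.0 - f)


def genotype_counts(col: np.ndarray) -> tuple[int, int, int]:
    """(hom-risk, het, hom-other) counts of a dosage column, missing excluded."""
    ok = ~np.isnan(col)
    vals = col[ok]
    return int((vals == 2).sum()), int((vals == 1).sum()), int((vals == 0).sum())


def hwe_exact_test(n_AA: int, n_AB: int, n_BB: int) -> float:
    """Two-sided exact Hardy-Weinberg test p-value.

    Conditions on the allele counts and sums the probabilities of every
    heterozygote count no more probable than the observed one (the standard
    chip-QC exact test).  Returns 1.0 for monomorphic input.
    """
    for name, c in (("n_AA", n_AA), ("n_AB", n_AB), ("n_BB", n_BB)):
        if c < 0:
            raise ValueError(f"{name} must be non-negative, got {c}")
    n = n_AA + n_AB + n_BB
    if n < 1:
        raise ValueError("total genotype count must be >= 1")
    minor = min(2 * n_AA + n_AB, 2 * n_BB + n_AB)
    if minor == 0:
        return 1.0
    hets = np.arange(minor % 2, minor + 1, 2)
    hom_minor = (minor - hets) // 2
    hom_major = n - hets - hom_minor
    # multinomial coefficient x 2^het, conditional normalisation via logsumexp
    logw = (
        hets * math.log(2.0)
        - np.array([math.lgamma(h + 1) for h in hets])
        - np.array([math.lgamma(h + 1) for h in hom_minor])
        - np.array([math.lgamma(h + 1) for h in hom_major])
    )
    logp = logw - logsumexp(logw)
    probs = np.exp(logp)
    p_obs = probs[hets == n_AB][0]
    p = probs[probs <= p_obs * (1.0 + 1e-12)].sum()
    return float(min(1.0, p))


# ---------------------------------------------------------------------------
# genotype QC


def qc_genotypes(
    genotypes: GenotypeMatrix,
    maf_min: float = 0.01,
    hwe_p_min: float = 1e-6,
    sample_call_min: float = 0.9,
    variant_call_min: float = 0.9,
    controls: Sequence[str] | None = None,
) -> tuple[GenotypeMatrix, QCReport]:
    """Chip-style QC: call rates strictly above the thresholds are kept,
    variants need MAF >= ``maf_min`` and HWE exact p >= ``hwe_p_min``.

    HWE is evaluated in ``controls`` (sample-id subset) when given, otherwise
    in all retained samples.
    """
    for name, t in (("maf_min", maf_min), ("hwe_p_min", hwe_p_min),
                    ("sample_call_min", sample_call_min),
                    ("variant_call_min", variant_call_min)):
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {t}")

    removed_samples: dict[str, str] = {}
    removed_variants: dict[str, str] = {}

    scr = genotypes.sample_call_rate()
    keep_samples = scr > sample_call_min
    for sid, rate in zip(genotypes.sample_ids[~keep_samples], scr[~keep_samples]):
        removed_samples[str(sid)] = f"sample call rate {rate:.3f} <= {sample_call_min}"
    mat = GenotypeMatrix(genotypes.sample_ids[keep_samples], genotypes.rsids.copy(),
                         genotypes.dosage[keep_samples])
    if mat.n_samples == 0:
        raise ValueError("no samples left after sample call-rate QC")

    if controls is not None:
        ctrl_set = set(controls)
        ctrl_mask = np.array([s in ctrl_set for s in mat.sample_ids])
    else:
        ctrl_mask = np.ones(mat.n_samples, dtype=bool)

    vcr = mat.variant_call_rate()
    keep = []
    for j, rsid in enumerate(mat.rsids):
        col = mat.dosage[:, j]
        if vcr[j] <= variant_call_min:
            removed_variants[str(rsid)] = (
                f"variant call rate {vcr[j]:.3f} <= {variant_call_min}")
            continue
        maf = compute_maf(mat, rsid)
        if maf < maf_min:
            removed_variants[str(rsid)] = f"MAF {maf:.4f} < {maf_min}"
            continue
        if ctrl_mask.any():
            hom_r, het, hom_o = genotype_counts(col[ctrl_mask])
            if hom_r + het + hom_o >= 1:
                p = hwe_exact_test(hom_r, het, hom_o)
                if p < hwe_p_min:
                    removed_variants[str(rsid)] = f"HWE exact p {p:.3g} < {hwe_p_min}"
                    continue
        keep.append(str(rsid))
    if not keep:
        raise ValueError("no variants left after variant QC")

    out = mat.subset_variants(keep)
    report = QCReport(
        removed_samples=removed_samples,
        removed_variants=removed_variants,
        n_samples_in=genotypes.n_samples, n_samples_out=out.n_samples,
        n_variants_in=genotypes.n_variants, n_variants_out=out.n_variants,
    )
    return out, report


# ---------------------------------------------------------------------------
# GRS


def compute_grs(genotypes: GenotypeMatrix, panel: VariantPanel,
                missing_policy: str = "zero") -> GRSVector:
    """Unweighted allele-count GRS over the panel variants.

    Default policy counts a missing dosage as 0 and increments
    ``n_missing_loci`` (keeps the score integral); ``missing_policy="mean"``
    substitutes the variant's mean dosage instead.
    """
    if missing_policy not in ("zero", "mean"):
        raise ValueError("missing_policy must be 'zero' or 'mean'")
    have = set(genotypes.rsids)
    absent = [r for r in panel.rsids if r not in have]
    if absent:
        raise KeyError(f"panel variants absent from genotype matrix: {absent}")
    idx = [genotypes.variant_index(r) for r in panel.rsids]
    sub = genotypes.dosage[:, idx]
    missing = np.isnan(sub)
    n_missing = missing.sum(axis=1)
    if missing_policy == "zero":
        grs = np.nansum(sub, axis=1)
    else:
        col_means = np.nanmean(sub, axis=0)
        filled = np.where(missing, np.broadcast_to(col_means, sub.shape), sub)
        grs = filled.sum(axis=1)
    return GRSVector(genotypes.sample_ids.copy(), grs, n_missing)
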