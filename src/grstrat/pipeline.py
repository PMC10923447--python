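"""Per-cohort analysis orchestration and cross-cohort group contrasts.

Flow per cohort: risk score -> two-step clustering of cases on
(GRS, %predicted FEV1, onset age) -> clusters lettered A.. by decreasing
mean GRS -> Tukey contrast of every cluster against healthy controls ->
GRS-extreme clusters selected (p < alpha with direction).  Extreme clusters
are pooled across cohorts into Hi / Lo / average combined groups, which are
compared per SNP (allele-based 2x2 with the Hi group as reference) and
pooled by fixed-effect meta-analysis.
"""

from __future__ import annotations

import hashlib
import json
import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats as st
from .panel import GenotypeMatrix, GRSVector, VariantPanel, compute_grs, qc_genotypes
from .simulate import SimulationConfig, SyntheticDataset, config_to_dict, simulate_all
from .twostep import ClusterModel, FeatureMatrix, fit

CLUSTER_FEATURES = ("grs", "fev1_pct", "onset_age")


# ---------------------------------------------------------------------------
# per-cohort results


@dataclass
class CohortResult:
    """Fitted clustering for one cohort with letter labels and Tukey contrasts."""

    cohort: str
    model: ClusterModel
    letter_of: dict[int, str]            # internal label -> letter
    assignments: pd.DataFrame            # sample_id, cluster (letter)
    cluster_grs: pd.DataFrame            # cluster, n, grs_mean, grs_sd
    healthy_grs: tuple[int, float, float]  # n, mean, sd
    tukey: st.TukeyResult | None = None
    n_deleted: int = 0

    @property
    def letters(self) -> list[str]:
        return sorted(self.letter_of.values())

    def members(self, letter: str) -> np.ndarray:
        return self.assignments.loc[self.assignments["cluster"] == letter,
                                    "sample_id"].to_numpy()


def build_features(phenotypes: pd.DataFrame, grs: GRSVector) -> tuple[FeatureMatrix, int]:
    """Join case phenotypes with GRS and apply listwise deletion on the three
    clustering variables.  Returns the complete-case matrix and the number of
    deleted cases."""
    cases = phenotypes.loc[phenotypes["status"] == "case"].copy()
    gdf = pd.DataFrame({"sample_id": grs.sample_ids, "grs": grs.grs})
    merged = cases.merge(gdf, on="sample_id", how="left")
    cols = ["grs", "fev1_pct", "onset_age"]
    complete = merged.dropna(subset=cols)
    n_deleted = len(merged) - len(complete)
    fm = FeatureMatrix(
        sample_ids=complete["sample_id"].to_numpy(dtype=object),
        X=complete[cols].to_numpy(dtype=float),
        feature_names=CLUSTER_FEATURES,
    )
    return fm, n_deleted


def label_clusters(model: ClusterModel, grs_values: np.ndarray,
                   cohort: str = "") -> dict[int, str]:
    """Letter labels A, B, ... by decreasing cluster mean GRS.

    Ties on the mean break by cluster size (descending), then by the
    internal cluster index.
    """
    order = []
    for c in range(1, model.k + 1):
        members = model.members(c)
        order.append((c, float(np.mean(grs_values[members])), int(members.size)))
    order.sort(key=lambda t: (-t[1], -t[2], t[0]))
    return {c: string.ascii_uppercase[i] for i, (c, _, _) in enumerate(order)}


def analyze_cohort(cohort: str, phenotypes: pd.DataFrame, grs: GRSVector,
                   J_max: int = 15) -> CohortResult:
    """Cluster one cohort's cases and contrast each cluster against healthy."""
    fm, n_deleted = build_features(phenotypes, grs)
    model = fit(fm, J_max=J_max)
    grs_values = fm.X[:, 0]
    letter_of = label_clusters(model, grs_values, cohort)

    assignments = pd.DataFrame({
        "sample_id": model.sample_ids,
        "cluster": [letter_of[int(c)] for c in model.assignments],
    })
    rows = []
    for c in range(1, model.k + 1):
        members = model.members(c)
        vals = grs_values[members]
        rows.append({"cluster": letter_of[c], "n": int(members.size),
                     "grs_mean": float(vals.mean()),
                     "grs_sd": float(vals.std(ddof=1)) if members.size > 1 else 0.0})
    cluster_grs = pd.DataFrame(rows).sort_values("cluster", ignore_index=True)

    gdf = pd.DataFrame({"sample_id": grs.sample_ids, "grs": grs.grs})
    healthy = phenotypes.loc[phenotypes["status"] == "control", ["sample_id"]] \
        .merge(gdf, on="sample_id")["grs"].to_numpy(dtype=float)
    result = CohortResult(
        cohort=cohort, model=model, letter_of=letter_of,
        assignments=assignments, cluster_grs=cluster_grs,
        healthy_grs=(int(healthy.size), float(healthy.mean()) if healthy.size else float("nan"),
                     float(healthy.std(ddof=1)) if healthy.size > 1 else 0.0),
        n_deleted=n_deleted,
    )
    if healthy.size >= 2:
        values = np.concatenate([healthy, grs_values])
        groups = np.concatenate([np.repeat("healthy", healthy.size),
                                 assignments["cluster"].to_numpy()])
        result.tukey = st.tukey_hsd(values, groups)
    return result


def select_extreme_clusters(result: CohortResult,
                            alpha: float = 0.05) -> tuple[set[str], set[str]]:
    """Clusters whose GRS differs from healthy (Tukey p < alpha), split by
    direction of the mean difference."""
    if result.tukey is None:
        raise ValueError(f"cohort {result.cohort}: no healthy group present")
    _, healthy_mean, _ = result.healthy_grs
    hi, lo = set(), set()
    for row in result.cluster_grs.itertuples(index=False):
        p = result.tukey.pvalue("healthy", row.cluster)
        if p < alpha:
            (hi if row.grs_mean > healthy_mean else lo).add(row.cluster)
    return hi, lo


# ---------------------------------------------------------------------------
# combined groups and contrasts

GROUP_NAMES = {1: "hi", 2: "lo", 3: "average"}


@dataclass
class GroupContrast:
    """Hi / Lo / average combined groups and their per-SNP contrasts."""

    membership: pd.DataFrame             # sample_id, cohort, cluster, group (1/2/3)
    selections: dict[str, tuple[set[str], set[str]]]
    per_snp: pd.DataFrame | None = None  # cohort, rsid, or, p, log_or, se
    meta: pd.DataFrame | None = None     # rsid, or, p, q, i2
    summary: pd.DataFrame | None = None

    def group_sizes(self) -> dict[int, int]:
        return self.membership["group"].value_counts().to_dict()

    def group_ids(self, group: int, cohort: str | None = None) -> np.ndarray:
        m = self.membership
        sel = m["group"] == group
        if cohort is not None:
            sel &= m["cohort"] == cohort
        return m.loc[sel, "sample_id"].to_numpy()


def combine_groups(results: list[CohortResult],
                   selections: dict[str, tuple[set[str], set[str]]]) -> GroupContrast:
    """Pool Hi clusters into group 1, Lo into group 2, the rest into group 3.

    The three groups partition all clustered cases across cohorts.
    """
    frames = []
    for res in results:
        hi, lo = selections[res.cohort]
        if hi & lo:
            raise ValueError(f"{res.cohort}: clusters {hi & lo} in both Hi and Lo")
        df = res.assignments.copy()
        df["cohort"] = res.cohort
        df["group"] = [1 if c in hi else 2 if c in lo else 3 for c in df["cluster"]]
        frames.append(df[["sample_id", "cohort", "cluster", "group"]])
    membership = pd.concat(frames, ignore_index=True)
    if membership["sample_id"].duplicated().any():
        raise ValueError("overlapping sample membership across cohorts")
    return GroupContrast(membership=membership, selections=selections)


def _allele_counts(genotypes: GenotypeMatrix, sample_ids: np.ndarray,
                   rsid: str) -> tuple[int, int]:
    sub = genotypes.subset_samples(list(sample_ids))
    col = sub.column(rsid)
    ok = ~np.isnan(col)
    return int(col[ok].sum()), int(2 * ok.sum())


def contrast_extremes(genotypes_by_cohort: dict[str, GenotypeMatrix],
                      contrast: GroupContrast, panel: VariantPanel,
                      reference: str = "hi") -> GroupContrast:
    """Per SNP and cohort: allele 2x2 of the Lo group against the Hi group
    (Hi as reference by default), then a fixed-effect meta-analysis per SNP
    across cohorts.  Cohorts with an empty group are skipped with a warning.
    """
    import warnings as _warnings

    if reference not in ("hi", "lo"):
        raise ValueError("reference must be 'hi' or 'lo'")
    numer_group, denom_group = (2, 1) if reference == "hi" else (1, 2)

    rows = []
    for cohort, gmat in genotypes_by_cohort.items():
        ids_num = contrast.group_ids(numer_group, cohort)
        ids_den = contrast.group_ids(denom_group, cohort)
        if len(ids_num) == 0 or len(ids_den) == 0:
            _warnings.warn(f"cohort {cohort}: empty extreme group; skipped")
            continue
        for rsid in panel.rsids:
            a, na = _allele_counts(gmat, ids_num, rsid)
            c, nc = _allele_counts(gmat, ids_den, rsid)
            res = st.allele_assoc_2x2(a, na, c, nc)
            rows.append({"cohort": cohort, "rsid": rsid, "or": res.or_point,
                         "p": res.pvalue, "log_or": res.log_or, "se": res.log_or_se})
    per_snp = pd.DataFrame(rows, columns=["cohort", "rsid", "or", "p",
                                          "log_or", "se"])

    meta_rows = []
    for rsid in panel.rsids:
        sub = per_snp.loc[per_snp["rsid"] == rsid]
        if len(sub) == 0:
            continue
        m = st.meta_fixed(list(zip(sub["log_or"], sub["se"])))
        meta_rows.append({"rsid": rsid, "or": m.or_point, "p": m.pvalue,
                          "q": m.q, "i2": m.i2, "k": m.k})
    contrast.per_snp = per_snp
    contrast.meta = pd.DataFrame(meta_rows)
    return contrast


def cluster_vs_rest(result: CohortResult, genotypes: GenotypeMatrix,
                    panel: VariantPanel, clusters: set[str],
                    comparison: str = "rest",
                    control_ids: np.ndarray | None = None) -> pd.DataFrame:
    """Per-SNP allele contrast of an extreme cluster set against either the
    remaining clustered cases (``comparison="rest"``) or healthy controls
    (``comparison="controls"``)."""
    in_ids = np.concatenate([result.members(c) for c in sorted(clusters)]) \
        if clusters else np.array([], dtype=object)
    if comparison == "rest":
        other = result.assignments.loc[~result.assignments["cluster"].isin(clusters),
                                       "sample_id"].to_numpy()
    elif comparison == "controls":
        if control_ids is None:
            raise ValueError("comparison='controls' requires control_ids")
        other = control_ids
    else:
        raise ValueError("comparison must be 'rest' or 'controls'")
    rows = []
    for rsid in panel.rsids:
        a, na = _allele_counts(genotypes, in_ids, rsid)
        c, nc = _allele_counts(genotypes, other, rsid)
        res = st.allele_assoc_2x2(a, na, c, nc)
        rows.append({"cohort": result.cohort, "clusters": "".join(sorted(clusters)),
                     "comparison": comparison, "rsid": rsid,
                     "or": res.or_point, "p": res.pvalue})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# combined-group phenotype summary (the three-column report)


def combined_summary(contrast: GroupContrast,
                     phenotypes: pd.DataFrame,
                     grs_frames: pd.DataFrame) -> pd.DataFrame:
    """Three-group phenotype comparison table.

    Continuous variables get pooled mean (sd) or median (range); categorical
    variables get counts with Pearson adjusted standardized residuals from
    the group x category table.
    """
    merged = contrast.membership.merge(phenotypes, on="sample_id", how="left",
                                       suffixes=("", "_ph"))
    merged = merged.merge(grs_frames[["sample_id", "grs"]], on="sample_id", how="left")
    groups = [1, 2, 3]
    out_rows = []

    sizes = {g: int((merged["group"] == g).sum()) for g in groups}
    out_rows.append({"variable": "N", **{f"group{g}": sizes[g] for g in groups}})

    for var, how in (("grs", "mean"), ("fev1_pct", "mean"), ("fev1_fvc", "mean"),
                     ("log_ige", "mean"), ("age", "median"), ("onset_age", "median")):
        row = {"variable": var}
        for g in groups:
            vals = merged.loc[merged["group"] == g, var].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                row[f"group{g}"] = "NA"
            elif how == "mean":
                row[f"group{g}"] = f"{vals.mean():.2f} ({vals.std(ddof=1):.2f})"
            else:
                row[f"group{g}"] = (f"{np.median(vals):.1f} "
                                    f"({vals.min():.0f}-{vals.max():.0f})")
        out_rows.append(row)

    for var, positive in (("sex", "F"), ("atopy", 1), ("eosinophilic", 1)):
        counts = []
        for g in groups:
            sub = merged.loc[merged["group"] == g, var].dropna()
            counts.append((int((sub == positive).sum()), int(len(sub))))
        table = np.array([[c for c, _ in counts],
                          [t - c for c, t in counts]], dtype=float)
        try:
            chi = st.chi2_rxc(table)
            resid = chi.adjusted_residuals[0]
            pval = chi.pvalue
        except ValueError:
            resid = [float("nan")] * 3
            pval = float("nan")
        row = {"variable": var}
        for i, g in enumerate(groups):
            c, t = counts[i]
            pct = 100.0 * c / t if t else float("nan")
            row[f"group{g}"] = f"{c} ({pct:.1f}%)"
        row["pvalue"] = pval
        out_rows.append(row)
        out_rows.append({"variable": f"{var}_adjusted_residual",
                         **{f"group{g}": f"{resid[i]:.2f}" for i, g in enumerate(groups)}})
    return pd.DataFrame(out_rows)


# ---------------------------------------------------------------------------
# end-to-end driver


@dataclass
class RunResult:
    cohort_results: dict[str, CohortResult]
    contrast: GroupContrast
    datasets: dict[str, SyntheticDataset] = field(repr=False, default=None)
    manifest: dict = field(default_factory=dict)


def run_all(config: SimulationConfig, out_dir: str | Path | None = None,
            alpha: float = 0.05, J_max: int = 15,
            qc: bool = True, missing_policy: str = "zero") -> RunResult:
    """Simulate (or accept) cohorts, run the full per-cohort and cross-cohort
    analysis, and optionally write the report bundle."""
    datasets = simulate_all(config)
    panel = config.panel()

    cohort_results: dict[str, CohortResult] = {}
    grs_frames = []
    genotypes_by_cohort: dict[str, GenotypeMatrix] = {}
    qc_reports = {}
    for name, ds in datasets.items():
        gmat = ds.genotypes
        if qc:
            controls = list(ds.control_ids)
            gmat, report = qc_genotypes(gmat, controls=controls)
            qc_reports[name] = report
        genotypes_by_cohort[name] = gmat
        cohort_panel = panel.subset([r for r in panel.rsids if r in set(gmat.rsids)])
        grs = compute_grs(gmat, cohort_panel, missing_policy=missing_policy)
        status = ds.phenotypes.set_index("sample_id")["status"]
        grs_frames.append(grs.to_frame(cohort=name,
                                       status=[status.get(s, "NA") for s in grs.sample_ids]))
        cohort_results[name] = analyze_cohort(name, ds.phenotypes, grs, J_max=J_max)
    grs_all = pd.concat(grs_frames, ignore_index=True)

    selections = {name: select_extreme_clusters(res, alpha=alpha)
                  for name, res in cohort_results.items()}
    contrast = combine_groups(list(cohort_results.values()), selections)
    contrast = contrast_extremes(genotypes_by_cohort, contrast, panel)
    phenos = pd.concat([ds.phenotypes for ds in datasets.values()], ignore_index=True)
    contrast.summary = combined_summary(contrast, phenos, grs_all)

    manifest = {
        "seed": config.seed,
        "mode": config.mode,
        "alpha": alpha,
        "J_max": J_max,
        "config_digest": hashlib.sha256(
            json.dumps(config_to_dict(config), sort_keys=True).encode()).hexdigest(),
        "cohorts": {
            name: {
                "n_cases_clustered": int(len(res.assignments)),
                "n_deleted": res.n_deleted,
                "k": res.model.k,
                "hi": sorted(selections[name][0]),
                "lo": sorted(selections[name][1]),
            }
            for name, res in cohort_results.items()
        },
        "group_sizes": {str(g): int(n) for g, n in
                        sorted(contrast.group_sizes().items())},
    }
    result = RunResult(cohort_results=cohort_results, contrast=contrast,
                       datasets=datasets, manifest=manifest)
    if out_dir is not None:
        write_reports(result, grs_all, Path(out_dir))
    return result


def write_reports(result: RunResult, grs_all: pd.DataFrame, out_dir: Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    grs_all.to_csv(out_dir / "grs.tsv", sep="\t", index=False, na_rep="NA")
    for name, res in result.cohort_results.items():
        res.assignments.to_csv(out_dir / f"clusters_{name}.tsv", sep="\t", index=False)
        res.cluster_grs.to_csv(out_dir / f"cluster_grs_{name}.tsv", sep="\t", index=False)
        if res.tukey is not None:
            res.tukey.pairs.to_csv(out_dir / f"tukey_{name}.tsv", sep="\t", index=False)
        model_json = {
            "k": res.model.k,
            "bic_trace": {str(k): v for k, v in sorted(res.model.bic_trace.items())},
            "merge_distances": {str(k): v for k, v in
                                sorted(res.model.merge_distances.items())},
            "selection": {k: v for k, v in res.model.selection.items()
                          if not isinstance(v, dict)},
        }
        (out_dir / f"model_{name}.json").write_text(json.dumps(model_json, indent=2))
    c = result.contrast
    c.membership.to_csv(out_dir / "groups.tsv", sep="\t", index=False)
    if c.per_snp is not None:
        c.per_snp.to_csv(out_dir / "assoc_per_cohort.tsv", sep="\t", index=False)
    if c.meta is not None:
        c.meta.to_csv(out_dir / "assoc_meta.tsv", sep="\t", index=False)
    if c.summary is not None:
        c.summary.to_csv(out_dir / "combined_summary.tsv", sep="\t", index=False,
                         na_rep="NA")
    (out_dir / "manifest.json").write_text(json.dumps(result.manifest, indent=2,
                                                      sort_keys=True))
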