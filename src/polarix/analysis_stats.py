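"""The statistical surface: binned summaries, ECDFs, stratified
correlations, group tests, SNP-vs-background contrasts and the age x DAF
corner classification.

Conventions: all tests are two-sided with raw (uncorrected) p-values;
"t-test" means Welch's unequal-variance test; the Wilcoxon rank-sum test
is the Mann-Whitney U test (as in R's ``wilcox.test``); the ECDF is the
right-continuous step function with jumps i/n at tied observations (as in
R's ``ecdf``).
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.distributions.empirical_distribution import ECDF as _ECDF

from .io_formats import PipelineConfig

__all__ = [
    "BinnedSummary",
    "CornerLabel",
    "CORNER_LABELS",
    "binned_summary",
    "ecdf",
    "stratified_correlation",
    "group_compare",
    "snp_vs_background",
    "classify_age_corners",
    "run_full_analysis",
]

CORNER_LABELS = ("quick_running", "slow_running", "old_high", "young_low", "interior")


class SchemaError(KeyError):
    """A required column is missing from an input table."""


@dataclass(frozen=True)
class BinnedSummary:
    metric: str
    table: pd.DataFrame  # columns: bin, n, mean, sem

    def mean_of(self, bin_idx: int) -> float:
        row = self.table.loc[self.table["bin"] == bin_idx]
        return float(row["mean"].iloc[0]) if len(row) else float("nan")


def binned_summary(
    values: Sequence[float] | np.ndarray,
    bins: Sequence[int] | np.ndarray,
    metric: str = "metric",
    all_bins: Sequence[int] = range(1, 9),
) -> BinnedSummary:
    """Per-bin n, mean and standard error of the mean.

    Bins with no observations are omitted (missing, not zero); a single
    observation gives an undefined (NaN) SEM.
    """
    values = np.asarray(values, dtype=float)
    bins_arr = np.asarray(bins, dtype=int)
    if values.shape != bins_arr.shape:
        raise ValueError("values and bins must align")
    if values.size and not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    rows = []
    for b in all_bins:
        sel = values[bins_arr == b]
        if sel.size == 0:
            continue
        sem = float(np.std(sel, ddof=1) / np.sqrt(sel.size)) if sel.size > 1 else np.nan
        rows.append({"bin": int(b), "n": int(sel.size), "mean": float(sel.mean()), "sem": sem})
    return BinnedSummary(metric=metric, table=pd.DataFrame(rows, columns=["bin", "n", "mean", "sem"]))


def ecdf(values: Sequence[float] | np.ndarray):
    """Right-continuous empirical CDF, F(x) = #{v <= x} / n."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("ecdf of an empty sample is undefined")
    return _ECDF(values, side="right")


def stratified_correlation(
    maf: np.ndarray,
    score: np.ndarray,
    minor_is_derived: np.ndarray,
    daf: np.ndarray | None = None,
    method: str = "spearman",
) -> pd.DataFrame:
    """Rank correlation of (MAF, score) per ancestry stratum, plus pooled DAF.

    Rows: stratum in {derived_minor, ancestral_minor, pooled_daf} with
    (n, rho, p). The opposite correlation signs of the two MAF strata for
    any DAF-monotone score follow from MAF = DAF vs MAF = 1 - DAF.
    """
    if method != "spearman":
        raise ValueError("only Spearman rank correlation is supported")
    maf = np.asarray(maf, float)
    score = np.asarray(score, float)
    flag = np.asarray(minor_is_derived, bool)
    rows = []
    for name, sel_x, sel_y in (
        ("derived_minor", maf[flag], score[flag]),
        ("ancestral_minor", maf[~flag], score[~flag]),
    ):
        if sel_x.size < 10:
            raise ValueError(f"stratum {name} has fewer than 10 pairs")
        if np.ptp(sel_x) == 0 or np.ptp(sel_y) == 0:
            raise ValueError(f"stratum {name}: constant input, correlation undefined")
        rho, p = stats.spearmanr(sel_x, sel_y)
        rows.append({"stratum": name, "n": int(sel_x.size), "rho": float(rho), "p": float(p)})
    if daf is not None:
        daf = np.asarray(daf, float)
        rho, p = stats.spearmanr(daf, score)
        rows.append({"stratum": "pooled_daf", "n": int(daf.size), "rho": float(rho), "p": float(p)})
    return pd.DataFrame(rows, columns=["stratum", "n", "rho", "p"])


def _direction(a: np.ndarray, b: np.ndarray, use_median: bool) -> str:
    fa = np.median(a) if use_median else np.mean(a)
    fb = np.median(b) if use_median else np.mean(b)
    if fa > fb:
        return "group_true_higher"
    if fa < fb:
        return "group_true_lower"
    return "none"


def group_compare(
    values: np.ndarray,
    group_flag: np.ndarray,
    test: str = "wilcoxon",
) -> tuple[float, float, str]:
    """Two-sided two-group test: (statistic, p, direction of True group)."""
    values = np.asarray(values, float)
    flag = np.asarray(group_flag, bool)
    a, b = values[flag], values[~flag]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if test == "wilcoxon":
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        return float(stat), float(p), _direction(a, b, use_median=True)
    if test == "t":
        if a.size < 2 or b.size < 2:
            raise ValueError("t-test requires >= 2 observations per group")
        stat, p = stats.ttest_ind(a, b, equal_var=False)
        return float(stat), float(p), _direction(a, b, use_median=False)
    raise ValueError(f"unknown test {test!r}")


def snp_vs_background(
    snp_values: np.ndarray, background_values: np.ndarray
) -> dict[str, float]:
    """Welch contrast of a metric between observed SNPs and the random
    background; the difference is reported background-minus-SNP."""
    a = np.asarray(snp_values, float)
    b = np.asarray(background_values, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples must have >= 2 observations")
    t, p = stats.ttest_ind(b, a, equal_var=False)
    return {
        "snp_mean": float(a.mean()),
        "background_mean": float(b.mean()),
        "background_minus_snp": float(b.mean() - a.mean()),
        "t": float(t),
        "p": float(p),
        "n_snp": int(a.size),
        "n_background": int(b.size),
    }


def classify_age_corners(
    age_ky: float | None,
    daf: float,
    age_young_ky: float = 300.0,
    age_old_ky: float = 700.0,
    daf_high: float = 0.8,
    daf_low: float = 0.2,
) -> str | None:
    """Corner of the age x DAF plane (strict inequalities at all edges).

    quick_running: young but already at high DAF; slow_running: old yet
    still rare. Missing age returns None (excluded from corner analyses).
    """
    if age_ky is None or (isinstance(age_ky, float) and np.isnan(age_ky)):
        return None
    if not 0.0 < daf < 1.0:
        raise ValueError(f"daf must be in (0,1), got {daf}")
    if age_ky < 0:
        raise ValueError("age must be >= 0")
    young, old = age_ky < age_young_ky, age_ky > age_old_ky
    high, low = daf > daf_high, daf < daf_low
    if young and high:
        return "quick_running"
    if old and low:
        return "slow_running"
    if old and high:
        return "old_high"
    if young and low:
        return "young_low"
    return "interior"


# ---------------------------------------------------------------------------
# full report bundle


_PROTEIN_METRICS = ("grantham", "hydrophobicity_delta", "blosum62")
_STRUCT_METRICS = ("rel_entropy", "mfe_gap", "bpp_distance")


def _require(df: pd.DataFrame, cols: Sequence[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing required column(s) {missing}")


def _metric_bin_table(
    df: pd.DataFrame,
    metrics: Sequence[str],
    background: pd.DataFrame | None,
) -> pd.DataFrame:
    rows = []
    for metric in metrics:
        if metric not in df.columns:
            continue
        sub = df.dropna(subset=[metric])
        bs = binned_summary(sub[metric].to_numpy(), sub["daf_bin"].to_numpy(), metric)
        for r in bs.table.itertuples(index=False):
            rows.append(
                {"metric": metric, "kind": "bin", "key": str(r.bin),
                 "n": r.n, "value": r.mean, "sem": r.sem, "stat": np.nan, "p": np.nan}
            )
        if background is not None and metric in background.columns:
            bg = background[metric].dropna().to_numpy()
            if bg.size >= 2 and len(sub) >= 2:
                res = snp_vs_background(sub[metric].to_numpy(), bg)
                rows.append(
                    {"metric": metric, "kind": "background_mean", "key": "all",
                     "n": res["n_background"], "value": res["background_mean"],
                     "sem": np.nan, "stat": np.nan, "p": np.nan}
                )
                rows.append(
                    {"metric": metric, "kind": "snp_vs_background",
                     "key": "background_minus_snp", "n": res["n_snp"],
                     "value": res["background_minus_snp"], "sem": np.nan,
                     "stat": res["t"], "p": res["p"]}
                )
        # high-DAF (bins 7-8) vs the rest
        hi = sub.loc[sub["daf_bin"] >= 7, metric].to_numpy()
        lo = sub.loc[sub["daf_bin"] <= 6, metric].to_numpy()
        if hi.size >= 2 and lo.size >= 2:
            t, p = stats.ttest_ind(hi, lo, equal_var=False)
            rows.append(
                {"metric": metric, "kind": "bins78_vs_16", "key": "mean_diff",
                 "n": int(hi.size), "value": float(hi.mean() - lo.mean()),
                 "sem": np.nan, "stat": float(t), "p": float(p)}
            )
    return pd.DataFrame(
        rows, columns=["metric", "kind", "key", "n", "value", "sem", "stat", "p"]
    )


def run_full_analysis(
    cohort: pd.DataFrame,
    background: pd.DataFrame | None = None,
    config: PipelineConfig | None = None,
) -> "OrderedDict[str, pd.DataFrame]":
    """Assemble the six result tables from a scored, annotated cohort.

    Expects the scored-cohort schema (maf/daf/minor_is_derived/site_class/
    daf_bin plus whatever metric and annotation columns were computed) and
    an optionally scored background table. Output order and content are
    deterministic given the inputs.
    """
    config = config or PipelineConfig()
    _require(cohort, ["maf", "daf", "minor_is_derived", "site_class", "daf_bin"], "cohort")
    tables: OrderedDict[str, pd.DataFrame] = OrderedDict()

    # (1) MAF-stratified correlations for every score column
    score_cols = [c for c in cohort.columns if c.startswith("score_") or c == "cons_score"]
    corr_rows = []
    for col in score_cols:
        sub = cohort.dropna(subset=[col])
        try:
            t = stratified_correlation(
                sub["maf"].to_numpy(), sub[col].to_numpy(),
                sub["minor_is_derived"].to_numpy(), sub["daf"].to_numpy(),
            )
        except ValueError:
            continue
        t.insert(0, "score", col)
        corr_rows.append(t)
    tables["score_correlations"] = (
        pd.concat(corr_rows, ignore_index=True)
        if corr_rows
        else pd.DataFrame(columns=["score", "stratum", "n", "rho", "p"])
    )

    # (2) protein metrics vs DAF (nonsynonymous only) + omega split
    nonsyn = cohort.loc[cohort["site_class"] == "nonsyn"]
    bg_nonsyn = (
        background.loc[background["site_class"] == "nonsyn"]
        if background is not None and "site_class" in getattr(background, "columns", [])
        else None
    )
    prot = _metric_bin_table(nonsyn, _PROTEIN_METRICS, bg_nonsyn)
    omega_rows = []
    if "omega_mouse" in nonsyn.columns:
        sub = nonsyn.dropna(subset=["omega_mouse"])
        if len(sub) >= 4:
            cutoff = float(sub["omega_mouse"].median())
            flag = (sub["omega_mouse"] > cutoff).to_numpy()
            for metric in _PROTEIN_METRICS:
                if metric not in sub.columns:
                    continue
                vals = sub.dropna(subset=[metric])
                f = (vals["omega_mouse"] > cutoff).to_numpy()
                if f.sum() >= 2 and (~f).sum() >= 2:
                    t, p, direction = group_compare(vals[metric].to_numpy(), f, test="t")
                    omega_rows.append(
                        {"metric": metric, "kind": "omega_split",
                         "key": f"median_cutoff={cutoff:.6g}", "n": int(len(vals)),
                         "value": float(vals.loc[f, metric].mean() - vals.loc[~f, metric].mean()),
                         "sem": np.nan, "stat": t, "p": p}
                    )
    if omega_rows:
        prot = pd.concat(
            [prot, pd.DataFrame(omega_rows, columns=prot.columns)], ignore_index=True
        )
    tables["protein_effects_by_daf"] = prot

    # (3) structural metrics vs DAF + regional structure contrasts
    struct = _metric_bin_table(cohort, _STRUCT_METRICS, background)
    contrast_rows = []
    if "rel_entropy" in cohort.columns:
        sub = cohort.dropna(subset=["rel_entropy"])
        for name, f1, f2 in (
            ("utr5_vs_utr3", sub["site_class"] == "utr5", sub["site_class"] == "utr3"),
            ("nonsyn_vs_syn", sub["site_class"] == "nonsyn", sub["site_class"] == "syn"),
        ):
            a = sub.loc[f1, "rel_entropy"].to_numpy()
            b = sub.loc[f2, "rel_entropy"].to_numpy()
            if a.size >= 2 and b.size >= 2:
                t, p = stats.ttest_ind(a, b, equal_var=False)
                contrast_rows.append(
                    {"metric": "rel_entropy", "kind": name, "key": "mean_diff",
                     "n": int(a.size + b.size), "value": float(a.mean() - b.mean()),
                     "sem": np.nan, "stat": float(t), "p": float(p)}
                )
    if contrast_rows:
        struct = pd.concat(
            [struct, pd.DataFrame(contrast_rows, columns=struct.columns)],
            ignore_index=True,
        )
    tables["structure_effects_by_daf"] = struct

    # (4) |dO_codon| vs DAF (synonymous only)
    syn = cohort.loc[cohort["site_class"] == "syn"]
    bg_syn = (
        background.loc[background["site_class"] == "syn"]
        if background is not None and "site_class" in getattr(background, "columns", [])
        else None
    )
    tables["codon_optimality_by_daf"] = _metric_bin_table(
        syn, ("delta_codon_optimality",), bg_syn
    )

    # (5) regional DAF ECDFs and comparisons
    grid = [0.001, 0.01, 0.1, 0.2, 0.5, 0.8, 0.9, 0.99, 0.999]
    reg_rows = []

    def add_group(group_type: str, name: str, daf_values: np.ndarray) -> None:
        if daf_values.size == 0:
            return
        F = ecdf(daf_values)
        reg_rows.append(
            {"group_type": group_type, "group": name, "kind": "summary",
             "x": np.nan, "n": int(daf_values.size),
             "value": float(np.median(daf_values)), "stat": np.nan, "p": np.nan}
        )
        for x in grid:
            reg_rows.append(
                {"group_type": group_type, "group": name, "kind": "ecdf",
                 "x": x, "n": int(daf_values.size), "value": float(F(x)),
                 "stat": np.nan, "p": np.nan}
            )

    def add_compare(group_type: str, name: str, flag: np.ndarray, daf: np.ndarray) -> None:
        if flag.sum() == 0 or (~flag).sum() == 0:
            return
        stat, p, direction = group_compare(daf, flag, test="wilcoxon")
        reg_rows.append(
            {"group_type": group_type, "group": name, "kind": "wilcoxon",
             "x": np.nan, "n": int(daf.size),
             "value": float(np.median(daf[flag]) - np.median(daf[~flag])),
             "stat": stat, "p": p}
        )

    for sc in ("utr5", "utr3", "syn", "nonsyn"):
        add_group("site_class", sc, cohort.loc[cohort["site_class"] == sc, "daf"].to_numpy())
    cds_like = cohort["site_class"].isin(["syn", "nonsyn", "nonsense"])
    add_compare("site_class", "nonsyn_vs_syn",
                (cohort.loc[cohort["site_class"].isin(["syn", "nonsyn"]), "site_class"] == "nonsyn").to_numpy(),
                cohort.loc[cohort["site_class"].isin(["syn", "nonsyn"]), "daf"].to_numpy())
    add_compare("site_class", "utr3_vs_utr5",
                (cohort.loc[cohort["site_class"].isin(["utr5", "utr3"]), "site_class"] == "utr3").to_numpy(),
                cohort.loc[cohort["site_class"].isin(["utr5", "utr3"]), "daf"].to_numpy())
    utr5 = cohort.loc[cohort["site_class"] == "utr5"]
    add_group("tis", "tis", utr5.loc[utr5["in_tis"], "daf"].to_numpy())
    add_compare("tis", "tis_vs_non_tis", utr5["in_tis"].to_numpy(), utr5["daf"].to_numpy())
    add_group("ss", "ss", cohort.loc[cohort["in_ss"], "daf"].to_numpy())
    add_compare("ss", "ss_vs_non_ss", cohort["in_ss"].to_numpy(), cohort["daf"].to_numpy())
    for col in ("essential", "mendelian"):
        if col in cohort.columns:
            sub = cohort.dropna(subset=[col])
            flag = sub[col].astype(bool).to_numpy()
            add_group("gene_category", col, sub.loc[flag, "daf"].to_numpy())
            add_compare("gene_category", f"{col}_vs_not", flag, sub["daf"].to_numpy())
    tables["regional_daf"] = pd.DataFrame(
        reg_rows, columns=["group_type", "group", "kind", "x", "n", "value", "stat", "p"]
    )

    # (6) age x DAF corner table with per-corner score comparisons
    corner_rows = []
    if "age_ky" in cohort.columns:
        sub = cohort.dropna(subset=["age_ky"])
        labels = np.array(
            [
                classify_age_corners(
                    a, d, config.age_young_ky, config.age_old_ky,
                    config.daf_high, config.daf_low,
                )
                for a, d in zip(sub["age_ky"], sub["daf"])
            ],
            dtype=object,
        )
        for lab in CORNER_LABELS:
            n = int((labels == lab).sum())
            corner_rows.append(
                {"kind": "count", "corner_a": lab, "corner_b": "", "score": "",
                 "n": n, "value": float(n), "stat": np.nan, "p": np.nan}
            )
        corners_only = [l for l in CORNER_LABELS if l != "interior"]
        for col in score_cols:
            vals = sub[col].to_numpy(dtype=float)
            for lab in corners_only:
                v = vals[labels == lab]
                if v.size:
                    corner_rows.append(
                        {"kind": "corner_mean", "corner_a": lab, "corner_b": "",
                         "score": col, "n": int(v.size), "value": float(v.mean()),
                         "stat": np.nan, "p": np.nan}
                    )
            for i, la in enumerate(corners_only):
                for lb in corners_only[i + 1 :]:
                    va, vb = vals[labels == la], vals[labels == lb]
                    if va.size >= 2 and vb.size >= 2:
                        t, p = stats.ttest_ind(va, vb, equal_var=False)
                        corner_rows.append(
                            {"kind": "welch", "corner_a": la, "corner_b": lb,
                             "score": col, "n": int(va.size + vb.size),
                             "value": float(va.mean() - vb.mean()),
                             "stat": float(t), "p": float(p)}
                        )
    tables["age_daf_corners"] = pd.DataFrame(
        corner_rows,
        columns=["kind", "corner_a", "corner_b", "score", "n", "value", "stat", "p"],
    )
    return tables
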