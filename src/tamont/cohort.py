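"""Bulk-cohort analysis: ontogeny scores, subtype comparison, survival.

Each bulk sample is scored with the lineage signature by averaging the
log-scale expression of the blood-derived and microglial signature genes
separately, then z-scoring each score across the cohort. Scores are
compared across glioma subtypes with Tukey's range test, and survival is
analyzed by splitting the cohort at the median score and fitting a Cox
proportional-hazards model of the high-vs-low stratum adjusted for age and
gender (Efron tie handling).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats

from .compare import bh_adjust
from .simulate import BLOOD, MICROGLIA


@dataclass
class OntogenyScore:
    """Per-sample signature scores (raw means and cohort z-scores)."""

    scores: pd.DataFrame  # columns: blood, microglia, blood_z, microglia_z
    missing_genes: dict[str, list[str]]

    def z(self, lineage: str) -> pd.Series:
        return self.scores[f"{lineage}_z"]


def ontogeny_score(expr: pd.DataFrame, signature) -> OntogenyScore:
    """Average the expression of each lineage's signature genes per sample.

    ``expr`` is samples x genes on a log scale; ``signature`` is a
    SignatureGeneSet or a frame with ``gene``/``lineage`` columns. Signature
    genes absent from the cohort are logged per lineage; an error is raised
    only when no signature gene overlaps the cohort at all.
    """
    entries = signature.as_frame() if hasattr(signature, "as_frame") else signature
    if not set(entries.gene) & set(expr.columns):
        raise ValueError(
            f"no signature gene present in cohort; missing: {sorted(entries.gene)}"
        )
    missing: dict[str, list[str]] = {}
    cols = {}
    for lineage in (BLOOD, MICROGLIA):
        genes = list(entries.gene[entries.lineage == lineage])
        present = [g for g in genes if g in expr.columns]
        missing[lineage] = sorted(set(genes) - set(present))
        cols[lineage] = expr[present].mean(axis=1) if present else pd.Series(np.nan, index=expr.index)
    if any(missing[ln] for ln in missing):
        warnings.warn(f"signature genes missing from cohort: {missing}")
    out = pd.DataFrame({BLOOD: cols[BLOOD], MICROGLIA: cols[MICROGLIA]})
    for lineage in (BLOOD, MICROGLIA):
        v = out[lineage]
        sd = v.std(ddof=0)
        out[f"{lineage}_z"] = (v - v.mean()) / (sd if sd > 0 else 1.0)
    return OntogenyScore(scores=out, missing_genes=missing)


def subtype_comparison(scores: pd.Series, subtypes) -> pd.DataFrame:
    """Tukey's range test (HSD) of a score across subtype groups.

    Returns one row per group pair with the mean difference, the
    studentized-range statistic, and the range-distribution adjusted p.
    """
    s = pd.Series(np.asarray(scores, float), index=scores.index)
    g = pd.Series(np.asarray(subtypes), index=scores.index)
    levels = list(pd.unique(g))
    if len(levels) < 2:
        raise ValueError("need at least two subtype groups")
    groups = [s[g == lv].to_numpy() for lv in levels]
    if any(len(x) < 2 for x in groups):
        raise ValueError("each subtype group needs at least 2 samples")
    res = stats.tukey_hsd(*groups)
    n_tot = sum(len(x) for x in groups)
    df_w = n_tot - len(levels)
    ms_w = sum(((x - x.mean()) ** 2).sum() for x in groups) / df_w
    rows = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            diff = groups[i].mean() - groups[j].mean()
            se = np.sqrt(ms_w / 2.0 * (1.0 / len(groups[i]) + 1.0 / len(groups[j])))
            rows.append(
                {
                    "group1": levels[i],
                    "group2": levels[j],
                    "mean_diff": diff,
                    "q_stat": abs(diff) / se if se > 0 else np.inf,
                    "padj": float(res.pvalue[i, j]),
                }
            )
    return pd.DataFrame(rows)


def median_split(scores: pd.Series) -> pd.Series:
    """Binary strata at the median: 'high' strictly above, ties go low."""
    s = pd.Series(np.asarray(scores, float), index=scores.index)
    if len(s) < 2:
        raise ValueError("need at least 2 samples to split")
    med = float(s.median())
    if (s == s.iloc[0]).all():
        raise ValueError("all scores identical; no median split exists")
    return pd.Series(np.where(s > med, "high", "low"), index=s.index, name="stratum")


@dataclass
class CoxResult:
    """Median-split Cox proportional-hazards fit."""

    hazard_ratio: float
    log_hr: float
    log_hr_se: float
    p: float
    ci_low: float  # 95% CI on the hazard ratio
    ci_high: float
    covariate_coefs: pd.Series
    n_per_stratum: dict[str, int]
    km_curves: dict[str, pd.DataFrame]  # stratum -> step table (time, survival)


def cox_survival(
    clinical: pd.DataFrame,
    strata: pd.Series,
    covariates: tuple[str, ...] = ("age", "gender"),
) -> CoxResult:
    """Cox model of high-vs-low stratum membership, adjusted for covariates.

    ``clinical`` needs ``time`` and ``event`` columns plus any requested
    covariates; gender is encoded as an indicator for 'male' (reference
    level: female). The partial likelihood uses Efron tie handling. Also
    emits Kaplan-Meier step tables per stratum.
    """
    df = clinical.loc[strata.index, ["time", "event", *covariates]].copy()
    if (df.time <= 0).any():
        raise ValueError("survival times must be positive")
    df["high"] = (pd.Series(strata, index=df.index) == "high").astype(float)
    for stratum in ("high", "low"):
        mask = strata == stratum
        if df.loc[mask.to_numpy(), "event"].sum() < 1:
            raise ValueError(f"stratum {stratum!r} has no events; Cox fit unidentifiable")
    if "gender" in df.columns:
        df["gender"] = (df.gender.astype(str) == "male").astype(float)

    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event", show_progress=False)
    coef = float(cph.params_["high"])
    se = float(cph.standard_errors_["high"])
    p = float(cph.summary.loc["high", "p"])
    covs = cph.params_.drop("high")

    km = {}
    kmf = KaplanMeierFitter()
    for stratum in ("high", "low"):
        mask = (strata == stratum).to_numpy()
        kmf.fit(df.time[mask], df.event[mask], label=stratum)
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        km[stratum] = sf
    return CoxResult(
        hazard_ratio=float(np.exp(coef)),
        log_hr=coef,
        log_hr_se=se,
        p=p,
        ci_low=float(np.exp(coef - 1.959963984540054 * se)),
        ci_high=float(np.exp(coef + 1.959963984540054 * se)),
        covariate_coefs=covs,
        n_per_stratum={
            "high": int((strata == "high").sum()),
            "low": int((strata == "low").sum()),
        },
        km_curves=km,
    )


def survival_by_signature(
    expr: pd.DataFrame,
    clinical: pd.DataFrame,
    signature,
    lineage: str = BLOOD,
    covariates: tuple[str, ...] = ("age", "gender"),
) -> CoxResult:
    """Score a cohort, median-split on one lineage's z-score, and fit the
    adjusted Cox model — the full bulk survival analysis in one call."""
    score = ontogeny_score(expr, signature).z(lineage)
    strata = median_split(score)
    return cox_survival(clinical, strata, covariates=covariates)
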