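"""Clinical association tests for module scores and module genes.

Survival: a multiple Cox proportional-hazards regression of overall survival
on all module scores jointly (Efron tie handling), and Kaplan-Meier curves
with a log-rank test for a single score split at its median. Response:
RECIST categories are collapsed to CR/PR vs SD vs PD (NE patients removed),
module scores are tested across groups by Kruskal-Wallis, and individual
module genes by two-sample Wilcoxon rank-sum with Benjamini-Hochberg FDR
control across the module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import DifferenceMatrix


@dataclass
class SurvivalFit:
    """Hazard ratios with 95% CIs and Wald p-values from a Cox fit."""

    summary: pd.DataFrame  # index covariate; columns hr, ci_lower, ci_upper, p, coef, se
    n: int
    n_events: int
    log_likelihood: float

    def hazard_ratio(self, covariate) -> float:
        return float(self.summary.loc[covariate, "hr"])


def _align_clinical(scores: pd.DataFrame | pd.Series, clinical: pd.DataFrame):
    patients = [p for p in (scores.index if hasattr(scores, "index") else []) if p in clinical.index]
    if not patients:
        raise ValueError("no overlap between score patients and clinical table")
    return patients


def cox_multiple(scores: pd.DataFrame, clinical: pd.DataFrame) -> SurvivalFit:
    """Multiple Cox regression of survival on all module scores jointly.

    ``scores`` is patient x module; ``clinical`` supplies ``os_time`` and
    ``os_event`` indexed by patient. Ties are handled by Efron's method
    (lifelines default). Errors on zero events.
    """
    patients = _align_clinical(scores, clinical)
    df = scores.loc[patients].copy()
    df.columns = [f"module_{c}" for c in df.columns]
    df["os_time"] = clinical.loc[patients, "os_time"].astype(float)
    df["os_event"] = clinical.loc[patients, "os_event"].astype(int)
    if df["os_event"].sum() == 0:
        raise ValueError("no events observed; Cox model is not identifiable")
    cph = CoxPHFitter()
    cph.fit(df, duration_col="os_time", event_col="os_event")
    s = cph.summary
    summary = pd.DataFrame(
        {
            "coef": s["coef"],
            "se": s["se(coef)"],
            "hr": s["exp(coef)"],
            "ci_lower": s["exp(coef) lower 95%"],
            "ci_upper": s["exp(coef) upper 95%"],
            "p": s["p"],
        }
    )
    return SurvivalFit(
        summary=summary,
        n=len(df),
        n_events=int(df["os_event"].sum()),
        log_likelihood=float(cph.log_likelihood_),
    )


@dataclass
class KMResult:
    p_value: float
    statistic: float
    groups: pd.Series  # patient -> "low"/"high"
    fitters: dict  # group -> fitted KaplanMeierFitter


def km_logrank(score: pd.Series, clinical: pd.DataFrame, split: str = "median") -> KMResult:
    """Kaplan-Meier curves and log-rank test for a median split of one score."""
    patients = _align_clinical(score, clinical)
    s = score.loc[patients].astype(float)
    if split != "median":
        raise ValueError("only the median split is supported")
    cut = s.median()
    groups = pd.Series(np.where(s > cut, "high", "low"), index=s.index, name="group")
    if groups.nunique() < 2:
        raise ValueError("degenerate split: all scores on one side of the median")
    t = clinical.loc[patients, "os_time"].astype(float)
    e = clinical.loc[patients, "os_event"].astype(int)
    hi = groups == "high"
    res = logrank_test(t[hi], t[~hi], event_observed_A=e[hi], event_observed_B=e[~hi])
    fitters = {}
    for name, mask in (("high", hi), ("low", ~hi)):
        kmf = KaplanMeierFitter()
        kmf.fit(t[mask], e[mask], label=name)
        fitters[name] = kmf
    return KMResult(
        p_value=float(res.p_value),
        statistic=float(res.test_statistic),
        groups=groups,
        fitters=fitters,
    )


def response_groups(clinical: pd.DataFrame) -> pd.Series:
    """Collapse RECIST categories to CR/PR, SD, PD; drop NE patients."""
    resp = clinical["response"]
    keep = resp != "NE"
    collapsed = resp[keep].replace({"CR": "CR/PR", "PR": "CR/PR"})
    return collapsed


def kruskal_wallis(score: pd.Series, groups: pd.Series) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p across response groups."""
    common = [p for p in score.index if p in groups.index]
    g = groups.loc[common]
    samples = [score.loc[g.index[g == lvl]].to_numpy() for lvl in sorted(g.unique())]
    samples = [s for s in samples if len(s) > 0]
    if len(samples) < 2:
        raise ValueError("Kruskal-Wallis needs at least two nonempty groups")
    if len(np.unique(np.concatenate(samples))) == 1:
        return 0.0, 1.0  # every observation tied: no rank variation at all
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


def wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sample Wilcoxon (Mann-Whitney) test.

    Exact distribution for combined n <= 20 without ties; otherwise the
    normal approximation with continuity and tie corrections.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    exact = len(pooled) <= 20 and len(np.unique(pooled)) == len(pooled)
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.statistic), float(res.pvalue)


def per_gene_response_test(
    scaled_diff: DifferenceMatrix,
    module_genes,
    groups: pd.Series,
    group_a: str = "CR/PR",
    group_b: str = "PD",
) -> pd.DataFrame:
    """Per-gene Wilcoxon comparison of expression change between two response groups.

    Returns group means, the rank-sum statistic, raw p and BH-adjusted FDR
    (adjusted across the module's genes only).
    """
    pa = [p for p in scaled_diff.patient_ids if groups.get(p) == group_a]
    pb = [p for p in scaled_diff.patient_ids if groups.get(p) == group_b]
    if not pa or not pb:
        raise ValueError(f"empty comparison group: {group_a}={len(pa)}, {group_b}={len(pb)}")
    rows = []
    for gene in module_genes:
        xa = scaled_diff.values.loc[gene, pa].to_numpy(float)
        xb = scaled_diff.values.loc[gene, pb].to_numpy(float)
        u, p = wilcoxon_rank_sum(xa, xb)
        rows.append(
            {
                "gene": gene,
                f"mean_{group_a.replace('/', '_')}": xa.mean(),
                f"mean_{group_b}": xb.mean(),
                "statistic": u,
                "p": p,
            }
        )
    table = pd.DataFrame(rows).set_index("gene")
    table["fdr"] = bh_adjust(table["p"].to_numpy())
    return table.sort_values("p")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotonicity enforced)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
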