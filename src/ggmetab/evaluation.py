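"""Distance-stratified evaluation of partial-correlation networks.

Given a fitted correlation result and a pathway distance matrix, each
applicable metabolite pair is assigned to a distance stratum (1, 2, ...,
inf).  A pair predicted positive (significantly positive partial correlation
by default) and lying at distance 1 is a true positive; sensitivity,
specificity and their harmonic mean F1 quantify how well partial
correlations separate direct from indirect pathway neighbours, alongside a
Wilcoxon rank-sum comparison of the two value distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ranksums

from .ggm import CorrelationResult

__all__ = [
    "ConfusionCounts",
    "ClassificationRates",
    "stratify_by_distance",
    "classify_edges",
    "sens_spec_f1",
    "ranksum_direct_vs_indirect",
    "pearson_vs_partial_summary",
    "evaluate",
]


def stratify_by_distance(result: CorrelationResult, distances: pd.DataFrame) -> pd.DataFrame:
    """Long table of applicable pairs with distance stratum and correlations.

    One row per unordered pair whose pathway distance is defined (NaN
    distances mark not-applicable pairs and are excluded).  Columns carry
    both correlation types, their p-values, and significance flags at the
    result's adjusted level.
    """
    ids = [m for m in result.metabolite_ids if m in distances.index]
    idx = {m: i for i, m in enumerate(result.metabolite_ids)}
    sig_pos = result.significant_partial("positive")
    sig_neg = result.significant_partial("negative")
    rows = []
    for a_pos, met_a in enumerate(ids):
        for met_b in ids[a_pos + 1:]:
            d = float(distances.loc[met_a, met_b])
            if math.isnan(d):
                continue
            i, j = idx[met_a], idx[met_b]
            rows.append(
                {
                    "met_a": met_a,
                    "met_b": met_b,
                    "distance": d,
                    "zeta": float(result.Z[i, j]),
                    "rho": float(result.P[i, j]),
                    "p_partial": float(result.p_partial[i, j]),
                    "p_pearson": float(result.p_pearson[i, j]),
                    "sig_partial_pos": bool(sig_pos[i, j]),
                    "sig_partial_neg": bool(sig_neg[i, j]),
                    "sig_pearson": bool(result.p_pearson[i, j] <= result.alpha_adj),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "met_a", "met_b", "distance", "zeta", "rho", "p_partial", "p_pearson",
            "sig_partial_pos", "sig_partial_neg", "sig_pearson",
        ],
    )


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int
    empty_strata: bool = False

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def classify_edges(table: pd.DataFrame, rule: str = "positive") -> ConfusionCounts:
    """Confusion counts of significant partial correlations vs distance 1.

    Condition positive = pathway distance exactly 1.  The default prediction
    rule counts significantly *positive* partial correlations as positive
    predictions (significant negatives count as negative predictions);
    ``rule="absolute"`` predicts positive for any significant value.
    """
    if rule == "positive":
        pred = table["sig_partial_pos"].to_numpy(dtype=bool)
    elif rule == "absolute":
        pred = (table["sig_partial_pos"] | table["sig_partial_neg"]).to_numpy(dtype=bool)
    else:
        raise ValueError("rule must be 'positive' or 'absolute'")
    direct = (table["distance"] == 1).to_numpy(dtype=bool)
    tp = int(np.sum(pred & direct))
    fp = int(np.sum(pred & ~direct))
    fn = int(np.sum(~pred & direct))
    tn = int(np.sum(~pred & ~direct))
    return ConfusionCounts(
        tp=tp, fp=fp, tn=tn, fn=fn, empty_strata=(not direct.any()) or direct.all()
    )


@dataclass(frozen=True)
class ClassificationRates:
    sensitivity: float | None
    specificity: float | None
    f1: float | None


def sens_spec_f1(confusion: ConfusionCounts) -> ClassificationRates:
    """sens = TP/(TP+FN), spec = TN/(TN+FP), F1 = harmonic mean of the two.

    A rate with a zero denominator is reported as None (undefined), never 0.
    """
    sens = confusion.tp / (confusion.tp + confusion.fn) if confusion.tp + confusion.fn else None
    spec = confusion.tn / (confusion.tn + confusion.fp) if confusion.tn + confusion.fp else None
    if sens is None or spec is None or sens + spec == 0:
        f1 = None
    else:
        f1 = 2.0 * sens * spec / (sens + spec)
    return ClassificationRates(sensitivity=sens, specificity=spec, f1=f1)


def ranksum_direct_vs_indirect(table: pd.DataFrame) -> float | None:
    """Two-sided Wilcoxon rank-sum p comparing zeta at distance 1 vs >= 2.

    Returns None (not applicable) when either group is empty.
    """
    direct = table.loc[table["distance"] == 1, "zeta"]
    indirect = table.loc[table["distance"] >= 2, "zeta"]
    if direct.empty or indirect.empty:
        return None
    return float(ranksums(direct, indirect).pvalue)


def pearson_vs_partial_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Counts and fractions of significant values per distance stratum.

    Compares the Pearson and the partial test side by side; empty strata
    report NaN fractions.  Partial significance here counts any sign (the
    histogram-style comparison), positives are reported separately.
    """
    tab = table.copy()
    tab["stratum"] = tab["distance"].map(lambda d: math.inf if math.isinf(d) else float(d))
    rows = []
    for stratum, grp in tab.groupby("stratum"):
        n = len(grp)
        n_pearson = int(grp["sig_pearson"].sum())
        n_partial = int((grp["sig_partial_pos"] | grp["sig_partial_neg"]).sum())
        n_partial_pos = int(grp["sig_partial_pos"].sum())
        rows.append(
            {
                "stratum": stratum,
                "n_pairs": n,
                "n_sig_pearson": n_pearson,
                "n_sig_partial": n_partial,
                "n_sig_partial_pos": n_partial_pos,
                "frac_sig_pearson": n_pearson / n if n else math.nan,
                "frac_sig_partial": n_partial / n if n else math.nan,
            }
        )
    return pd.DataFrame(rows).sort_values("stratum").reset_index(drop=True)


@dataclass
class EvaluationReport:
    table: pd.DataFrame
    confusion: ConfusionCounts
    rates: ClassificationRates
    ranksum_p: float | None
    per_stratum: pd.DataFrame


def evaluate(result: CorrelationResult, distances: pd.DataFrame, rule: str = "positive") -> EvaluationReport:
    """Full distance-stratified evaluation of a correlation result."""
    table = stratify_by_distance(result, distances)
    confusion = classify_edges(table, rule=rule)
    return EvaluationReport(
        table=table,
        confusion=confusion,
        rates=sens_spec_f1(confusion),
        ranksum_p=ranksum_direct_vs_indirect(table),
        per_stratum=pearson_vs_partial_summary(table),
    )
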