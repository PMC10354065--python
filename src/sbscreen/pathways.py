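"""Signature-based pathway activity scoring and compartment comparison.

Pathway activity per sample is the mean z-score of the signature's genes,
min-max rescaled to [0, 1] across the cohort so activity differences are on
a common heat-map scale.  Pathways are then compared between primary and
metastasis samples with an unpaired two-tailed Welch t-test (a paired test
is available for paired cohorts): a pathway is M-enriched when the
difference in mean activity (ΔMean = mean_met − mean_primary) exceeds the
robustness threshold (default 0.27) *and* the test is significant (default
alpha 1e-4); P-enriched symmetrically for ΔMean below −0.27; everything
else is shared.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

COMPARISON_COLUMNS = [
    "pathway_name",
    "n_genes_used",
    "mean_primary",
    "mean_met",
    "delta_mean",
    "p_value",
    "classification",
]


def score_signature(expression: pd.DataFrame, signature: list[str]) -> pd.Series:
    """Per-sample activity of one gene signature, rescaled to [0, 1].

    ``expression`` is genes x samples.  Each signature gene is z-scored
    across samples (a zero-variance gene contributes z = 0 everywhere), the
    per-sample mean z is taken over the signature genes present, and the
    result is min-max rescaled across the cohort; a degenerate cohort with
    no spread scores 0.5 everywhere by convention.
    """
    present = [g for g in signature if g in expression.index]
    if len(present) < 2 and len(signature) > 1:
        raise ValueError(
            f"fewer than 2 signature genes found in the matrix ({len(present)})"
        )
    if not present:
        raise ValueError("no signature genes found in the matrix")
    sub = expression.loc[present]
    mu = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=0)
    z = sub.sub(mu, axis=0).div(sd.where(sd > 0, np.inf), axis=0)
    raw = z.mean(axis=0)
    lo, hi = raw.min(), raw.max()
    if hi - lo == 0:
        return pd.Series(0.5, index=expression.columns, name="activity")
    return ((raw - lo) / (hi - lo)).rename("activity")


def score_signatures(
    expression: pd.DataFrame, signatures: Mapping[str, list[str]]
) -> pd.DataFrame:
    """Score every signature; skips (with a warning) unusable ones."""
    rows = {}
    for name, genes in signatures.items():
        present = [g for g in genes if g in expression.index]
        if len(present) < 2:
            logger.warning("skipping pathway %s: <2 signature genes in matrix", name)
            continue
        rows[name] = score_signature(expression, present)
    return pd.DataFrame(rows).T


def compare_pathways(
    activities: pd.DataFrame,
    labels: pd.Series,
    alpha: float = 1e-4,
    delta_threshold: float = 0.27,
    paired: bool = False,
) -> pd.DataFrame:
    """Classify each pathway as M-enriched, P-enriched, or shared.

    ``activities`` is pathways x samples; ``labels`` maps sample to
    "primary"/"metastasis".  Classification requires both significance
    (p < alpha, Welch unpaired two-tailed t-test by default, paired t-test
    when ``paired``) and robustness (|ΔMean| > delta_threshold).  A
    compartment with fewer than 2 samples yields an undefined p-value and a
    "shared" call flagged by ``p_value = NaN``.
    """
    labels = labels.reindex(activities.columns)
    is_met = (labels == "metastasis").to_numpy()
    is_prim = (labels == "primary").to_numpy()
    if is_met.sum() == 0 or is_prim.sum() == 0:
        raise ValueError("both compartments must be non-empty")
    rows = []
    for name, act in activities.iterrows():
        met = act.to_numpy()[is_met]
        prim = act.to_numpy()[is_prim]
        delta = float(met.mean() - prim.mean())
        if len(met) < 2 or len(prim) < 2:
            p_value = float("nan")
        elif paired:
            if len(met) != len(prim):
                raise ValueError("paired comparison needs equal group sizes")
            p_value = float(stats.ttest_rel(met, prim).pvalue)
        else:
            p_value = float(stats.ttest_ind(met, prim, equal_var=False).pvalue)
        if np.isfinite(p_value) and p_value < alpha and delta > delta_threshold:
            cls = "M-enriched"
        elif np.isfinite(p_value) and p_value < alpha and delta < -delta_threshold:
            cls = "P-enriched"
        else:
            cls = "shared"
        rows.append(
            {
                "pathway_name": name,
                "n_genes_used": np.nan,
                "mean_primary": float(prim.mean()),
                "mean_met": float(met.mean()),
                "delta_mean": delta,
                "p_value": p_value,
                "classification": cls,
            }
        )
    return pd.DataFrame(rows, columns=COMPARISON_COLUMNS)


def run_pathway_comparison(
    expression: pd.DataFrame,
    labels: pd.Series,
    signatures: Mapping[str, list[str]],
    alpha: float = 1e-4,
    delta_threshold: float = 0.27,
    paired: bool = False,
) -> pd.DataFrame:
    """Score signatures and compare compartments in one call."""
    activities = score_signatures(expression, signatures)
    result = compare_pathways(
        activities, labels, alpha=alpha, delta_threshold=delta_threshold, paired=paired
    )
    n_used = {
        name: sum(g in expression.index for g in genes)
        for name, genes in signatures.items()
    }
    result["n_genes_used"] = result["pathway_name"].map(n_used)
    return result
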