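"""Dynamic clonal/subclonal read-count filter for insertion libraries.

For each sequencing library, three data-driven thresholds are computed from
the per-site read counts:

1. the 95th percentile of a negative-binomial distribution fitted to the
   counts (method of moments; Poisson fallback when there is no
   overdispersion),
2. the read count at the top-1% abundance rank of the library's sites,
3. 0.1% of the library's total reads.

The most stringent (largest) of the three is the clonal cutoff and the
second-most stringent (the median) separates subclonal from discarded.  An
insertion with ``read_count >= clonal_cut`` is clonal; one with
``subclonal_cut <= read_count < clonal_cut`` is subclonal; the rest are
discarded.  "filtered_clonal" data keep the clonal class only;
"filtered_subclonal" keep clonal plus subclonal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CLASS_ORDER = {"discarded": 0, "subclonal": 1, "clonal": 2}


@dataclass(frozen=True)
class ClonalThresholds:
    """The three per-library thresholds and the derived cutoffs."""

    nb_q95: float
    top1pct: float
    frac_total: float

    @property
    def clonal_cut(self) -> float:
        return max(self.nb_q95, self.top1pct, self.frac_total)

    @property
    def subclonal_cut(self) -> float:
        return float(np.median([self.nb_q95, self.top1pct, self.frac_total]))


def fit_nb_q95(counts, q: float = 0.95) -> int:
    """Smallest integer count c with fitted-NB CDF(c) >= q.

    The negative binomial is fitted by method of moments (mean m, variance v,
    size r = m^2/(v-m)); with no overdispersion (v <= m, e.g. all counts
    identical) a Poisson with the same mean is used instead.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0:
        raise ValueError("cannot fit a count distribution to an empty library")
    m = counts.mean()
    v = counts.var(ddof=1) if counts.size > 1 else 0.0
    if v <= m:
        return int(stats.poisson.ppf(q, m))
    r = m * m / (v - m)
    p = r / (r + m)
    return int(stats.nbinom.ppf(q, r, p))


def fit_nb_q95_mle(counts, q: float = 0.95) -> int:
    """Maximum-likelihood NB fit (Poisson fallback), same quantile contract."""
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0:
        raise ValueError("cannot fit a count distribution to an empty library")
    m = counts.mean()
    v = counts.var(ddof=1) if counts.size > 1 else 0.0
    if v <= m:
        return int(stats.poisson.ppf(q, m))

    def negloglik(log_r: float) -> float:
        r = math.exp(log_r)
        p = r / (r + m)
        return -stats.nbinom.logpmf(counts, r, p).sum()

    from scipy.optimize import minimize_scalar

    res = minimize_scalar(negloglik, bounds=(-10, 15), method="bounded")
    r = math.exp(res.x)
    return int(stats.nbinom.ppf(q, r, r / (r + m)))


def top1pct_threshold(counts, fraction: float = 0.01) -> float:
    """Read count of the site at the top-1% abundance rank.

    With n sites, k = ceil(fraction * n); returns the k-th largest count —
    the minimum count inside the top-1% set.
    """
    counts = np.asarray(counts)
    if counts.size == 0:
        raise ValueError("no counts")
    k = max(1, math.ceil(fraction * counts.size))
    return float(np.sort(counts)[::-1][k - 1])


def frac_total_threshold(counts, fraction: float = 0.001) -> float:
    """0.1% of the library's total reads, as a real-valued cutoff."""
    return fraction * float(np.sum(counts))


def compute_thresholds(counts, nb_fit: str = "moments") -> ClonalThresholds:
    """Compute the three thresholds for one library's per-site read counts."""
    fit = fit_nb_q95 if nb_fit == "moments" else fit_nb_q95_mle
    return ClonalThresholds(
        nb_q95=float(fit(counts)),
        top1pct=top1pct_threshold(counts),
        frac_total=frac_total_threshold(counts),
    )


def classify_counts(counts, thresholds: ClonalThresholds) -> pd.Series:
    """Label counts clonal / subclonal / discarded (cut boundaries inclusive
    in the higher class)."""
    counts = pd.Series(counts)
    labels = pd.Series("discarded", index=counts.index)
    labels[counts >= thresholds.subclonal_cut] = "subclonal"
    labels[counts >= thresholds.clonal_cut] = "clonal"
    return labels


def classify(calls: pd.DataFrame, thresholds: ClonalThresholds) -> pd.DataFrame:
    """Add a ``clonality`` column to one library's call table."""
    out = calls.copy()
    out["clonality"] = classify_counts(out["read_count"], thresholds).to_numpy()
    return out


def filter_libraries(
    calls: pd.DataFrame, nb_fit: str = "moments"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every sample x library and derive merged per-sample labels.

    Thresholds are computed per sample x library (before merging).  The
    returned merged table unions the two libraries' addresses with the higher
    read count; an address present in both libraries keeps the *stricter*
    (lower) of the two clonality labels.  Returns
    ``(merged labeled calls, thresholds table)``.
    """
    labeled_parts = []
    threshold_rows = []
    for (sample_id, library), sub in calls.groupby(["sample_id", "library"]):
        thr = compute_thresholds(sub["read_count"].to_numpy(), nb_fit=nb_fit)
        labeled_parts.append(classify(sub, thr))
        threshold_rows.append(
            {
                "sample_id": sample_id,
                "library": library,
                "nb_q95": thr.nb_q95,
                "top1pct": thr.top1pct,
                "frac_total": thr.frac_total,
                "clonal_cut": thr.clonal_cut,
                "subclonal_cut": thr.subclonal_cut,
            }
        )
    thresholds = pd.DataFrame(threshold_rows)
    if not labeled_parts:
        empty = calls.copy()
        empty["clonality"] = pd.Series(dtype=str)
        return empty, thresholds
    labeled = pd.concat(labeled_parts, ignore_index=True)

    labeled["_rank"] = labeled["clonality"].map(CLASS_ORDER)
    merged = (
        labeled.groupby(["sample_id", "chrom", "ta_pos", "orientation"], as_index=False)
        .agg(read_count=("read_count", "max"), _rank=("_rank", "min"))
        .assign(library="merged")
    )
    merged["clonality"] = merged["_rank"].map(
        {v: k for k, v in CLASS_ORDER.items()}
    )
    merged = merged.drop(columns="_rank")
    cols = ["sample_id", "library", "chrom", "ta_pos", "orientation", "read_count", "clonality"]
    merged = merged[cols].sort_values(
        ["sample_id", "chrom", "ta_pos", "orientation"]
    ).reset_index(drop=True)
    return merged, thresholds


def filtered_clonal(labeled: pd.DataFrame) -> pd.DataFrame:
    """Clonal insertions only (the most stringent dataset)."""
    return labeled[labeled["clonality"] == "clonal"].reset_index(drop=True)


def filtered_subclonal(labeled: pd.DataFrame) -> pd.DataFrame:
    """Clonal plus subclonal insertions (discarded class dropped)."""
    return labeled[labeled["clonality"].isin(["clonal", "subclonal"])].reset_index(drop=True)
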