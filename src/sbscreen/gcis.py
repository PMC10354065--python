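"""Gene-centric common insertion site (gCIS) statistics.

Sleeping Beauty transposons integrate at TA dinucleotides, so under
neutrality a gene is expected to collect cohort insertions in proportion to
its share of the genome's TA sites:

    expected = n_insertions_cohort * ta_in_gene / ta_genome

For each gene the one-sided enrichment of the observed insertion count over
this expectation is tested — by the exact binomial upper tail by default
(``P(X >= observed)`` with ``X ~ Binomial(n, ta_in_gene/ta_genome)``), or by
a 1-df chi-square statistic ``(obs - exp)^2 / exp`` with the upper-tail
p-value halved for one-sidedness (falling back to the exact test when
``expected < 5``).  P-values are Bonferroni-corrected over the tested genes
and calls with adjusted p < 0.05 are significant.  Before testing, each
screen arm's donor-concatemer chromosome is excluded (local hopping) along
with blacklisted multi-copy artifact genes (the Sfi1 class).
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from sbscreen.annotate import GeneModel

GCIS_COLUMNS = [
    "gene_name",
    "chrom",
    "ta_in_gene",
    "ta_genome",
    "n_insertions_cohort",
    "observed",
    "expected",
    "statistic",
    "p_raw",
    "p_adj",
    "significant",
    "n_samples_hit",
    "samples_hit",
]


def count_ta(sequence: str, start: int = 0, end: int | None = None) -> int:
    """Number of positions i in [start, end) with sequence[i:i+2] == 'TA'."""
    if end is None:
        end = len(sequence)
    if not 0 <= start <= end <= len(sequence):
        raise ValueError(f"malformed interval [{start}, {end}) for length {len(sequence)}")
    window = sequence[start : min(end + 1, len(sequence))]
    arr = np.frombuffer(window.encode(), dtype="S1")
    if arr.size < 2:
        return 0
    hits = (arr[:-1] == b"T") & (arr[1:] == b"A")
    # the T must lie within [start, end)
    return int(hits[: end - start].sum())


def ta_in_interval(ta_index: np.ndarray, start: int, end: int) -> int:
    """TA count in [start, end) from a sorted TA-position index."""
    return int(np.searchsorted(ta_index, end) - np.searchsorted(ta_index, start))


def apply_exclusions(
    insertions: pd.DataFrame,
    metadata: pd.DataFrame,
    donor_map: Mapping[str, str] | None,
) -> tuple[pd.DataFrame, set[str]]:
    """Remove local-hopping insertions and identify excluded chromosomes.

    ``donor_map`` maps screen arm -> donor chromosome.  Insertions from a
    sample land on its arm's donor chromosome are removed before testing;
    genes on any donor chromosome are skipped entirely.  Returns the
    filtered insertions and the set of donor chromosomes.
    """
    if not donor_map:
        return insertions, set()
    arm_of = dict(zip(metadata["sample_id"], metadata["screen_arm"]))
    unknown = set(insertions["sample_id"]) - set(arm_of)
    if unknown:
        raise ValueError(f"samples with unknown screen arm: {sorted(unknown)[:5]}")
    bad_arms = set(metadata.loc[metadata["sample_id"].isin(insertions["sample_id"]), "screen_arm"]) - set(donor_map)
    if bad_arms:
        raise ValueError(f"screen arms missing from donor map: {sorted(bad_arms)}")
    donor_of = insertions["sample_id"].map(lambda s: donor_map[arm_of[s]])
    kept = insertions[insertions["chrom"] != donor_of].reset_index(drop=True)
    return kept, set(donor_map.values())


def gcis_test(
    observed: int,
    n_insertions_cohort: int,
    ta_in_gene: int,
    ta_genome: int,
    method: str = "binomial",
) -> tuple[float, float, float]:
    """One-sided per-gene enrichment test.

    Returns ``(expected, statistic, p_raw)``.  Enrichment only: with
    ``observed <= expected`` the p-value is 1.  A gene with no TA sites is
    untestable (expected 0, p 1).
    """
    if ta_in_gene == 0 or ta_genome == 0 or n_insertions_cohort == 0:
        return 0.0, 0.0, 1.0
    rate = ta_in_gene / ta_genome
    expected = n_insertions_cohort * rate
    statistic = (observed - expected) ** 2 / expected
    if observed <= expected:
        return expected, 0.0, 1.0
    if method == "binomial" or (method == "chisq" and expected < 5):
        p_raw = float(stats.binom.sf(observed - 1, n_insertions_cohort, rate))
    elif method == "chisq":
        p_raw = float(stats.chi2.sf(statistic, df=1) / 2.0)
    else:
        raise ValueError(f"unknown gcis method {method!r}")
    return expected, statistic, min(p_raw, 1.0)


def adjust_and_call(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Bonferroni adjustment over the tested genes; significant iff p_adj < alpha."""
    out = results.copy()
    m = len(out)
    out["p_adj"] = np.minimum(out["p_raw"] * m, 1.0)
    out["significant"] = out["p_adj"] < alpha
    return out


def run_gcis(
    insertions: pd.DataFrame,
    models: list[GeneModel],
    ta_index: Mapping[str, np.ndarray],
    metadata: pd.DataFrame | None = None,
    donor_map: Mapping[str, str] | None = None,
    blacklist: Iterable[str] = (),
    promoter_window: int = 0,
    method: str = "binomial",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """gCIS scan over all genes for one cohort's filtered insertions.

    ``insertions`` must already be restricted to the desired clonality level
    (filtered_clonal or filtered_subclonal).  Gene territory is the
    transcript span, optionally extended by a strand-aware upstream promoter
    window.  The Bonferroni family is the set of genes actually tested
    (TA-containing, off donor chromosomes, not blacklisted).  Results are
    sorted by adjusted p then gene name.
    """
    blacklist = set(blacklist)
    if metadata is None:
        metadata = pd.DataFrame(
            {
                "sample_id": insertions["sample_id"].unique(),
                "screen_arm": "armA",
            }
        )
    insertions, donor_chroms = apply_exclusions(insertions, metadata, donor_map)
    n_cohort = len(insertions)
    ta_genome = int(
        sum(idx.size for chrom, idx in ta_index.items() if chrom not in donor_chroms)
    )

    rows = []
    for model in models:
        if model.gene_name in blacklist or model.chrom in donor_chroms:
            continue
        start, end = model.tx_start, model.tx_end
        if promoter_window:
            if model.strand == "+":
                start = max(0, start - promoter_window)
            else:
                end = end + promoter_window
        ta_gene = ta_in_interval(ta_index[model.chrom], start, end)
        in_gene = insertions[
            (insertions["chrom"] == model.chrom)
            & (insertions["ta_pos"] >= start)
            & (insertions["ta_pos"] < end)
        ]
        observed = len(in_gene)
        expected, statistic, p_raw = gcis_test(
            observed, n_cohort, ta_gene, ta_genome, method=method
        )
        samples = sorted(set(in_gene["sample_id"]))
        rows.append(
            {
                "gene_name": model.gene_name,
                "chrom": model.chrom,
                "ta_in_gene": ta_gene,
                "ta_genome": ta_genome,
                "n_insertions_cohort": n_cohort,
                "observed": observed,
                "expected": expected,
                "statistic": statistic,
                "p_raw": p_raw,
                "n_samples_hit": len(samples),
                "samples_hit": ",".join(samples),
            }
        )
    results = pd.DataFrame(rows)
    if results.empty:
        return pd.DataFrame(columns=GCIS_COLUMNS)
    tested = results[results["ta_in_gene"] > 0].reset_index(drop=True)
    tested = adjust_and_call(tested, alpha=alpha)
    tested = tested.sort_values(["p_adj", "gene_name"]).reset_index(drop=True)
    return tested[GCIS_COLUMNS]
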