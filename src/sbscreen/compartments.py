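"""Compartment classification of significant gCIS genes.

A gene significant in the primary-tumor cohort only is a P-specific driver;
significant in the metastasis cohort only, M-specific; significant in both,
a shared (S-) driver.  At the more permissive subclonal stringency, a
compartment-specific gene that nonetheless shows at least one
filtered-subclonal insertion in the other compartment is relabeled
"enriched" rather than "specific" — subclonal presence softens specificity
but never deletes a call.
"""

from __future__ import annotations

import pandas as pd

COMPARTMENT_COLUMNS = [
    "gene_name",
    "clonal_class",
    "subclonal_in_primary",
    "subclonal_in_met",
    "enriched_label",
]


def classify_compartments(
    primary_gcis: pd.DataFrame,
    met_gcis: pd.DataFrame,
    subclonal_primary: pd.DataFrame | None = None,
    subclonal_met: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Set algebra over the two compartments' significant gCIS genes.

    ``primary_gcis``/``met_gcis`` are gCIS result tables from identical gene
    universes and exclusions; the optional subclonal tables are annotated
    filtered-subclonal insertion tables (with a ``gene_name`` column) used
    to relabel specific genes as enriched.  Raises when the two gCIS runs
    tested different gene universes.
    """
    universe_p = set(primary_gcis["gene_name"])
    universe_m = set(met_gcis["gene_name"])
    if universe_p != universe_m:
        diff = sorted(universe_p ^ universe_m)[:5]
        raise ValueError(f"gCIS gene universes differ (e.g. {diff})")

    sig_p = set(primary_gcis.loc[primary_gcis["significant"], "gene_name"])
    sig_m = set(met_gcis.loc[met_gcis["significant"], "gene_name"])

    present_p = (
        set(subclonal_primary["gene_name"].dropna()) if subclonal_primary is not None else set()
    )
    present_m = (
        set(subclonal_met["gene_name"].dropna()) if subclonal_met is not None else set()
    )

    rows = []
    for gene in sorted(sig_p | sig_m):
        if gene in sig_p and gene in sig_m:
            clonal_class = "shared"
            label = "shared"
        elif gene in sig_p:
            clonal_class = "P-specific"
            label = "P-enriched" if gene in present_m else "P-specific"
        else:
            clonal_class = "M-specific"
            label = "M-enriched" if gene in present_p else "M-specific"
        rows.append(
            {
                "gene_name": gene,
                "clonal_class": clonal_class,
                "subclonal_in_primary": gene in present_p,
                "subclonal_in_met": gene in present_m,
                "enriched_label": label,
            }
        )
    return pd.DataFrame(rows, columns=COMPARTMENT_COLUMNS)


def venn_counts(calls: pd.DataFrame) -> dict[str, int]:
    """Primary-only / metastasis-only / shared counts of significant genes."""
    counts = calls["clonal_class"].value_counts()
    return {
        "P-specific": int(counts.get("P-specific", 0)),
        "M-specific": int(counts.get("M-specific", 0)),
        "shared": int(counts.get("shared", 0)),
    }


def summarize_driver_coverage(
    sample_gene_hits: pd.DataFrame,
    driver_genes: set[str],
    n_samples_total: int,
) -> dict[str, float]:
    """Cohort bookkeeping of driver coverage across samples.

    ``sample_gene_hits`` lists (sample_id, gene_name) pairs for samples with
    at least one significant gCIS gene.  Returns the number of samples with
    any significant gCIS, how many of those carry one of ``driver_genes``,
    the complementary count, their percentages (one decimal, as printed in
    screen summaries), and the number of samples with no significant gCIS.
    """
    with_gcis = sample_gene_hits["sample_id"].nunique()
    hit = sample_gene_hits[sample_gene_hits["gene_name"].isin(driver_genes)][
        "sample_id"
    ].nunique()
    without = with_gcis - hit
    pct_with = round(100.0 * hit / with_gcis, 1) if with_gcis else 0.0
    pct_without = round(100.0 * without / with_gcis, 1) if with_gcis else 0.0
    return {
        "n_samples_with_gcis": int(with_gcis),
        "n_samples_without_gcis": int(n_samples_total - with_gcis),
        "n_with_driver": int(hit),
        "n_without_driver": int(without),
        "pct_with_driver": pct_with,
        "pct_without_driver": pct_without,
    }
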