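"""Tumor clonality via shared transposon integration coordinates.

Because each Sleeping Beauty integration is mapped to the exact TA
dinucleotide, a primary tumor and a metastasis from the same animal that
carry an insertion at the *identical* genomic address almost certainly share
a clonal origin.  Matching uses (chrom, ta_pos) at the filtered-subclonal
level; orientation agreement is recorded as a QC column but not required,
since a site is identified by its nucleotide interval.  Metastases that
share no site with any primary biopsy of their animal are reported as
unassigned — clonality cannot be demonstrated for them (the disseminating
clone may not have been biopsied).
"""

from __future__ import annotations

import pandas as pd

PAIR_COLUMNS = [
    "animal_id",
    "primary_sample",
    "met_sample",
    "n_shared",
    "shared_sites",
    "orientation_agreement",
]


def detect_clonal_pairs(
    insertions: pd.DataFrame,
    metadata: pd.DataFrame,
    min_shared: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Find clonally related (primary, metastasis) pairs within each animal.

    ``insertions`` is a merged, filtered-subclonal insertion table;
    ``metadata`` maps sample_id -> (animal_id, compartment).  Only pairs
    within one animal are ever considered.  Returns
    ``(pairs, unassigned metastases)``; pairs report the exact shared
    addresses ("chrom:pos" list) and the fraction of shared addresses whose
    transposon orientation also agrees.
    """
    if min_shared < 1:
        raise ValueError("min_shared must be >= 1")
    meta = metadata.set_index("sample_id")
    sites: dict[str, dict[tuple[str, int], str]] = {}
    for sample_id, sub in insertions.groupby("sample_id"):
        sites[sample_id] = {
            (r.chrom, r.ta_pos): r.orientation for r in sub.itertuples(index=False)
        }

    pairs, unassigned = [], []
    for animal_id, group in meta.groupby("animal_id"):
        primaries = group.index[group["compartment"] == "primary"].tolist()
        mets = group.index[group["compartment"] == "metastasis"].tolist()
        for met in mets:
            met_sites = sites.get(met, {})
            matched = False
            for prim in primaries:
                prim_sites = sites.get(prim, {})
                shared = sorted(set(met_sites) & set(prim_sites))
                if len(shared) < min_shared:
                    continue
                matched = True
                agree = sum(met_sites[s] == prim_sites[s] for s in shared)
                pairs.append(
                    {
                        "animal_id": animal_id,
                        "primary_sample": prim,
                        "met_sample": met,
                        "n_shared": len(shared),
                        "shared_sites": ";".join(f"{c}:{p}" for c, p in shared),
                        "orientation_agreement": agree / len(shared),
                    }
                )
            if not matched:
                unassigned.append(
                    {
                        "animal_id": animal_id,
                        "met_sample": met,
                        "reason": "no_primary_biopsy" if not primaries else "no_shared_sites",
                    }
                )
    pairs_df = pd.DataFrame(pairs, columns=PAIR_COLUMNS)
    unassigned_df = pd.DataFrame(unassigned, columns=["animal_id", "met_sample", "reason"])
    return pairs_df, unassigned_df
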