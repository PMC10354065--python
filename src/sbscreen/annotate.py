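"""Gene-model annotation of insertion calls and gene-level effect prediction.

Each insertion is mapped onto refFlat gene models: exon, intron, promoter
(a strand-aware window upstream of the TSS) or intergenic, with the
transposon's orientation recorded relative to the gene's strand.  Across a
cohort, the spatial/orientation pattern of a gene's insertions predicts
whether the transposon acts as an activator (same-orientation hits clustered
at the 5' end, where the transposon's promoter drives the gene) or as a
gene trap (mixed orientations dispersed over the gene body, truncating the
transcript).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

_REGION_PRIORITY = {"exon": 0, "intron": 1, "promoter": 2}


@dataclass(frozen=True)
class GeneModel:
    """One refFlat transcript record (0-based half-open coordinates)."""

    gene_name: str
    transcript_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exon_starts: tuple[int, ...]
    exon_ends: tuple[int, ...]

    def __post_init__(self):
        if not self.tx_start < self.tx_end:
            raise ValueError(f"{self.gene_name}: tx_start must be < tx_end")
        prev_end = self.tx_start - 1
        for s, e in zip(self.exon_starts, self.exon_ends):
            if not (self.tx_start <= s < e <= self.tx_end) or s < prev_end:
                raise ValueError(f"{self.gene_name}: malformed exon structure")
            prev_end = e

    @property
    def span(self) -> int:
        return self.tx_end - self.tx_start

    def region_of(self, pos: int, promoter_window: int) -> str | None:
        """Region label for a position, or None if outside the gene territory."""
        if self.tx_start <= pos < self.tx_end:
            for s, e in zip(self.exon_starts, self.exon_ends):
                if s <= pos < e:
                    return "exon"
            return "intron"
        if self.strand == "+":
            if self.tx_start - promoter_window <= pos < self.tx_start:
                return "promoter"
        else:
            if self.tx_end <= pos < self.tx_end + promoter_window:
                return "promoter"
        return None

    def five_prime_fraction(self, pos: int) -> float:
        """Position along the transcript from the 5' end, in [0, 1]; promoter < 0."""
        if self.strand == "+":
            return (pos - self.tx_start) / self.span
        return (self.tx_end - 1 - pos) / self.span


def models_from_refflat(genes: pd.DataFrame) -> list[GeneModel]:
    return [
        GeneModel(
            gene_name=r.geneName,
            transcript_id=r.name,
            chrom=r.chrom,
            strand=r.strand,
            tx_start=int(r.txStart),
            tx_end=int(r.txEnd),
            cds_start=int(r.cdsStart),
            cds_end=int(r.cdsEnd),
            exon_starts=tuple(r.exonStarts),
            exon_ends=tuple(r.exonEnds),
        )
        for r in genes.itertuples(index=False)
    ]


def annotate_position(
    chrom: str,
    pos: int,
    orientation: str,
    models_by_chrom: dict[str, list[GeneModel]],
    promoter_window: int = 5000,
) -> tuple[str | None, str, str | None]:
    """Annotate one insertion address.

    Returns ``(gene_name, region, relative_orientation)``; overlapping genes
    are resolved by region priority (exon > intron > promoter), then smallest
    transcript span, then lexicographic gene name.  A chromosome without gene
    models yields intergenic.
    """
    candidates = []
    for model in models_by_chrom.get(chrom, []):
        region = model.region_of(pos, promoter_window)
        if region is not None:
            candidates.append((_REGION_PRIORITY[region], model.span, model.gene_name, region, model))
    if not candidates:
        return None, "intergenic", None
    _, _, _, region, model = min(candidates, key=lambda c: c[:3])
    rel = "same" if orientation == model.strand else "opposite"
    return model.gene_name, region, rel


def annotate_table(
    insertions: pd.DataFrame,
    models: list[GeneModel],
    promoter_window: int = 5000,
) -> pd.DataFrame:
    """Annotate an insertion table with gene_name/region/relative_orientation."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for m in models:
        by_chrom.setdefault(m.chrom, []).append(m)
    genes, regions, rels = [], [], []
    for row in insertions.itertuples(index=False):
        g, r, o = annotate_position(
            row.chrom, row.ta_pos, row.orientation, by_chrom, promoter_window
        )
        genes.append(g)
        regions.append(r)
        rels.append(o)
    out = insertions.copy()
    out["gene_name"] = genes
    out["region"] = regions
    out["relative_orientation"] = rels
    return out


def predict_gene_effect(
    gene_insertions: pd.DataFrame,
    model: GeneModel,
    f_same: float = 0.75,
    f_5p: float = 0.75,
    five_prime_cut: float = 0.25,
) -> str:
    """Predict a gene's insertion effect from its cohort-wide hit pattern.

    ``activating``: at least ``f_same`` of insertions are in the gene's
    transcriptional orientation AND at least ``f_5p`` lie in the promoter or
    the 5'-most ``five_prime_cut`` of the transcript (the transposon promoter
    drives the gene).  ``inactivating``: two or more hits with mixed
    orientations (same-orientation fraction within [1-f_same, f_same]) or
    dispersed over the gene body (gene-trap truncation).  Otherwise
    ``ambiguous``.  The call is independent of row order.
    """
    n = len(gene_insertions)
    if n == 0:
        raise ValueError("need at least one insertion")
    same_frac = (gene_insertions["relative_orientation"] == "same").mean()
    positions = gene_insertions["ta_pos"]
    is_promoter = gene_insertions["region"] == "promoter"
    fp = positions.map(model.five_prime_fraction)
    five_prime = (is_promoter | (fp <= five_prime_cut)).mean()
    if same_frac >= f_same and five_prime >= f_5p and n >= 2:
        return "activating"
    if n >= 2:
        mixed = (1 - f_same) <= same_frac <= f_same
        inside = fp[~is_promoter]
        dispersed = len(inside) >= 2 and (inside.max() - inside.min()) > 0.5
        if mixed or dispersed:
            return "inactivating"
    return "ambiguous"
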