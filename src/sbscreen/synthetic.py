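"""Forward simulator for Sleeping Beauty mutagenesis screens.

Generates a toy multi-chromosome genome with TA dinucleotide integration
sites, refFlat gene models, per-sample insertion tables for two transposon-end
libraries (IRL/IRR), sequencing reads, and an expression cohort — all with a
recorded ground truth (:class:`ScreenTruth`) so the downstream read
processing, clonal filter, gCIS, compartment, clonality and pathway stages
can be validated end to end.

The simulated screen has the structure of a two-compartment insertional
mutagenesis experiment: primary tumors carry clonal (high read count)
insertions in planted primary-specific and shared driver genes plus a
uniform subclonal background over TA sites; each metastasis descends from
one primary and inherits a fraction of its clonal insertions at *identical*
genomic coordinates (the basis of clonality detection), then adds its own
metastasis-driver hits and background.  The donor concatemer chromosome
receives an excess of background insertions (local hopping), and a
multi-copy artifact gene accumulates recurrent insertions in both
compartments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from sbscreen.config import ConfigurationError, ScreenConfig
from sbscreen import io

logger = logging.getLogger(__name__)

ADAPTER = "TGTATGTAAACTTCCGACTTCAACTG"
BARCODE_LENGTH = 8

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def ta_positions(seq: str) -> np.ndarray:
    """0-based positions i with seq[i:i+2] == 'TA' (position of the T)."""
    arr = np.frombuffer(seq.encode(), dtype="S1")
    if arr.size < 2:
        return np.empty(0, dtype=np.int64)
    hits = (arr[:-1] == b"T") & (arr[1:] == b"A")
    return np.flatnonzero(hits).astype(np.int64)


@dataclass
class ScreenTruth:
    """Ground truth of one simulated screen.

    drivers_by_compartment maps "primary"/"metastasis" to the planted driver
    gene sets (shared drivers appear in both); lineage maps each metastasis
    sample to its parent primary; shared_sites lists, per animal, the
    integration coordinates planted in both compartments; sources records the
    origin and true clonality class of every insertion event.
    """

    drivers_by_compartment: dict[str, set[str]]
    lineage: dict[str, str]
    shared_sites: dict[str, list[tuple[str, int]]]
    artifact_genes: set[str]
    sources: pd.DataFrame = field(repr=False)
    metadata: pd.DataFrame = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "drivers_by_compartment": {
                k: sorted(v) for k, v in self.drivers_by_compartment.items()
            },
            "lineage": dict(sorted(self.lineage.items())),
            "shared_sites": {
                k: [[c, int(p)] for c, p in v] for k, v in sorted(self.shared_sites.items())
            },
            "artifact_genes": sorted(self.artifact_genes),
        }


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _place_genes(
    rng: np.random.Generator, config: ScreenConfig, chrom: str, n: int
) -> list[tuple[int, int]]:
    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    slack = config.chrom_length - int(lengths.sum())
    if slack < n + 1:
        raise ConfigurationError(
            f"cannot place {n} genes of total length {lengths.sum()} on {chrom}"
        )
    gaps = rng.multinomial(slack - (n + 1), np.full(n + 1, 1.0 / (n + 1))) + 1
    spans, pos = [], 0
    for i in range(n):
        pos += int(gaps[i])
        spans.append((pos, pos + int(lengths[i])))
        pos += int(lengths[i])
    return spans


def _make_exons(
    rng: np.random.Generator, tx_start: int, tx_end: int
) -> tuple[tuple[int, ...], tuple[int, ...]]:
    n_exons = int(rng.integers(1, 6))
    if n_exons == 1:
        return (tx_start,), (tx_end,)
    # 2(n-1) interior breakpoints alternate exon/intron boundaries
    cuts = np.sort(rng.choice(np.arange(tx_start + 1, tx_end), 2 * (n_exons - 1), replace=False))
    bounds = [tx_start, *cuts.tolist(), tx_end]
    starts = tuple(bounds[0::2][:n_exons])
    ends = tuple(bounds[1::2][:n_exons])
    return starts, ends


def simulate_genome(
    config: ScreenConfig,
) -> tuple[dict[str, str], pd.DataFrame, dict[str, np.ndarray]]:
    """Simulate chromosome sequences, refFlat gene models and the TA-site index.

    Genes are non-overlapping, strand-assigned, with 1-5 exons; every gene is
    guaranteed at least 20 TA sites (its sequence is locally resampled
    otherwise).  Planted driver genes and the artifact gene are placed off the
    donor chromosome so that donor-chromosome exclusion never removes a
    planted signal.

    Returns ``(sequences, genes, ta_index)`` where ``sequences`` maps
    chromosome name to sequence, ``genes`` is a refFlat-shaped DataFrame and
    ``ta_index`` maps chromosome name to the sorted array of TA positions.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 11])
    chroms = config.chromosome_names

    sequences = {c: _random_sequence(rng, config.chrom_length) for c in chroms}

    # distribute genes round-robin over chromosomes
    per_chrom = {c: 0 for c in chroms}
    for i in range(config.n_genes):
        per_chrom[chroms[i % len(chroms)]] += 1

    rows = []
    gene_idx = 0
    for chrom in chroms:
        spans = _place_genes(rng, config, chrom, per_chrom[chrom])
        seq = sequences[chrom]
        for tx_start, tx_end in spans:
            # guarantee enough integration sites inside the gene
            while ta_positions(seq[tx_start:tx_end]).size < 20:
                seq = (
                    seq[:tx_start]
                    + _random_sequence(rng, tx_end - tx_start)
                    + seq[tx_end:]
                )
            strand = "+" if rng.random() < 0.5 else "-"
            exon_starts, exon_ends = _make_exons(rng, tx_start, tx_end)
            gene_idx += 1
            rows.append(
                {
                    "geneName": f"gene{gene_idx:04d}",
                    "name": f"tx{gene_idx:04d}",
                    "chrom": chrom,
                    "strand": strand,
                    "txStart": tx_start,
                    "txEnd": tx_end,
                    "cdsStart": tx_start,
                    "cdsEnd": tx_end,
                    "exonCount": len(exon_starts),
                    "exonStarts": exon_starts,
                    "exonEnds": exon_ends,
                }
            )
        sequences[chrom] = seq

    genes = pd.DataFrame(rows)

    # rename evenly spaced off-donor genes to the planted driver / artifact names
    special = [*config.all_driver_names, config.artifact_gene]
    eligible = genes.index[genes["chrom"] != config.donor_chromosome].to_numpy()
    if len(special) > eligible.size:
        raise ConfigurationError("not enough off-donor genes for planted drivers")
    picks = eligible[np.linspace(0, eligible.size - 1, len(special)).astype(int)]
    genes.loc[picks, "geneName"] = special

    ta_index = {c: ta_positions(sequences[c]) for c in chroms}
    return sequences, genes, ta_index


def _nb_count(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    """Negative-binomial read count (>=1); dispersion -> inf is Poisson."""
    if not np.isfinite(dispersion):
        draw = rng.poisson(mean)
    else:
        p = dispersion / (dispersion + mean)
        draw = rng.negative_binomial(dispersion, p)
    return max(int(draw), 1)


def simulate_insertions(
    config: ScreenConfig,
    genes: pd.DataFrame,
    ta_index: Mapping[str, np.ndarray],
) -> tuple[pd.DataFrame, ScreenTruth]:
    """Simulate per-sample IRL/IRR insertion tables and the screen ground truth.

    Every insertion event is recorded in both libraries with independently
    drawn read counts, except a ``single_library_fraction`` of events that are
    detected in only one library.  Returns the concatenated insertion table
    (columns of :data:`sbscreen.io.INSERTION_COLUMNS`) and the truth object.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 23])

    known = set(genes["geneName"])
    missing = [g for g in [*config.all_driver_names, config.artifact_gene] if g not in known]
    if missing:
        raise ConfigurationError(f"planted driver genes absent from gene models: {missing}")

    margin = config.chrom_end_margin
    # TA sites usable for planting: inside chromosome-end margins (so that
    # emitted reads always fit) and per-gene
    safe_ta = {
        c: tas[(tas >= margin) & (tas < config.chrom_length - margin)]
        for c, tas in ta_index.items()
    }
    gene_rows = genes.set_index("geneName")
    gene_sites: dict[str, tuple[str, np.ndarray]] = {}
    for name, row in gene_rows.iterrows():
        tas = safe_ta[row["chrom"]]
        inside = tas[(tas >= row["txStart"]) & (tas < row["txEnd"])]
        gene_sites[name] = (row["chrom"], inside)

    chroms = config.chromosome_names
    weights = np.array(
        [
            safe_ta[c].size * (config.local_hop_excess if c == config.donor_chromosome else 1.0)
            for c in chroms
        ],
        dtype=float,
    )
    chrom_probs = weights / weights.sum() if weights.sum() > 0 else weights

    p_set = set(config.planted_p_drivers)
    m_set = set(config.planted_m_drivers)
    s_set = set(config.planted_shared_drivers)

    samples = []
    for i in range(config.n_primary_samples):
        samples.append((f"P{i + 1:03d}", f"animal{i + 1:03d}", "primary"))
    parent_of: dict[str, str] = {}
    for j in range(config.n_met_samples):
        met = f"M{j + 1:03d}"
        if config.n_primary_samples == 0:
            samples.append((met, f"orphan{j + 1:03d}", "metastasis"))
            continue
        parent_idx = int(rng.integers(config.n_primary_samples))
        parent, animal, _ = samples[parent_idx]
        parent_of[met] = parent
        samples.append((met, animal, "metastasis"))

    metadata = pd.DataFrame(samples, columns=["sample_id", "animal_id", "compartment"])
    metadata["screen_arm"] = "armA"

    def plant_driver_events(compartment: str) -> list[tuple[str, int, str, str, str]]:
        drivers = (p_set if compartment == "primary" else m_set) | s_set
        events = []
        for gene in sorted(drivers):
            if rng.random() >= config.driver_hit_probability:
                continue
            chrom, sites = gene_sites[gene]
            if sites.size == 0:
                continue
            pos = int(sites[rng.integers(sites.size)])
            orient = "+" if rng.random() < 0.5 else "-"
            events.append((chrom, pos, orient, "driver", "clonal"))
        if rng.random() < config.artifact_hit_probability:
            chrom, sites = gene_sites[config.artifact_gene]
            if sites.size:
                pos = int(sites[rng.integers(sites.size)])
                orient = "+" if rng.random() < 0.5 else "-"
                events.append((chrom, pos, orient, "artifact", "clonal"))
        return events

    def background_events() -> list[tuple[str, int, str, str, str]]:
        events = []
        n = config.background_insertions_per_sample
        if n == 0 or chrom_probs.sum() == 0:
            return events
        picked = rng.choice(len(chroms), size=n, p=chrom_probs)
        for ci in picked:
            sites = safe_ta[chroms[ci]]
            if sites.size == 0:
                continue
            pos = int(sites[rng.integers(sites.size)])
            orient = "+" if rng.random() < 0.5 else "-"
            events.append((chroms[ci], pos, orient, "background", "subclonal"))
        return events

    clonal_events: dict[str, list[tuple[str, int, str, str, str]]] = {}
    events_by_sample: dict[str, list[tuple[str, int, str, str, str]]] = {}

    for sample_id, animal, compartment in samples:
        if compartment == "primary":
            events = plant_driver_events("primary") + background_events()
        else:
            inherited = []
            parent = parent_of.get(sample_id)
            if parent is not None:
                for ev in clonal_events[parent]:
                    if rng.random() < config.met_inherited_fraction:
                        inherited.append((ev[0], ev[1], ev[2], "inherited", "clonal"))
            events = inherited + plant_driver_events("metastasis") + background_events()
        # deduplicate identical addresses within the sample
        seen: dict[tuple[str, int, str], tuple[str, int, str, str, str]] = {}
        for ev in events:
            seen.setdefault((ev[0], ev[1], ev[2]), ev)
        events = list(seen.values())
        events_by_sample[sample_id] = events
        clonal_events[sample_id] = [ev for ev in events if ev[4] == "clonal"]

    rows, source_rows = [], []
    for sample_id, animal, compartment in samples:
        for chrom, pos, orient, source, true_class in events_by_sample[sample_id]:
            mean, disp = (
                (config.clonal_count_mean, config.clonal_dispersion)
                if true_class == "clonal"
                else (config.subclonal_count_mean, config.subclonal_dispersion)
            )
            libs = ["IRL", "IRR"]
            if rng.random() < config.single_library_fraction:
                libs = [libs[int(rng.integers(2))]]
            for lib in libs:
                rows.append(
                    (sample_id, lib, chrom, pos, orient, _nb_count(rng, mean, disp))
                )
            source_rows.append((sample_id, chrom, pos, orient, source, true_class))

    table = pd.DataFrame(rows, columns=io.INSERTION_COLUMNS)
    sources = pd.DataFrame(
        source_rows,
        columns=["sample_id", "chrom", "ta_pos", "orientation", "source", "true_class"],
    )

    # shared sites per animal: inherited met coordinates, which by construction
    # exist in the parent primary at the identical address
    shared_sites: dict[str, list[tuple[str, int]]] = {}
    animal_of = dict(zip(metadata["sample_id"], metadata["animal_id"]))
    inherited = sources[sources["source"] == "inherited"]
    for row in inherited.itertuples(index=False):
        shared_sites.setdefault(animal_of[row.sample_id], []).append((row.chrom, row.ta_pos))
    shared_sites = {k: sorted(set(v)) for k, v in shared_sites.items()}

    truth = ScreenTruth(
        drivers_by_compartment={
            "primary": p_set | s_set,
            "metastasis": m_set | s_set,
            "shared": set(s_set),
        },
        lineage=parent_of,
        shared_sites=shared_sites,
        artifact_genes={config.artifact_gene},
        sources=sources,
        metadata=metadata,
    )
    return table, truth


def make_manifest(insertions: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Assign a unique 8-nt barcode to every sample x library pair."""
    rng = np.random.default_rng([seed, 31])
    pairs = (
        insertions[["sample_id", "library"]].drop_duplicates().sort_values(
            ["sample_id", "library"]
        )
    )
    barcodes: set[str] = set()
    assigned = []
    for _ in range(len(pairs)):
        while True:
            bc = _random_sequence(rng, BARCODE_LENGTH)
            if bc not in barcodes:
                barcodes.add(bc)
                assigned.append(bc)
                break
    manifest = pairs.reset_index(drop=True)
    manifest["barcode"] = assigned
    return manifest


def emit_fastq(
    insertions: pd.DataFrame,
    sequences: Mapping[str, str],
    manifest: pd.DataFrame,
    out_dir: str | Path,
    read_length: int = 50,
    emit_r2: bool = True,
) -> pd.DataFrame:
    """Write per-sample x library FASTQ files for the simulated insertions.

    Read 1 is ``barcode + adapter + genomic sequence`` where the genomic part
    starts at the insertion's TA site read in the transposon's direction (so
    it always begins with TA); each insertion contributes exactly
    ``read_count`` read-1 records.  Read 2 is a downstream genomic fragment.
    Insertions too close to a chromosome end for the requested read length
    are skipped with a warning.  Returns the manifest annotated with file
    paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    glen = read_length
    barcode_of = {
        (r.sample_id, r.library): r.barcode for r in manifest.itertuples(index=False)
    }

    manifest = manifest.copy()
    r1_paths, r2_paths = [], []
    for m in manifest.itertuples(index=False):
        key = (m.sample_id, m.library)
        sub = insertions[
            (insertions["sample_id"] == m.sample_id) & (insertions["library"] == m.library)
        ]
        r1_path = out_dir / f"{m.sample_id}_{m.library}_R1.fastq"
        r2_path = out_dir / f"{m.sample_id}_{m.library}_R2.fastq"
        serial = 0
        with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
            for ins in sub.itertuples(index=False):
                seq = sequences[ins.chrom]
                if ins.orientation == "+":
                    g1 = seq[ins.ta_pos : ins.ta_pos + glen]
                    g2 = revcomp(seq[ins.ta_pos + glen : ins.ta_pos + 2 * glen])
                else:
                    g1 = revcomp(seq[ins.ta_pos + 2 - glen : ins.ta_pos + 2])
                    g2 = seq[max(ins.ta_pos + 2 - 2 * glen, 0) : ins.ta_pos + 2 - glen]
                if len(g1) < glen or ins.ta_pos + 2 - glen < 0:
                    logger.warning(
                        "skipping insertion %s:%d (%s) too close to chromosome end",
                        ins.chrom,
                        ins.ta_pos,
                        ins.orientation,
                    )
                    continue
                read1 = barcode_of[key] + ADAPTER + g1
                qual1 = "I" * len(read1)
                qual2 = "I" * len(g2)
                for _ in range(int(ins.read_count)):
                    serial += 1
                    rid = f"{m.sample_id}_{m.library}_{serial}"
                    f1.write(f"@{rid}/1\n{read1}\n+\n{qual1}\n")
                    if emit_r2:
                        f2.write(f"@{rid}/2\n{g2}\n+\n{qual2}\n")
        if not emit_r2:
            r2_path.unlink(missing_ok=True)
        r1_paths.append(str(r1_path))
        r2_paths.append(str(r2_path) if emit_r2 else "")
    manifest["fastq_r1"] = r1_paths
    manifest["fastq_r2"] = r2_paths
    return manifest


def simulate_expression_cohort(
    n_primary: int,
    n_met: int,
    pathways: Mapping[str, tuple[list[str], float]],
    noise_sd: float = 0.2,
    seed: int = 0,
    n_background_genes: int = 100,
) -> tuple[pd.DataFrame, pd.Series, dict[str, str]]:
    """Simulate a genes x samples expression cohort with planted pathway shifts.

    ``pathways`` maps pathway name to ``(signature gene list, effect)``;
    a positive effect raises the signature genes' mean expression in
    metastasis samples (ground-truth class "M-enriched"), a negative effect
    in primaries ("P-enriched"), zero means "shared".  Signature lists must
    be pairwise disjoint.  Returns ``(expression, compartment labels,
    truth classes)``.
    """
    all_genes: list[str] = []
    for name, (genes, _) in pathways.items():
        if set(genes) & set(all_genes):
            raise ValueError(f"signature gene lists overlap (pathway {name})")
        all_genes.extend(genes)
    rng = np.random.default_rng([seed, 47])
    samples = [f"P{i + 1:03d}" for i in range(n_primary)] + [
        f"M{i + 1:03d}" for i in range(n_met)
    ]
    labels = pd.Series(
        ["primary"] * n_primary + ["metastasis"] * n_met, index=samples, name="compartment"
    )
    genes = all_genes + [f"bg{i + 1:04d}" for i in range(n_background_genes)]
    expr = rng.normal(0.0, noise_sd, size=(len(genes), len(samples)))
    expr = pd.DataFrame(expr, index=genes, columns=samples)
    is_met = (labels == "metastasis").to_numpy()
    truth: dict[str, str] = {}
    for name, (sig, effect) in pathways.items():
        if effect > 0:
            expr.loc[sig, expr.columns[is_met]] += effect
            truth[name] = "M-enriched"
        elif effect < 0:
            expr.loc[sig, expr.columns[~is_met]] += -effect
            truth[name] = "P-enriched"
        else:
            truth[name] = "shared"
    return expr, labels, truth
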