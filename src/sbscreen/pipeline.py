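"""End-to-end pipeline orchestration with a reproducible run report.

Stages: simulate (optional) -> read calling -> annotation -> clonal filter
-> gCIS per compartment -> compartment comparison -> clonality ->
pathway activity (optional).  Every intermediate artifact is a plain TSV in
the output directory; the run report records the seed, parameters,
per-stage record counts and SHA-256 checksums of all outputs so a rerun
with the same configuration can be verified byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from sbscreen import __version__, io
from sbscreen.annotate import annotate_table, models_from_refflat
from sbscreen.clonal_filter import filter_libraries, filtered_clonal, filtered_subclonal
from sbscreen.clonality import detect_clonal_pairs
from sbscreen.compartments import classify_compartments, venn_counts
from sbscreen.config import ScreenConfig
from sbscreen.gcis import run_gcis
from sbscreen.pathways import run_pathway_comparison
from sbscreen.reads import PrefixAligner, call_sites
from sbscreen import synthetic

logger = logging.getLogger("sbscreen.pipeline")


class PipelineConfigError(ValueError):
    """A run configuration failed schema validation."""


_STAGE_DEFAULTS = {
    "promoter_window": 5000,
    "nb_fit": "moments",
    "gcis_method": "binomial",
    "gcis_alpha": 0.05,
    "pathway_alpha": 1e-4,
    "delta_threshold": 0.27,
    "min_shared": 1,
    "blacklist": [],
    "donor_map": None,
    "emit_reads": True,
}


def validate_config(cfg: dict) -> dict:
    """Fill stage defaults and validate the run-configuration schema."""
    if "screen" not in cfg and "inputs" not in cfg:
        raise PipelineConfigError("config needs a 'screen' (simulate) or 'inputs' section")
    if "inputs" in cfg:
        for key in ("genome", "refflat", "insertions", "metadata"):
            if key not in cfg["inputs"]:
                raise PipelineConfigError(f"inputs section is missing field '{key}'")
            if not Path(cfg["inputs"][key]).exists():
                raise PipelineConfigError(f"inputs.{key}: no such file {cfg['inputs'][key]}")
    out = dict(_STAGE_DEFAULTS)
    out.update(cfg.get("params", {}))
    cfg = dict(cfg)
    cfg["params"] = out
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def run_pipeline(cfg: dict, out_dir: str | Path) -> dict:
    """Run the configured stages; returns the run report as a dict."""
    cfg = validate_config(cfg)
    params = cfg["params"]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "params": params, "counts": {}}

    if "screen" in cfg:
        screen = ScreenConfig(**cfg["screen"])
        report["seed"] = screen.seed
        logger.info("simulate: seed=%d", screen.seed)
        sequences, genes, ta_index = synthetic.simulate_genome(screen)
        true_table, truth = synthetic.simulate_insertions(screen, genes, ta_index)
        io.write_fasta(sequences, out / "genome.fa")
        io.write_refflat(genes, out / "genes.refFlat")
        io.write_insertions(true_table, out / "insertions_true.tsv")
        io.write_truth(truth, out / "truth.json")
        metadata = truth.metadata
        metadata.to_csv(out / "metadata.tsv", sep="\t", index=False)
        manifest = synthetic.make_manifest(true_table, screen.seed)
        if params["emit_reads"]:
            logger.info("emit_fastq + call")
            manifest = synthetic.emit_fastq(
                true_table, sequences, manifest, out / "reads", screen.read_length
            )
            on_disk = manifest.copy()
            for col in ("fastq_r1", "fastq_r2"):
                on_disk[col] = on_disk[col].map(
                    lambda p: str(Path(p).relative_to(out)) if p else p
                )
            io.write_manifest(on_disk, out / "manifest.tsv")
            aligner = PrefixAligner(sequences)
            calls, stats = call_sites(manifest["fastq_r1"], manifest, aligner)
            report["counts"]["reads"] = stats.as_dict()
        else:
            io.write_manifest(manifest, out / "manifest.tsv")
            calls = true_table
    else:
        inputs = cfg["inputs"]
        sequences = io.read_fasta(inputs["genome"])
        genes = io.read_refflat(inputs["refflat"])
        ta_index = {c: synthetic.ta_positions(s) for c, s in sequences.items()}
        calls = io.read_insertions(inputs["insertions"])
        metadata = pd.read_csv(inputs["metadata"], sep="\t")
        report["seed"] = cfg.get("seed")

    io.write_insertions(calls, out / "insertions_called.tsv")
    report["counts"]["calls"] = len(calls)

    logger.info("filter: dynamic clonal/subclonal thresholds")
    labeled, thresholds = filter_libraries(calls, nb_fit=params["nb_fit"])
    thresholds.to_csv(out / "thresholds.tsv", sep="\t", index=False)
    io.write_insertions(labeled, out / "insertions_filtered.tsv")
    report["counts"]["clonality"] = labeled["clonality"].value_counts().to_dict()

    logger.info("annotate")
    models = models_from_refflat(genes)
    annotated = annotate_table(labeled, models, params["promoter_window"])
    io.write_insertions(annotated, out / "annotated.tsv")

    comp_of = dict(zip(metadata["sample_id"], metadata["compartment"]))
    annotated["compartment"] = annotated["sample_id"].map(comp_of)
    donor_map = params["donor_map"]
    gcis_runs = {}
    for compartment in ("primary", "metastasis"):
        comp_ann = annotated[annotated["compartment"] == compartment]
        for level, selector in (("clonal", filtered_clonal), ("subclonal", filtered_subclonal)):
            subset = selector(comp_ann)
            result = run_gcis(
                subset,
                models,
                ta_index,
                metadata=metadata,
                donor_map=donor_map,
                blacklist=params["blacklist"],
                method=params["gcis_method"],
                alpha=params["gcis_alpha"],
            )
            name = f"gcis_{compartment}_{level}"
            result.to_csv(out / f"{name}.tsv", sep="\t", index=False)
            gcis_runs[(compartment, level)] = result
            report["counts"][name] = int(result["significant"].sum())

    logger.info("compartment comparison")
    calls_df = classify_compartments(
        gcis_runs[("primary", "clonal")],
        gcis_runs[("metastasis", "clonal")],
        subclonal_primary=filtered_subclonal(annotated[annotated["compartment"] == "primary"]),
        subclonal_met=filtered_subclonal(annotated[annotated["compartment"] == "metastasis"]),
    )
    calls_df.to_csv(out / "compartments.tsv", sep="\t", index=False)
    report["counts"]["venn"] = venn_counts(calls_df)

    logger.info("clonality")
    pairs, unassigned = detect_clonal_pairs(
        filtered_subclonal(labeled), metadata, min_shared=params["min_shared"]
    )
    pairs.to_csv(out / "clonal_pairs.tsv", sep="\t", index=False)
    unassigned.to_csv(out / "unassigned_mets.tsv", sep="\t", index=False)
    report["counts"]["clonal_pairs"] = len(pairs)
    report["counts"]["unassigned_mets"] = len(unassigned)

    if "expression" in cfg:
        logger.info("pathways")
        expr = io.read_expression(cfg["expression"]["matrix"])
        labels = pd.read_csv(cfg["expression"]["labels"], sep="\t", index_col=0).iloc[:, 0]
        signatures = io.read_gmt(cfg["expression"]["signatures"])
        comparison = run_pathway_comparison(
            expr,
            labels,
            signatures,
            alpha=params["pathway_alpha"],
            delta_threshold=params["delta_threshold"],
        )
        comparison.to_csv(out / "pathway_comparison.tsv", sep="\t", index=False)
        report["counts"]["pathways"] = comparison["classification"].value_counts().to_dict()

    checksums = {
        p.name: _sha256(p) for p in sorted(out.glob("*.tsv")) if p.is_file()
    }
    report["checksums"] = checksums
    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=str)
    return report
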