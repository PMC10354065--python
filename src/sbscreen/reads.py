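"""Raw-read processing: adapter trimming, TA filtering, alignment, site calls.

Converts ligation-library FASTQ into per-sample insertion calls at TA
dinucleotide resolution.  The splinkerette read-1 layout is::

    [8 nt sample barcode][26 nt transposon-end adapter][genomic, starts with TA]

Trimming follows the no-indel, discard-untrimmed contract of a 5'-anchored
adapter match; reads whose genomic part does not start with TA are discarded
(non-canonical integration); the remainder are aligned and aggregated into
(sample, library, chrom, ta_pos, orientation, read_count) calls, and the two
transposon-end libraries (IRL/IRR) are merged per sample keeping the higher
read count at addresses seen in both.
"""

from __future__ import annotations

import gzip
import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

from sbscreen.io import INSERTION_COLUMNS
from sbscreen.synthetic import ADAPTER, BARCODE_LENGTH, revcomp

logger = logging.getLogger(__name__)


@dataclass
class ProcessingStats:
    """Per-stage read accounting for one processing run."""

    total: int = 0
    no_adapter: int = 0
    too_short: int = 0
    non_ta: int = 0
    unknown_barcode: int = 0
    unmapped: int = 0
    aligned: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def trim_adapter(
    sequence: str, min_len: int = 5, max_mismatches: int = 0
) -> tuple[str, str] | None:
    """Trim the 5'-anchored ``NNNNNNNN + adapter`` prefix from a read-1 sequence.

    Returns ``(genomic suffix, 8-nt barcode)`` when the read starts with any
    8 nucleotides followed by the exact transposon-end adapter (no indels;
    ``max_mismatches`` substitutions allowed, default 0) and the suffix is at
    least ``min_len`` long; otherwise ``None`` (read discarded).
    """
    prefix_len = BARCODE_LENGTH + len(ADAPTER)
    if len(sequence) < prefix_len + min_len:
        return None
    window = sequence[BARCODE_LENGTH:prefix_len]
    if max_mismatches == 0:
        if window != ADAPTER:
            return None
    else:
        mismatches = sum(a != b for a, b in zip(window, ADAPTER))
        if mismatches > max_mismatches:
            return None
    return sequence[prefix_len:], sequence[:BARCODE_LENGTH]


def ta_filter(reads: Iterable[str]) -> tuple[list[str], int, int]:
    """Keep exactly the reads whose first two bases are TA.

    Returns ``(kept reads, n_kept, n_discarded)``.
    """
    kept, discarded = [], 0
    for read in reads:
        if read[:2] == "TA":
            kept.append(read)
        else:
            discarded += 1
    return kept, len(kept), discarded


class PrefixAligner:
    """Exact-prefix aligner for error-free reads against a small genome.

    Looks up the first ``k`` bases of a read on both strands of the genome; a
    unique hit yields ``(chrom, ta_pos, orientation)`` where ``ta_pos`` is
    the forward-strand position of the T of the integration TA and
    orientation is the strand of the match.  Zero or multiple hits (either
    strand, any chromosome) return ``None`` (unmapped) — multimapping reads
    are discarded rather than assigned.
    """

    def __init__(self, sequences: Mapping[str, str], k: int = 25):
        self.k = k
        self._index: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in sequences.items():
            for i in range(len(seq) - k + 1):
                self._index.setdefault(seq[i : i + k], []).append((chrom, i))
        self._cache: dict[str, tuple[str, int, str] | None] = {}

    def align(self, read: str) -> tuple[str, int, str] | None:
        if len(read) < self.k:
            return None
        prefix = read[: self.k]
        hit = self._cache.get(prefix, "?")
        if hit != "?":
            return hit
        fwd = self._index.get(prefix, [])
        rev = self._index.get(revcomp(prefix), [])
        if len(fwd) + len(rev) != 1:
            result = None
        elif fwd:
            chrom, pos = fwd[0]
            result = (chrom, pos, "+")
        else:
            # reverse-strand read: its first base pairs with the last base of
            # the forward-strand match, whose TA occupies the final two bases
            chrom, pos = rev[0]
            result = (chrom, pos + self.k - 2, "-")
        self._cache[prefix] = result
        return result


def _open_text(path: str | Path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (id, sequence, quality) from a FASTQ file (gz-transparent)."""
    with _open_text(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            fh.readline()
            qual = fh.readline().rstrip("\n")
            yield header[1:].rstrip("\n"), seq, qual


def call_sites(
    fastq_paths: Iterable[str | Path],
    manifest: pd.DataFrame,
    aligner: PrefixAligner,
    min_len: int = 5,
    max_mismatches: int = 0,
) -> tuple[pd.DataFrame, ProcessingStats]:
    """Process read-1 FASTQ files into per-sample x library insertion calls.

    Reads are adapter-trimmed, demultiplexed by exact barcode lookup in the
    manifest, TA-filtered, aligned, and grouped by identical
    (sample, library, chrom, ta_pos, orientation); ``read_count`` is the
    group size.  Reads failing any step are counted in the returned stats.
    """
    barcode_map = {
        r.barcode: (r.sample_id, r.library) for r in manifest.itertuples(index=False)
    }
    stats = ProcessingStats()
    groups: Counter = Counter()
    for path in fastq_paths:
        for _rid, seq, _qual in iter_fastq(path):
            stats.total += 1
            trimmed = trim_adapter(seq, min_len=min_len, max_mismatches=max_mismatches)
            if trimmed is None:
                stats.no_adapter += 1
                continue
            genomic, barcode = trimmed
            target = barcode_map.get(barcode)
            if target is None:
                stats.unknown_barcode += 1
                logger.debug("unknown barcode %s", barcode)
                continue
            if genomic[:2] != "TA":
                stats.non_ta += 1
                continue
            hit = aligner.align(genomic)
            if hit is None:
                stats.unmapped += 1
                continue
            stats.aligned += 1
            chrom, ta_pos, orientation = hit
            groups[(target[0], target[1], chrom, ta_pos, orientation)] += 1

    rows = [(s, l, c, p, o, n) for (s, l, c, p, o), n in groups.items()]
    table = pd.DataFrame(rows, columns=INSERTION_COLUMNS)
    if len(table):
        table = table.sort_values(
            ["sample_id", "library", "chrom", "ta_pos", "orientation"]
        ).reset_index(drop=True)
    return table, stats


def calls_from_sam(
    sam_path: str | Path, sample_id: str, library: str
) -> pd.DataFrame:
    """Derive insertion calls from a pre-aligned SAM/BAM file.

    The TA address is the leftmost aligned base for forward-strand alignments
    and ``reference_end - 2`` for reverse-strand ones; unmapped and secondary
    alignments are ignored.
    """
    import pysam

    groups: Counter = Counter()
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.is_reverse:
                ta_pos, orientation = rec.reference_end - 2, "-"
            else:
                ta_pos, orientation = rec.reference_start, "+"
            groups[(rec.reference_name, ta_pos, orientation)] += 1
    rows = [
        (sample_id, library, c, p, o, n) for (c, p, o), n in sorted(groups.items())
    ]
    return pd.DataFrame(rows, columns=INSERTION_COLUMNS)


def merge_libraries(irl: pd.DataFrame, irr: pd.DataFrame) -> pd.DataFrame:
    """Merge one sample's IRL and IRR call tables into a single table.

    Union over genomic addresses (chrom, ta_pos, orientation); an address
    detected in both libraries keeps the higher read count.  The library
    column of the result is "merged".
    """
    both = pd.concat([irl, irr], ignore_index=True)
    if both.empty:
        return pd.DataFrame(columns=INSERTION_COLUMNS)
    merged = (
        both.groupby(["sample_id", "chrom", "ta_pos", "orientation"], as_index=False)[
            "read_count"
        ]
        .max()
        .assign(library="merged")
    )
    return merged[INSERTION_COLUMNS].sort_values(
        ["sample_id", "chrom", "ta_pos", "orientation"]
    ).reset_index(drop=True)


def merge_all_samples(calls: pd.DataFrame) -> pd.DataFrame:
    """Merge IRL/IRR per sample for a multi-sample call table."""
    parts = []
    for sample_id, sub in calls.groupby("sample_id"):
        irl = sub[sub["library"] == "IRL"]
        irr = sub[sub["library"] == "IRR"]
        parts.append(merge_libraries(irl, irr))
    if not parts:
        return pd.DataFrame(columns=INSERTION_COLUMNS)
    return pd.concat(parts, ignore_index=True)
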