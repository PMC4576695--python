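"""Read-level processing: demultiplexing, trim-rescue and fragment-end counting.

4C libraries are built so that informative reads begin exactly at a
restriction cut site with a protocol-determined orientation.  Counting
therefore keys every alignment on its 5' terminus and strand and matches
it against the expected coordinates of the fragment ends:

* ``first_cutter_primer`` — the sequencing primer sits at a first-cutter
  site, so reads start at a fragment boundary and point toward the
  fragment middle (left end: + strand at ``start``; right end: - strand
  at ``end``).
* ``second_cutter_primer`` — the primer sits at a second-cutter site, so
  reads start at the innermost second-enzyme cut coordinates and point
  toward the fragment boundaries (left end: - strand at the left cut;
  right end: + strand at the right cut).

Counts from the two ends of a fragment are summed into a single
per-fragment value.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

PROTOCOLS = ("first_cutter_primer", "second_cutter_primer")


@dataclass(frozen=True)
class AlignmentRecord:
    """Minimal alignment: 0-based half-open span, strand and quality."""

    chrom: str
    start: int
    end: int
    strand: str  # "+" or "-"
    mapq: int = 60
    is_unique: bool = True

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("alignment start must be < end")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")

    @property
    def five_prime(self) -> int:
        """5' terminus: start for + reads, (half-open) end for - reads."""
        return self.start if self.strand == "+" else self.end


def iter_bam_records(path, min_mapq: int = 0) -> Iterator[AlignmentRecord]:
    """Yield AlignmentRecords from a BAM/SAM file.

    Secondary, supplementary, duplicate and unmapped records are skipped.
    """
    import pysam

    with pysam.AlignmentFile(str(path), "rb" if str(path).endswith("bam") else "r") as bam:
        for rec in bam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary or rec.is_duplicate:
                continue
            yield AlignmentRecord(
                chrom=rec.reference_name,
                start=rec.reference_start,
                end=rec.reference_end,
                strand="-" if rec.is_reverse else "+",
                mapq=rec.mapping_quality,
                is_unique=rec.mapping_quality >= min_mapq,
            )


def _end_lookup(fragments: pd.DataFrame, protocol: str, slack: int):
    """Map (chrom, coordinate, strand) -> (frag_id, end_label, frag_is_valid).

    With slack > 0 every coordinate within +-slack of the required
    position is also keyed (ties broken in favour of the exact position,
    which is inserted last).
    """
    if protocol not in PROTOCOLS:
        raise ValueError(f"unknown protocol {protocol!r}; expected one of {PROTOCOLS}")
    lookup: dict[tuple[str, int, str], tuple[int, str, bool]] = {}
    offsets = [o for o in range(-slack, slack + 1) if o != 0] + [0]
    for row in fragments.itertuples():
        valid = bool(getattr(row, "is_valid", True))
        if protocol == "first_cutter_primer":
            anchors = [(int(row.start), "+", "left"), (int(row.end), "-", "right")]
        else:
            anchors = []
            if getattr(row, "has_second_site", False):
                anchors = [
                    (int(row.left_cut), "-", "left"),
                    (int(row.right_cut), "+", "right"),
                ]
        for coord, strand, label in anchors:
            for off in offsets:
                lookup[(row.chrom, coord + off, strand)] = (int(row.frag_id), label, valid)
    return lookup


def count_reads(
    alignments: Iterable[AlignmentRecord],
    fragments: pd.DataFrame,
    protocol: str = "first_cutter_primer",
    slack: int = 0,
    min_mapq: int = 0,
) -> tuple[pd.Series, dict]:
    """Assign alignments to fragment ends and return per-fragment counts.

    Returns ``(counts, qc)`` where ``counts`` is indexed like
    ``fragments`` (both ends summed; invalid fragments counted but
    reported separately in the QC dict and normally excluded downstream)
    and ``qc`` tallies every processed record by outcome, so that
    ``assigned_valid + assigned_invalid + sum(rejected_*) == total``.
    """
    known_chroms = set(fragments["chrom"].unique())
    lookup = _end_lookup(fragments, protocol, slack)
    row_of = {fid: i for i, fid in enumerate(fragments["frag_id"])}
    tallies = np.zeros(len(fragments), dtype=np.int64)
    qc: Counter = Counter(total=0, assigned_valid=0, assigned_invalid=0)
    for rec in alignments:
        qc["total"] += 1
        if rec.chrom not in known_chroms:
            raise ValueError(f"BAM chromosome {rec.chrom!r} absent from fragment table")
        if rec.mapq < min_mapq or not rec.is_unique:
            qc["rejected_low_mapq"] += 1
            continue
        hit = lookup.get((rec.chrom, rec.five_prime, rec.strand))
        if hit is None:
            qc["rejected_not_at_cut_site"] += 1
            continue
        frag_id, _end, valid = hit
        tallies[row_of[frag_id]] += 1
        qc["assigned_valid" if valid else "assigned_invalid"] += 1
    counts = pd.Series(tallies, index=fragments.index)
    return counts, dict(qc)


def count_bam(
    path,
    fragments: pd.DataFrame,
    protocol: str = "first_cutter_primer",
    slack: int = 0,
    min_mapq: int = 0,
) -> tuple[pd.Series, dict]:
    """``count_reads`` over a BAM file on disk."""
    return count_reads(
        iter_bam_records(path, min_mapq=min_mapq),
        fragments,
        protocol=protocol,
        slack=slack,
        min_mapq=min_mapq,
    )


def qc_valid_fraction(qc: dict, total_aligned: int | None = None, floor: float = 0.5) -> float:
    """Fraction of aligned reads assigned to valid fragments.

    4C libraries in good shape place the large majority (roughly 70-95%)
    of aligned reads on valid fragments; a warning is emitted below
    ``floor``.
    """
    total = total_aligned if total_aligned is not None else qc.get("total", 0)
    if total <= 0:
        raise ValueError("total_aligned must be > 0")
    frac = qc.get("assigned_valid", 0) / total
    if frac < floor:
        warnings.warn(
            f"only {frac:.1%} of aligned reads map to valid fragments "
            f"(expected well above {floor:.0%}); inspect the viewpoint region",
            stacklevel=2,
        )
    return frac


def assemble_count_matrix(
    columns: dict[str, pd.Series],
    fragments: pd.DataFrame,
    valid_only: bool = True,
) -> pd.DataFrame:
    """Stack per-sample count Series into a fragments x samples matrix."""
    mat = pd.DataFrame(columns, index=fragments.index)
    if valid_only and "is_valid" in fragments:
        mat = mat.loc[fragments["is_valid"]]
    if (mat < 0).any().any():
        raise ValueError("negative counts")
    return mat


# ---------------------------------------------------------------------------
# FASTQ-level helpers: demultiplexing and trim-rescue


def _hamming_prefix(read: str, prefix: str, max_mismatch: int) -> bool:
    if len(read) < len(prefix):
        return False
    mism = sum(a != b for a, b in zip(read, prefix))
    return mism <= max_mismatch


def demultiplex(
    reads: Iterable,
    primers: dict[str, str],
    barcodes: dict[str, str] | None = None,
    max_mismatch: int = 0,
):
    """Assign reads to viewpoints by (barcode+)primer prefix and trim it.

    ``reads`` iterates Biopython SeqRecords (e.g. from ``SeqIO.parse``).
    Yields ``(viewpoint_name_or_None, trimmed_record)``; ``None`` marks
    undetermined reads (no match, or ambiguous match across viewpoints).
    The matched prefix is removed from assigned reads.
    """
    prefixes = {
        name: ((barcodes or {}).get(name, "") + primer).upper()
        for name, primer in primers.items()
    }
    for a, pa in prefixes.items():
        for b, pb in prefixes.items():
            if a != b and max_mismatch == 0 and pb.startswith(pa):
                raise ValueError(f"primer of {a!r} is a prefix of {b!r}; demultiplexing ambiguous")
    for rec in reads:
        seq = str(rec.seq).upper()
        hits = [name for name, p in prefixes.items() if _hamming_prefix(seq, p, max_mismatch)]
        if len(hits) == 1:
            name = hits[0]
            yield name, rec[len(prefixes[name]) :]
        else:
            yield None, rec


def demultiplex_fastq(
    fastq_path,
    primers: dict[str, str],
    out_dir,
    barcodes: dict[str, str] | None = None,
    max_mismatch: int = 0,
) -> dict[str, int]:
    """File-level demultiplexing: one trimmed FASTQ per viewpoint."""
    import os

    from Bio import SeqIO

    os.makedirs(out_dir, exist_ok=True)
    handles = {
        name: open(os.path.join(out_dir, f"{name}.fastq"), "w") for name in primers
    }
    handles[None] = open(os.path.join(out_dir, "undetermined.fastq"), "w")
    tally: Counter = Counter()
    try:
        assigned = demultiplex(
            SeqIO.parse(str(fastq_path), "fastq"), primers, barcodes, max_mismatch
        )
        for name, rec in assigned:
            tally[name or "undetermined"] += 1
            SeqIO.write(rec, handles[name], "fastq")
    finally:
        for fh in handles.values():
            fh.close()
    return dict(tally)


def trim_to_second_site(read_sequence: str, second_enzyme, min_length: int = 1) -> str | None:
    """Truncate an unaligned read at the first second-cutter site.

    Short fragments yield reads that run through the second-enzyme cut
    site into the ligation partner, defeating unique alignment; cutting
    the read at that site rescues them for a second alignment pass.
    Returns the (possibly unchanged) sequence, or None when truncation
    leaves fewer than ``min_length`` nt.
    """
    seq = read_sequence.upper()
    pos = seq.find(second_enzyme.site)
    if pos == -1:
        return seq
    cut = pos + second_enzyme.cut_offset
    if cut < min_length:
        return None
    return seq[:cut]


def trim_rescue_fastq(fastq_path, second_enzyme, out_path, min_length: int = 20) -> dict:
    """Apply ``trim_to_second_site`` to a FASTQ of unaligned reads."""
    from Bio import SeqIO

    kept = dropped = unchanged = 0
    with open(out_path, "w") as out:
        for rec in SeqIO.parse(str(fastq_path), "fastq"):
            trimmed = trim_to_second_site(str(rec.seq), second_enzyme, min_length)
            if trimmed is None:
                dropped += 1
                continue
            if len(trimmed) == len(rec.seq):
                unchanged += 1
                SeqIO.write(rec, out, "fastq")
            else:
                kept += 1
                SeqIO.write(rec[: len(trimmed)], out, "fastq")
    return {"trimmed": kept, "unchanged": unchanged, "dropped": dropped}
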