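"""Restriction-fragment reference construction.

A 4C experiment resolves the genome at the level of the restriction
fragments produced by the *first* cutter.  This module digests a genome in
silico, annotates the resulting fragments with the cut sites of the
*second* cutter (which defines the "fragment ends" that reads actually map
to), flags fragments that can be observed by the protocol, locates the
viewpoint fragment from its PCR primer, and computes signed genomic
distances of every cis fragment to the viewpoint.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: columns of a digested (pre-annotation) fragment table
FRAGMENT_COLUMNS = ["frag_id", "chrom", "start", "end", "midpoint"]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme: recognition site plus cut position.

    ``cut_offset`` is measured in nt from the 5' end of the recognition
    sequence on the strand on which the site is read; 0 means the enzyme
    cuts immediately before the site.
    """

    name: str
    site: str
    cut_offset: int = 0

    def __post_init__(self) -> None:
        site = self.site.upper()
        object.__setattr__(self, "site", site)
        if len(site) < 4:
            raise ValueError(f"recognition site {site!r} shorter than 4 nt")
        if set(site) - set("ACGT"):
            raise ValueError(f"recognition site {site!r} contains non-ACGT characters")
        if not 0 <= self.cut_offset <= len(site):
            raise ValueError("cut_offset must lie within the recognition site")

    @property
    def is_palindromic(self) -> bool:
        return self.site == reverse_complement(self.site)


class Genome:
    """In-memory genome: chromosome name -> uppercase sequence."""

    def __init__(self, sequences: Mapping[str, str]):
        if not sequences:
            raise ValueError("genome has no chromosomes")
        self.sequences: dict[str, str] = {}
        for name, seq in sequences.items():
            if name in self.sequences:
                raise ValueError(f"duplicate chromosome name {name!r}")
            seq = str(seq).upper()
            if not seq:
                raise ValueError(f"chromosome {name!r} is empty")
            if set(seq) - set("ACGTN"):
                bad = sorted(set(seq) - set("ACGTN"))
                raise ValueError(f"chromosome {name!r} contains invalid characters {bad}")
            self.sequences[name] = seq

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    @property
    def chroms(self) -> list[str]:
        return list(self.sequences)

    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    @classmethod
    def from_fasta(cls, path) -> "Genome":
        from Bio import SeqIO

        return cls({rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")})

    def to_fasta(self, path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def _occurrences(seq: str, pattern: str) -> Iterable[int]:
    """All (overlapping) start offsets of ``pattern`` in ``seq``."""
    start = seq.find(pattern)
    while start != -1:
        yield start
        start = seq.find(pattern, start + 1)


def cut_positions(seq: str, enzyme: Enzyme) -> np.ndarray:
    """Sorted unique cut coordinates of ``enzyme`` in ``seq`` (both strands).

    A forward-strand occurrence at offset p cuts at p + cut_offset; an
    occurrence of the reverse complement cuts at p + (len(site) - cut_offset),
    the mirror image of the offset.  For the palindromic sites typical of
    4C first/second cutters the two sets coincide.  N bases never match.
    """
    cuts = [p + enzyme.cut_offset for p in _occurrences(seq, enzyme.site)]
    rc = reverse_complement(enzyme.site)
    mirror = len(enzyme.site) - enzyme.cut_offset
    if rc == enzyme.site:
        pass  # palindromic: identical occurrence set, identical cut set
    else:
        cuts.extend(p + mirror for p in _occurrences(seq, rc))
    return np.unique(np.asarray(cuts, dtype=np.int64))


def digest_genome(genome: Genome, first_enzyme: Enzyme) -> pd.DataFrame:
    """Cut the genome with the first cutter and return the fragment table.

    Fragments are the maximal intervals between consecutive cut
    coordinates; the two terminal intervals of each chromosome are kept
    (they have only one true restriction end), empty intervals are dropped.
    """
    rows = []
    frag_id = 0
    for chrom, seq in genome.sequences.items():
        cuts = cut_positions(seq, first_enzyme)
        bounds = np.unique(np.concatenate([[0], cuts, [len(seq)]]))
        bounds = bounds[(bounds >= 0) & (bounds <= len(seq))]
        for start, end in zip(bounds[:-1], bounds[1:]):
            if end <= start:
                continue
            rows.append((frag_id, chrom, int(start), int(end), (start + end) / 2.0))
            frag_id += 1
    table = pd.DataFrame(rows, columns=FRAGMENT_COLUMNS)
    return table.set_index("frag_id", drop=False).rename_axis(index=None)


def annotate_ends(
    fragments: pd.DataFrame,
    genome: Genome,
    second_enzyme: Enzyme,
    min_end_length: int = 20,
) -> pd.DataFrame:
    """Annotate fragment ends with the second cutter and flag valid fragments.

    The left (right) end length is the distance from the fragment start
    (end) to the nearest second-enzyme cut coordinate strictly inside the
    fragment.  An end is valid if its length is >= ``min_end_length``; a
    fragment is valid if it has at least one second-enzyme site and at
    least one valid end — a single short end does not invalidate a
    fragment whose other end is long enough.
    """
    out = fragments.copy()
    n = len(out)
    left_len = np.full(n, np.nan)
    right_len = np.full(n, np.nan)
    left_cut = np.full(n, np.nan)
    right_cut = np.full(n, np.nan)
    has_site = np.zeros(n, dtype=bool)

    for chrom, sub in out.groupby("chrom", sort=False):
        cuts = cut_positions(genome[chrom], second_enzyme)
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        lo = np.searchsorted(cuts, starts, side="right")
        hi = np.searchsorted(cuts, ends, side="left")
        pos = out.index.get_indexer(sub.index)
        for p, s, e, i0, i1 in zip(pos, starts, ends, lo, hi):
            if i1 > i0:  # at least one cut strictly inside (start, end)
                has_site[p] = True
                left_cut[p] = cuts[i0]
                right_cut[p] = cuts[i1 - 1]
                left_len[p] = cuts[i0] - s
                right_len[p] = e - cuts[i1 - 1]

    out["left_end_length"] = left_len
    out["right_end_length"] = right_len
    out["left_cut"] = left_cut
    out["right_cut"] = right_cut
    out["has_second_site"] = has_site
    out["left_end_valid"] = has_site & (left_len >= min_end_length)
    out["right_end_valid"] = has_site & (right_len >= min_end_length)
    out["is_valid"] = has_site & (out["left_end_valid"] | out["right_end_valid"])
    return out


@dataclass(frozen=True)
class Viewpoint:
    """The viewpoint: the fragment containing the 4C primer."""

    name: str
    primer: str
    chrom: str
    fragment_index: int
    midpoint: float


def _mismatch_occurrences(seq: str, pattern: str, max_mismatch: int) -> list[int]:
    """Start offsets where pattern matches seq with <= max_mismatch mismatches."""
    m, n = len(pattern), len(seq)
    if m > n:
        return []
    s = np.frombuffer(seq.encode(), dtype=np.uint8)
    p = np.frombuffer(pattern.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(s, m)
    mism = (windows != p).sum(axis=1)
    return np.flatnonzero(mism <= max_mismatch).tolist()


def locate_viewpoint(
    primer: str,
    genome: Genome,
    fragments: pd.DataFrame,
    name: str = "viewpoint",
    max_mismatch: int = 0,
) -> Viewpoint:
    """Map the viewpoint primer to the genome and find its fragment.

    The primer and its reverse complement are searched exactly (or with a
    Hamming tolerance); the fragment containing the match start is the
    viewpoint fragment.  The search must hit exactly one fragment.
    """
    primer = primer.upper()
    if len(primer) < 15:
        raise ValueError("primer shorter than 15 nt risks spurious matches")
    hit_frags: set[int] = set()
    for chrom, seq in genome.sequences.items():
        sub = fragments[fragments["chrom"] == chrom]
        if sub.empty:
            continue
        starts = sub["start"].to_numpy()
        for pat in {primer, reverse_complement(primer)}:
            if max_mismatch == 0:
                occ: Iterable[int] = _occurrences(seq, pat)
            else:
                occ = _mismatch_occurrences(seq, pat, max_mismatch)
            for p in occ:
                k = int(np.searchsorted(starts, p, side="right")) - 1
                if k >= 0 and p < sub["end"].iloc[k]:
                    hit_frags.add(int(sub["frag_id"].iloc[k]))
    if not hit_frags:
        raise ValueError(f"primer not found in genome: {primer[:20]}...")
    if len(hit_frags) > 1:
        raise ValueError(f"ambiguous primer: matches fragments {sorted(hit_frags)}")
    fid = hit_frags.pop()
    row = fragments.loc[fid]
    return Viewpoint(
        name=name,
        primer=primer,
        chrom=str(row["chrom"]),
        fragment_index=fid,
        midpoint=float(row["midpoint"]),
    )


def fragment_distances(fragments: pd.DataFrame, viewpoint: Viewpoint) -> pd.Series:
    """Signed midpoint-to-midpoint distance to the viewpoint; NaN for trans.

    Negative distances are on the left of the viewpoint.  Fragments on
    other chromosomes ("trans") have no defined genomic distance.
    """
    d = pd.Series(np.nan, index=fragments.index, name="distance")
    cis = fragments["chrom"] == viewpoint.chrom
    d[cis] = fragments.loc[cis, "midpoint"] - viewpoint.midpoint
    return d


def write_fragment_tsv(fragments: pd.DataFrame, path) -> None:
    fragments.to_csv(path, sep="\t", index=False)


def write_fragment_bed(fragments: pd.DataFrame, path, valid_only: bool = True) -> None:
    sub = fragments[fragments["is_valid"]] if valid_only and "is_valid" in fragments else fragments
    sub = sub.sort_values(["chrom", "start"])
    with open(path, "w") as fh:
        for _, r in sub.iterrows():
            fh.write(f"{r['chrom']}\t{int(r['start'])}\t{int(r['end'])}\tfrag_{int(r['frag_id'])}\n")
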