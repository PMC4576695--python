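"""Synthetic 4C data: toy genomes, counts with known truth, and alignments.

The generator emulates the statistical structure of a 4C contact
profile: per-fragment means follow a power-law decay with genomic
distance from the viewpoint on top of a constant background,

    mu_ij = s_j * (A * (|d_i| / 1 kb)^-gamma + B) * 2^(spike_i + diff_{i,c(j)}),

with negative-binomial noise whose dispersion follows the same
two-parameter trend alpha(mu) = a/mu + b that the transform module
fits.  Trans fragments sit at the background level.  Spikes (specific
interactions) and differential effects are multiplicative on the mean,
i.e. additive in log2, matching the GLM effect parameterization.
Alignment records are emitted with exact 5' termini and strands obeying
the protocol rules, so fragment-end counting recovers the simulated
count matrix exactly; an optional fraction of decoy records violates
the rules to exercise the rejection paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fragments import Enzyme, Genome, Viewpoint, reverse_complement
from .reads import AlignmentRecord

DEFAULT_DECAY = dict(amplitude=5000.0, gamma=1.2, background=20.0)
DEFAULT_DISPERSION = dict(a=3.0, b=0.05)


@dataclass
class SimulationTruth:
    """Ground truth of a simulated dataset.

    amplitude is the decay mean at 1 kb from the viewpoint; gamma the
    power-law exponent; background the far-distance plateau mean.
    ``spikes`` maps fragment id -> log2 interaction effect; ``diffs``
    maps (fragment id, condition) -> log2 differential effect.
    """

    amplitude: float = DEFAULT_DECAY["amplitude"]
    gamma: float = DEFAULT_DECAY["gamma"]
    background: float = DEFAULT_DECAY["background"]
    a: float = DEFAULT_DISPERSION["a"]
    b: float = DEFAULT_DISPERSION["b"]
    size_factors: np.ndarray | None = None
    spikes: dict = field(default_factory=dict)
    diffs: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0: the decay must decrease with distance")


def _plant_clean_sequence(rng, length: int, planted: list[tuple[int, str]],
                          sites: list[str], max_rounds: int = 60) -> str:
    """Random sequence with the given motifs planted and no accidental sites."""
    seq = rng.choice(list("ACGT"), size=length)
    protected = np.zeros(length, dtype=bool)
    for pos, motif in planted:
        seq[pos : pos + len(motif)] = list(motif)
        protected[pos : pos + len(motif)] = True
    patterns = set()
    for s in sites:
        patterns.add(s)
        patterns.add(reverse_complement(s))
    for _ in range(max_rounds):
        text = "".join(seq)
        dirty = []
        for pat in patterns:
            start = text.find(pat)
            while start != -1:
                if not protected[start : start + len(pat)].all():
                    dirty.append((start, len(pat)))
                start = text.find(pat, start + 1)
        if not dirty:
            return text
        for start, ln in dirty:
            free = [i for i in range(start, start + ln) if not protected[i]]
            if not free:
                continue
            i = int(rng.choice(free))
            alternatives = [c for c in "ACGT" if c != seq[i]]
            seq[i] = alternatives[int(rng.integers(len(alternatives)))]
    raise RuntimeError("could not scrub accidental recognition sites")


def make_toy_genome(
    n_chrom: int = 1,
    length: int = 20000,
    first_site: str = "GATC",
    second_site: str = "CATG",
    site_spacing: int = 1000,
    seed: int = 0,
    primer_length: int = 20,
    end_margin: int = 25,
) -> tuple[Genome, dict]:
    """Toy genome with first-cutter sites planted at jittered spacing.

    One second-cutter site is planted inside each inter-site interval
    at least ``end_margin`` nt from both boundaries, so every fragment
    is valid for the default 20-nt end threshold.  Returns the genome
    and a truth dict with the planted positions per chromosome and a
    unique primer sequence taken from the central fragment of the first
    chromosome.
    """
    if second_site in first_site or first_site in second_site:
        raise ValueError("first and second recognition sites must not contain each other")
    if site_spacing < len(first_site) + len(second_site) + 2 * end_margin:
        raise ValueError("site_spacing too small for the recognition sites and margins")
    rng = np.random.default_rng(seed)
    sequences = {}
    truth: dict = {"first_sites": {}, "second_sites": {}}
    for c in range(n_chrom):
        chrom = f"chr{c + 1}"
        firsts = []
        pos = site_spacing // 2
        while pos + len(first_site) < length - site_spacing // 4:
            jitter = int(rng.integers(-site_spacing // 5, site_spacing // 5 + 1))
            p = max(pos + jitter, (firsts[-1] + len(first_site) + 2 * end_margin + len(second_site) + 2) if firsts else 0)
            if p + len(first_site) >= length:
                break
            firsts.append(p)
            pos += site_spacing
        seconds = []
        bounds = [0] + [p + len(first_site) for p in firsts] + [length]
        for lo, hi in zip(bounds[:-1], [p for p in firsts] + [length]):
            lo_ok = lo + end_margin
            hi_ok = hi - end_margin - len(second_site)
            if hi_ok > lo_ok:
                seconds.append(int(rng.integers(lo_ok, hi_ok + 1)))
        planted = [(p, first_site) for p in firsts] + [(p, second_site) for p in seconds]
        sequences[chrom] = _plant_clean_sequence(
            rng, length, planted, [first_site, second_site]
        )
        truth["first_sites"][chrom] = firsts
        truth["second_sites"][chrom] = seconds
    genome = Genome(sequences)
    # unique primer: taken from the middle of the central fragment of chr1
    firsts = truth["first_sites"]["chr1"]
    mid_cut = firsts[len(firsts) // 2]
    primer_start = mid_cut - primer_length - end_margin - len(second_site) - 2
    truth["primer"] = genome["chr1"][primer_start : primer_start + primer_length]
    return genome, truth


def make_toy_fragment_table(
    n_cis: int = 2000,
    spacing: int = 1000,
    n_trans: int = 0,
    seed: int = 0,
) -> tuple[pd.DataFrame, Viewpoint, pd.Series]:
    """Direct fragment-table construction (no genome) for count-level studies.

    Builds ``n_cis`` adjacent valid fragments of jittered ~``spacing``
    length on one chromosome with the viewpoint at the centre, plus
    optional trans fragments on a second chromosome.  Returns the
    annotated table, the viewpoint, and the signed distances.
    """
    rng = np.random.default_rng(seed)
    lens = rng.integers(int(spacing * 0.6), int(spacing * 1.4) + 1, size=n_cis + n_trans)
    rows = []
    pos = 0
    for i in range(n_cis):
        rows.append((i, "chr1", pos, pos + int(lens[i])))
        pos += int(lens[i])
    pos = 0
    for i in range(n_cis, n_cis + n_trans):
        rows.append((i, "chr2", pos, pos + int(lens[i])))
        pos += int(lens[i])
    tab = pd.DataFrame(rows, columns=["frag_id", "chrom", "start", "end"])
    tab["midpoint"] = (tab["start"] + tab["end"]) / 2.0
    tab["has_second_site"] = True
    tab["left_end_length"] = 30.0
    tab["right_end_length"] = 30.0
    tab["left_cut"] = tab["start"] + 30.0
    tab["right_cut"] = tab["end"] - 30.0
    tab["left_end_valid"] = True
    tab["right_end_valid"] = True
    tab["is_valid"] = True
    tab = tab.set_index("frag_id", drop=False).rename_axis(index=None)
    vp_id = n_cis // 2
    vp = Viewpoint(
        name="toy",
        primer="A" * 20,
        chrom="chr1",
        fragment_index=vp_id,
        midpoint=float(tab.loc[vp_id, "midpoint"]),
    )
    d = pd.Series(np.nan, index=tab.index, name="distance")
    cis = tab["chrom"] == "chr1"
    d[cis] = tab.loc[cis, "midpoint"] - vp.midpoint
    return tab, vp, d


def _nb_sample(rng, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB draw with Var = mu + alpha mu^2 (Poisson where alpha ~ 0)."""
    out = np.empty(mu.shape, dtype=np.int64)
    poisson = alpha < 1e-12
    if poisson.any():
        out[poisson] = rng.poisson(mu[poisson])
    nb = ~poisson
    if nb.any():
        r = 1.0 / alpha[nb]
        p = r / (r + mu[nb])
        out[nb] = rng.negative_binomial(r, p)
    return out


def simulate_counts(
    fragments: pd.DataFrame,
    viewpoint: Viewpoint,
    truth: SimulationTruth,
    n_replicates: int = 2,
    conditions: tuple = ("A", "B"),
    distances: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the fragments x samples count matrix.

    Returns ``(counts, sample_table)``; sample ids are
    ``{condition}_{replicate}``.  Distance enters the decay in kb,
    clamped at 0.5 kb so the viewpoint fragment itself gets a finite
    (very large) mean.  If ``truth.size_factors`` is None, per-sample
    factors are drawn log-uniform in [2^-0.5, 2^0.5] and normalized to
    unit geometric mean.
    """
    rng = np.random.default_rng(truth.seed)
    if distances is None:
        d = pd.Series(np.nan, index=fragments.index)
        cis = fragments["chrom"] == viewpoint.chrom
        d[cis] = fragments.loc[cis, "midpoint"] - viewpoint.midpoint
    else:
        d = distances.reindex(fragments.index)

    samples = [f"{c}_{r + 1}" for c in conditions for r in range(n_replicates)]
    cond_of = {s: s.rsplit("_", 1)[0] for s in samples}
    J = len(samples)
    if truth.size_factors is None:
        s = np.exp2(rng.uniform(-0.5, 0.5, size=J))
        s = s / np.exp(np.mean(np.log(s)))
    else:
        s = np.asarray(truth.size_factors, dtype=float)
        if len(s) != J:
            raise ValueError("size_factors length must match the number of samples")

    d_kb = np.maximum(np.abs(d.to_numpy()) / 1000.0, 0.5)
    base = truth.amplitude * d_kb ** (-truth.gamma) + truth.background
    base = np.where(np.isnan(d.to_numpy()), truth.background, base)

    log2_fx = np.zeros((len(fragments), J))
    for fid, eff in truth.spikes.items():
        log2_fx[fragments.index.get_loc(fid), :] += eff
    for (fid, cond), eff in truth.diffs.items():
        for j, smp in enumerate(samples):
            if cond_of[smp] == cond:
                log2_fx[fragments.index.get_loc(fid), j] += eff

    mu = s[None, :] * base[:, None] * np.exp2(log2_fx)
    alpha = truth.a / np.maximum(mu, 1e-12) + truth.b
    counts = _nb_sample(rng, mu, alpha)
    counts_df = pd.DataFrame(counts, index=fragments.index, columns=samples)
    sample_table = pd.DataFrame(
        {
            "sample": samples,
            "condition": [cond_of[smp] for smp in samples],
            "replicate": [int(smp.rsplit("_", 1)[1]) for smp in samples],
        }
    ).set_index("sample", drop=False).rename_axis(index=None)
    return counts_df, sample_table


def simulate_alignments(
    fragments: pd.DataFrame,
    counts: pd.Series,
    protocol: str = "first_cutter_primer",
    read_length: int = 30,
    decoy_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[list[AlignmentRecord], int]:
    """Emit alignment records reproducing ``counts`` under the protocol rules.

    Each fragment's count is split between its two ends; records carry
    the exact 5' terminus and strand the counting rules require.  A
    ``decoy_fraction`` of additional records violates the start rule
    (shifted terminus) or the strand rule and must be rejected by the
    counter.  Returns ``(records, n_decoys)``.
    """
    rng = np.random.default_rng(seed)
    chrom_len = fragments.groupby("chrom")["end"].max().to_dict()
    records: list[AlignmentRecord] = []
    n_decoys = 0

    # every legal (chrom, 5'-terminus, strand) under either protocol: decoys
    # must avoid them all, or a "wrong" read could still be countable (e.g.
    # a flipped strand at a shared boundary matches the neighbouring
    # fragment's end)
    anchor_keys: set[tuple[str, int, str]] = set()
    for row in fragments.itertuples():
        anchor_keys.add((row.chrom, int(row.start), "+"))
        anchor_keys.add((row.chrom, int(row.end), "-"))
        if bool(getattr(row, "has_second_site", False)):
            anchor_keys.add((row.chrom, int(row.left_cut), "-"))
            anchor_keys.add((row.chrom, int(row.right_cut), "+"))

    def emit(chrom, five_prime, strand):
        L = chrom_len[chrom]
        if strand == "+":
            start = five_prime
            end = min(five_prime + read_length, L)
        else:
            end = five_prime
            start = max(five_prime - read_length, 0)
        if end <= start:
            return None
        return AlignmentRecord(chrom=chrom, start=int(start), end=int(end), strand=strand)

    for row in fragments.itertuples():
        c = int(counts.get(row.frag_id, 0))
        if c == 0:
            continue
        if protocol == "first_cutter_primer":
            anchors = [(int(row.start), "+"), (int(row.end), "-")]
        else:
            if not bool(getattr(row, "has_second_site", False)):
                continue
            anchors = [(int(row.left_cut), "-"), (int(row.right_cut), "+")]
        n_left = int(rng.binomial(c, 0.5))
        for (coord, strand), n_here in zip(anchors, (n_left, c - n_left)):
            for _ in range(n_here):
                rec = emit(row.chrom, coord, strand)
                if rec is not None:
                    records.append(rec)
                if rng.random() < decoy_fraction:
                    bad = None
                    for _attempt in range(20):
                        shift = int(rng.integers(3, 50)) * (1 if rng.random() < 0.5 else -1)
                        bad_strand = strand if rng.random() < 0.5 else ("-" if strand == "+" else "+")
                        bad_coord = max(coord + shift, 1)
                        if (row.chrom, bad_coord, bad_strand) in anchor_keys:
                            continue
                        bad = emit(row.chrom, bad_coord, bad_strand)
                        break
                    if bad is not None:
                        records.append(bad)
                        n_decoys += 1
    order = rng.permutation(len(records))
    return [records[i] for i in order], n_decoys


def write_bam(records: list[AlignmentRecord], fragments: pd.DataFrame, path,
              read_length: int = 30) -> None:
    """Write records to a coordinate-sorted, indexed BAM file."""
    import pysam

    chrom_len = fragments.groupby("chrom")["end"].max().to_dict()
    chroms = list(chrom_len)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": int(chrom_len[c])} for c in chroms],
    }
    tmp = str(path) + ".unsorted.bam"
    with pysam.AlignmentFile(tmp, "wb", header=header) as bam:
        for i, rec in enumerate(records):
            a = pysam.AlignedSegment(bam.header)
            a.query_name = f"read_{i}"
            a.reference_id = chroms.index(rec.chrom)
            a.reference_start = rec.start
            a.mapping_quality = rec.mapq
            a.is_reverse = rec.strand == "-"
            span = rec.end - rec.start
            a.query_sequence = "A" * span
            a.cigarstring = f"{span}M"
            a.flag |= 16 if rec.strand == "-" else 0
            bam.write(a)
    pysam.sort("-o", str(path), tmp)
    pysam.index(str(path))
    import os

    os.remove(tmp)
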