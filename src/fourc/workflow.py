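"""On-disk workflow: staged execution with TSV/BED/bedGraph artifacts.

Each stage reads the artifacts of its upstream stages from the output
directory and writes its own, so stages can be re-run individually; all
outputs are deterministic functions of the inputs and configuration.
"""

from __future__ import annotations

import json
import logging
import os

import numpy as np
import pandas as pd

from . import calling, decay, io, reads, vst
from .fragments import (Genome, annotate_ends, digest_genome,
                        fragment_distances, locate_viewpoint,
                        write_fragment_bed, write_fragment_tsv)
from .io import RunConfig
from .pipeline import AnalysisConfig, analyze_viewpoint, differential_analysis

log = logging.getLogger("fourc")

STAGES = ("digest", "count", "fit", "call", "diff", "export")


def _vp_path(cfg: RunConfig, stem: str, vp_name: str, ext: str = "tsv") -> str:
    return os.path.join(cfg.out_dir, f"{stem}_{vp_name}.{ext}")


def run_digest(cfg: RunConfig) -> dict:
    genome = Genome.from_fasta(cfg.genome)
    out = {}
    for vp_cfg in cfg.viewpoints:
        frags = digest_genome(genome, vp_cfg.first_enzyme)
        frags = annotate_ends(frags, genome, vp_cfg.second_enzyme, cfg.min_end_length)
        vp = locate_viewpoint(vp_cfg.primer, genome, frags, name=vp_cfg.name)
        frags["distance"] = fragment_distances(frags, vp)
        frags["is_viewpoint"] = frags["frag_id"] == vp.fragment_index
        write_fragment_tsv(frags, _vp_path(cfg, "fragments", vp_cfg.name))
        write_fragment_bed(frags, _vp_path(cfg, "valid_fragments", vp_cfg.name, "bed"))
        log.info("digest[%s]: %d fragments, %d valid, viewpoint fragment %d",
                 vp_cfg.name, len(frags), int(frags["is_valid"].sum()), vp.fragment_index)
        out[vp_cfg.name] = (frags, vp)
    return out


def _load_fragments(cfg: RunConfig, vp_name: str) -> pd.DataFrame:
    path = _vp_path(cfg, "fragments", vp_name)
    if not os.path.exists(path):
        raise FileNotFoundError(f"missing {path}: run the 'digest' stage first")
    frags = pd.read_csv(path, sep="\t")
    return frags.set_index("frag_id", drop=False).rename_axis(index=None)


def _viewpoint_from_fragments(cfg, vp_cfg, frags):
    from .fragments import Viewpoint

    row = frags[frags["is_viewpoint"]].iloc[0]
    return Viewpoint(name=vp_cfg.name, primer=vp_cfg.primer, chrom=row["chrom"],
                     fragment_index=int(row["frag_id"]), midpoint=float(row["midpoint"]))


def run_count(cfg: RunConfig) -> dict:
    out = {}
    for vp_cfg in cfg.viewpoints:
        frags = _load_fragments(cfg, vp_cfg.name)
        cols, qcs = {}, {}
        for smp in cfg.samples.itertuples():
            counts, qc = reads.count_bam(
                smp.bam, frags, protocol=vp_cfg.protocol, slack=cfg.slack
            )
            qc["valid_fraction"] = reads.qc_valid_fraction(qc)
            cols[smp.sample] = counts
            qcs[smp.sample] = qc
            log.info("count[%s/%s]: %s", vp_cfg.name, smp.sample, qc)
        mat = reads.assemble_count_matrix(cols, frags, valid_only=True)
        mat.insert(0, "frag_id", mat.index)
        mat.to_csv(_vp_path(cfg, "counts", vp_cfg.name), sep="\t", index=False)
        pd.DataFrame(qcs).T.rename_axis("sample").reset_index().to_csv(
            _vp_path(cfg, "qc", vp_cfg.name), sep="\t", index=False
        )
        out[vp_cfg.name] = mat.drop(columns="frag_id")
    return out


def _load_counts(cfg: RunConfig, vp_name: str) -> pd.DataFrame:
    path = _vp_path(cfg, "counts", vp_name)
    if not os.path.exists(path):
        raise FileNotFoundError(f"missing {path}: run the 'count' stage first")
    mat = pd.read_csv(path, sep="\t")
    return mat.set_index("frag_id").rename_axis(index=None)


def run_call(cfg: RunConfig) -> dict:
    out = {}
    acfg = AnalysisConfig(
        min_median=cfg.min_median, z_thresh=cfg.z_thresh, padj_thresh=cfg.padj_thresh,
        fit_mode=cfg.fit_mode, lam=cfg.lam,
    )
    for vp_cfg in cfg.viewpoints:
        frags = _load_fragments(cfg, vp_cfg.name)
        vp = _viewpoint_from_fragments(cfg, vp_cfg, frags)
        counts = _load_counts(cfg, vp_cfg.name)
        res = analyze_viewpoint(
            counts, frags, vp, cfg.samples,
            distances=frags["distance"], config=acfg,
        )
        tab = calling.results_table(frags, res.distances, res.z, res.p, res.padj, res.calls)
        tab.insert(0, "frag_id", tab.index)
        tab.to_csv(_vp_path(cfg, "results", vp_cfg.name), sep="\t", index=False)
        vmat = res.v_matrix.copy()
        vmat.insert(0, "frag_id", vmat.index)
        vmat.to_csv(_vp_path(cfg, "vst", vp_cfg.name), sep="\t", index=False)
        d_cis = res.distances.dropna().abs()
        grid = decay.export_fit_grid(res.fit, max(d_cis[d_cis > 0].min(), 1.0), d_cis.max())
        grid.to_csv(_vp_path(cfg, "fit", vp_cfg.name), sep="\t", index=False)
        io.write_calls_bed(frags, res.calls, _vp_path(cfg, "calls", vp_cfg.name, "bed"),
                           vp_cfg.name)
        log.info("call[%s]: %d tested fragments, %d masked, sigma=%s, calls=%s",
                 vp_cfg.name, len(res.tested), len(res.masked),
                 res.sigma.round(3).to_dict(), res.calls.sum().to_dict())
        out[vp_cfg.name] = res
    return out


def run_diff(cfg: RunConfig, results: dict | None = None,
             contrast: tuple[str, str] | None = None) -> dict:
    out = {}
    if results is None:
        results = run_call(cfg)
    conds = list(pd.unique(cfg.samples["condition"]))
    if contrast is None:
        if len(conds) < 2:
            raise ValueError("differential testing needs >= 2 conditions")
        contrast = (conds[1], conds[0])
    for vp_cfg in cfg.viewpoints:
        counts = _load_counts(cfg, vp_cfg.name)
        res, flags = differential_analysis(counts, results[vp_cfg.name], contrast,
                                           padj_thresh=cfg.padj_thresh)
        tab = res.table.join(flags)
        tab.insert(0, "frag_id", tab.index)
        tab.to_csv(_vp_path(cfg, "differential", vp_cfg.name), sep="\t", index=False)
        log.info("diff[%s]: contrast %s vs %s, %d significant",
                 vp_cfg.name, contrast[0], contrast[1], int(flags["differential"].sum()))
        out[vp_cfg.name] = (res, flags)
    return out


def run_export(cfg: RunConfig, results: dict | None = None) -> None:
    if results is None:
        results = run_call(cfg)
    for vp_cfg in cfg.viewpoints:
        frags = _load_fragments(cfg, vp_cfg.name)
        res = results[vp_cfg.name]
        chrom_sizes = frags.groupby("chrom")["end"].max().to_dict()
        for sample in res.v_matrix.columns:
            intervals = frags.loc[res.v_matrix.index]
            stem = os.path.join(cfg.out_dir, f"track_{vp_cfg.name}_{sample}")
            io.write_bedgraph(intervals, res.v_matrix[sample], stem + ".bedGraph",
                              track_name=f"{vp_cfg.name}:{sample}")
            io.write_bigwig(intervals, res.v_matrix[sample], stem + ".bw", chrom_sizes)


def run_pipeline(cfg: RunConfig, stages=STAGES) -> None:
    """Execute the requested stages in dependency order."""
    os.makedirs(cfg.out_dir, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    with open(os.path.join(cfg.out_dir, "run_config.json"), "w") as fh:
        json.dump(
            {
                k: getattr(cfg, k)
                for k in ("genome", "out_dir", "min_end_length", "min_median",
                          "z_thresh", "padj_thresh", "slack", "lam", "fit_mode", "seed")
            },
            fh, indent=2,
        )
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}; choose from {STAGES}")
    ordered = [s for s in STAGES if s in stages]
    # "fit" runs the same computation as "call" (the decay fit and the call
    # artifacts are written together); avoid running it twice
    if "fit" in ordered and "call" in ordered:
        ordered.remove("fit")
    results = None
    for stage in ordered:
        if stage == "digest":
            run_digest(cfg)
        elif stage == "count":
            run_count(cfg)
        elif stage in ("fit", "call"):
            results = run_call(cfg)
        elif stage == "diff":
            run_diff(cfg, results)
        elif stage == "export":
            run_export(cfg, results)
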