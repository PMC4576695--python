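"""Configuration parsing and track/table export."""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .fragments import Enzyme


@dataclass
class ViewpointConfig:
    name: str
    primer: str
    first_enzyme: Enzyme
    second_enzyme: Enzyme
    protocol: str = "first_cutter_primer"


@dataclass
class RunConfig:
    """Validated run configuration (YAML file + CLI overrides)."""

    genome: str
    viewpoints: list[ViewpointConfig]
    samples: pd.DataFrame  # sample, condition, replicate, bam
    out_dir: str = "fourc_out"
    min_end_length: int = 20
    min_median: float = 40.0
    z_thresh: float = 3.0
    padj_thresh: float = 0.01
    slack: int = 0
    lam: float = 1.0
    fit_mode: str = "symmetric"
    seed: int = 0

    def validate(self, check_files: bool = True) -> None:
        if self.min_end_length <= 0 or self.min_median < 0 or self.z_thresh <= 0:
            raise ValueError("thresholds must be positive")
        if not 0 < self.padj_thresh < 1:
            raise ValueError("padj_thresh must be in (0, 1)")
        if self.samples["condition"].eq("").any():
            raise ValueError("condition labels must be non-empty")
        if check_files:
            missing = [self.genome] if not os.path.exists(self.genome) else []
            missing += [b for b in self.samples["bam"] if b and not os.path.exists(b)]
            if missing:
                raise FileNotFoundError(f"missing input files: {missing}")


def _enzyme_from_dict(name: str, spec: dict) -> Enzyme:
    return Enzyme(name=name, site=spec["site"], cut_offset=int(spec.get("cut_offset", 0)))


def load_config(path, check_files: bool = True) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    vps = [
        ViewpointConfig(
            name=v["name"],
            primer=v["primer"],
            first_enzyme=_enzyme_from_dict(v["first_enzyme"].get("name", "first"), v["first_enzyme"]),
            second_enzyme=_enzyme_from_dict(v["second_enzyme"].get("name", "second"), v["second_enzyme"]),
            protocol=v.get("protocol", "first_cutter_primer"),
        )
        for v in raw["viewpoints"]
    ]
    samples = pd.DataFrame(raw["samples"])
    samples = samples.set_index("sample", drop=False).rename_axis(index=None)
    cfg = RunConfig(
        genome=raw["genome"],
        viewpoints=vps,
        samples=samples,
        out_dir=raw.get("out_dir", "fourc_out"),
        **{
            k: raw[k]
            for k in (
                "min_end_length", "min_median", "z_thresh", "padj_thresh",
                "slack", "lam", "fit_mode", "seed",
            )
            if k in raw
        },
    )
    cfg.validate(check_files=check_files)
    return cfg


def write_bedgraph(intervals: pd.DataFrame, values, path, track_name: str | None = None) -> None:
    """Write a bedGraph over fragment intervals (sorted by chrom, start)."""
    df = intervals[["chrom", "start", "end"]].copy()
    df["value"] = np.asarray(values, dtype=float)
    df = df.sort_values(["chrom", "start"])
    with open(path, "w") as fh:
        if track_name:
            fh.write(f'track type=bedGraph name="{track_name}"\n')
        for r in df.itertuples():
            fh.write(f"{r.chrom}\t{int(r.start)}\t{int(r.end)}\t{r.value:.4f}\n")


def read_bedgraph(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "#")):
                continue
            chrom, start, end, value = line.split("\t")
            rows.append((chrom, int(start), int(end), float(value)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def write_bigwig(intervals: pd.DataFrame, values, path, chrom_sizes: dict) -> bool:
    """Write a bigWig track; returns False (with a warning) if no writer."""
    try:
        import pyBigWig
    except ImportError:
        warnings.warn("pyBigWig not available; skipping bigWig export", stacklevel=2)
        return False
    df = intervals[["chrom", "start", "end"]].copy()
    df["value"] = np.asarray(values, dtype=float)
    df = df.sort_values(["chrom", "start"])
    bw = pyBigWig.open(str(path), "w")
    bw.addHeader([(c, int(l)) for c, l in chrom_sizes.items()])
    bw.addEntries(
        df["chrom"].tolist(),
        df["start"].astype(int).tolist(),
        ends=df["end"].astype(int).tolist(),
        values=df["value"].tolist(),
    )
    bw.close()
    return True


def write_calls_bed(fragments: pd.DataFrame, calls: pd.DataFrame, path,
                    viewpoint_name: str) -> None:
    """Called fragments as BED: one record per (fragment, condition)."""
    rows = []
    for cond in calls.columns:
        for fid in calls.index[calls[cond]]:
            r = fragments.loc[fid]
            rows.append((r["chrom"], int(r["start"]), int(r["end"]),
                         f"{viewpoint_name}:{cond}"))
    rows.sort()
    with open(path, "w") as fh:
        for chrom, start, end, name in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")
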