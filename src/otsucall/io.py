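"""Plain-text readers and writers (TSV / BED dialects).

All TSVs carry a header line; genomic coordinates in TSV output are 1-based
inclusive, BED output is 0-based half-open.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classify import CNVCall
from .profile import RDProfile
from .simulate import SimTruth

__all__ = [
    "write_rd_tsv",
    "write_diff_tsv",
    "read_rd_tsv",
    "write_calls_tsv",
    "read_calls_tsv",
    "write_calls_bed",
    "write_truth_tsv",
    "read_truth_tsv",
]

_FLOAT_FMT = "%.6g"


def write_rd_tsv(path, profiles) -> None:
    """Write one or more profiles as ``chrom<TAB>start<TAB>rd`` (1-based starts)."""
    if isinstance(profiles, RDProfile):
        profiles = [profiles]
    frames = []
    for p in profiles:
        frames.append(pd.DataFrame({
            "chrom": p.chrom,
            "start": p.bin_starts() + 1,
            "rd": p.values,
        }))
    df = pd.concat(frames) if frames else pd.DataFrame(columns=["chrom", "start", "rd"])
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_rd_tsv(path, bin_size: int | None = None) -> list:
    """Read an RD TSV back into per-chromosome profiles.

    The bin size is inferred per chromosome as the smallest start spacing
    (bins missing from the grid are marked masked); pass ``bin_size``
    explicitly for single-bin chromosomes.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "rd"}
    if not required.issubset(df.columns):
        raise ValueError(f"RD TSV must have columns {sorted(required)}")
    profiles = []
    for chrom, grp in df.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy(dtype=np.int64) - 1
        order = np.argsort(starts, kind="stable")
        starts, rd = starts[order], grp["rd"].to_numpy(dtype=float)[order]
        if bin_size is not None:
            bs = bin_size
        elif starts.size > 1:
            bs = int(np.diff(starts).min())
        else:
            raise ValueError(
                f"cannot infer bin size for single-bin chromosome {chrom!r}; "
                "pass bin_size")
        if bs < 1 or np.any(starts % bs):
            raise ValueError(f"bin starts of {chrom!r} not on a {bs} bp grid")
        n_total = int(starts[-1] // bs) + 1
        mask = np.ones(n_total, dtype=bool)
        mask[starts // bs] = False
        profiles.append(RDProfile(str(chrom), bs, rd, mask))
    return profiles


def write_diff_tsv(path, segmentation) -> None:
    """Segmentation diagnostics: per boundary position, the Diff value, the
    boxplot fence and whether a breakpoint was placed there (for plotting)."""
    lower, upper = segmentation.bounds
    positions = np.arange(1, segmentation.diff.size + 1)
    bp = np.zeros(positions.size, dtype=bool)
    idx = np.asarray(segmentation.breakpoints, dtype=int)
    bp[idx - 1] = True
    pd.DataFrame({
        "position": positions,
        "diff": segmentation.diff,
        "upper_limit": upper,
        "lower_limit": lower,
        "is_breakpoint": bp.astype(int),
    }).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_calls_tsv(path, calls) -> None:
    """Write calls as ``chrom start end type rd_mean`` (1-based inclusive)."""
    df = pd.DataFrame(
        [(c.chrom, c.start, c.end, c.type, c.rd_mean) for c in calls],
        columns=["chrom", "start", "end", "type", "rd_mean"],
    )
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_calls_tsv(path) -> list:
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "type"}
    if not required.issubset(df.columns):
        raise ValueError(f"calls TSV must have columns {sorted(required)}")
    return [
        CNVCall(str(r.chrom), int(r.start), int(r.end), str(r.type),
                float(getattr(r, "rd_mean", 0.0)))
        for r in df.itertuples(index=False)
    ]


def write_calls_bed(path, calls) -> None:
    """BED (0-based half-open): chrom, start, end, type."""
    df = pd.DataFrame(
        [(c.chrom, c.start - 1, c.end, c.type) for c in calls],
    )
    df.to_csv(path, sep="\t", index=False, header=False)


def write_truth_tsv(path, truth: SimTruth) -> None:
    """Ground-truth track as ``chrom start end copy_number type`` (1-based)."""
    df = pd.DataFrame(
        [(truth.chrom, e.start, e.end, e.copy_number, e.type) for e in truth.events],
        columns=["chrom", "start", "end", "copy_number", "type"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_truth_tsv(path):
    """Read a truth TSV back into (chrom, start, end, type) tuples."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end"}
    if not required.issubset(df.columns):
        raise ValueError(f"truth TSV must have columns {sorted(required)}")
    out = []
    for r in df.itertuples(index=False):
        typ = str(getattr(r, "type", "."))
        out.append((str(r.chrom), int(r.start), int(r.end), typ))
    return out
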