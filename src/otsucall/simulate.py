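"""Synthetic read-depth profiles with ground-truth CNVs, and call scoring.

The simulator emulates a whole-genome sequencing experiment at the binned
read-depth level: per-bin read counts are Poisson with mean

    bin_size * coverage * (c / 2) / read_length

where ``c`` is the bin's true copy number (2 outside events), and the read
depth is ``count * read_length / bin_size`` so copy-neutral bins average the
fold-coverage. Events draw lengths from 3,000-50,000 bp and copy numbers
from {0, 1, 3, 4} (homozygous/heterozygous loss, single/double gain) and are
placed uniformly without overlap, at least one bin apart and 10 bins from
the chromosome ends.

Scoring is position-wise: TP is the number of genomic positions shared by
declared and true CNVs, PP the positions declared, P the positions true;
precision = TP/PP, sensitivity = TP/P, F1 their harmonic mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profile import RDProfile

__all__ = [
    "SimConfig",
    "TruthEvent",
    "SimTruth",
    "EvalResult",
    "simulate_rd_profile",
    "evaluate_calls",
    "run_benchmark",
]

LENGTH_RANGE = (3000, 50000)
COPY_NUMBERS = (0, 1, 3, 4)
END_MARGIN_BINS = 10


@dataclass
class SimConfig:
    """Design of one simulated chromosome.

    ``events`` may be given explicitly as ``(start0, length, copy_number)``
    triples (0-based start); otherwise ``n_events`` events are placed
    uniformly at random.
    """

    genome_length: int = 30_000_000
    coverage: float = 2.0
    bin_size: int = 1000
    read_length: int = 100
    n_events: int = 20
    length_range: tuple = LENGTH_RANGE
    copy_numbers: tuple = COPY_NUMBERS
    seed: int = 0
    chrom: str = "sim1"
    dispersion: float | None = None  # negative-binomial size; None = Poisson
    events: list | None = None

    def __post_init__(self) -> None:
        if self.genome_length < self.bin_size:
            raise ValueError("genome shorter than one bin")
        if self.coverage <= 0 or self.read_length < 1 or self.bin_size < 1:
            raise ValueError("coverage, read_length and bin_size must be positive")
        lo, hi = self.length_range
        if not 0 < lo <= hi:
            raise ValueError(f"invalid length_range {self.length_range}")


@dataclass
class TruthEvent:
    """One true CNV (1-based inclusive coordinates)."""

    start: int
    end: int
    copy_number: int
    type: str


@dataclass
class SimTruth:
    """Ground-truth CNV track of a simulated chromosome."""

    chrom: str
    genome_length: int
    bin_size: int
    events: list

    def intervals(self) -> list:
        return [(self.chrom, e.start, e.end, e.type) for e in self.events]

    def bin_copy(self) -> np.ndarray:
        """Length-weighted mean copy number of each bin."""
        return _bin_copy(self.genome_length // self.bin_size, self.bin_size,
                         [(e.start - 1, e.end - e.start + 1, e.copy_number)
                          for e in self.events])


@dataclass
class EvalResult:
    """Position-level confusion counts and derived metrics."""

    tp: int
    pp: int
    p: int
    precision: float
    sensitivity: float
    f1: float

    @classmethod
    def from_counts(cls, tp: int, pp: int, p: int) -> "EvalResult":
        prec = tp / pp if pp else 0.0
        sens = tp / p if p else 0.0
        f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
        return cls(tp, pp, p, prec, sens, f1)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _place_events(rng: np.random.Generator, cfg: SimConfig) -> list:
    margin = END_MARGIN_BINS * cfg.bin_size
    lo, hi = cfg.length_range
    placed = []  # (start0, length, cn), kept sorted
    attempts = 0
    while len(placed) < cfg.n_events:
        attempts += 1
        if attempts > 1000 * max(cfg.n_events, 1):
            raise RuntimeError(
                f"could not place {cfg.n_events} non-overlapping events in "
                f"{cfg.genome_length} bp"
            )
        length = int(rng.integers(lo, hi + 1))
        cn = int(rng.choice(cfg.copy_numbers))
        max_start = cfg.genome_length - margin - length
        if max_start <= margin:
            raise ValueError("genome too short for requested event lengths")
        start = int(rng.integers(margin, max_start + 1))
        # require at least one bin between events so each bin sees one event
        gap = cfg.bin_size
        if any(start < s + l + gap and s < start + length + gap
               for s, l, _ in placed):
            continue
        placed.append((start, length, cn))
    placed.sort()
    return placed


def _bin_copy(n_bins: int, bin_size: int, events) -> np.ndarray:
    c = np.full(n_bins, 2.0)
    for start, length, cn in events:
        end = start + length
        b0, b1 = start // bin_size, (end - 1) // bin_size
        b1 = min(b1, n_bins - 1)
        bins = np.arange(b0, b1 + 1)
        ov = np.minimum(end, (bins + 1) * bin_size) - np.maximum(start, bins * bin_size)
        c[b0 : b1 + 1] += (cn - 2) * ov / bin_size
    return c


def simulate_rd_profile(config: SimConfig):
    """Generate one (RDProfile, SimTruth) pair from a seeded design.

    Raises on overlapping explicitly-specified events.
    """
    rng = np.random.default_rng(config.seed)
    if config.events is not None:
        events = sorted((int(s), int(l), int(cn)) for s, l, cn in config.events)
        for (s1, l1, _), (s2, _, _) in zip(events, events[1:]):
            if s2 < s1 + l1:
                raise ValueError("overlapping events")
        for s, l, _ in events:
            if s < 0 or s + l > config.genome_length:
                raise ValueError("event outside genome")
    else:
        events = _place_events(rng, config)

    n_bins = config.genome_length // config.bin_size
    c = _bin_copy(n_bins, config.bin_size, events)
    lam = config.bin_size * config.coverage * (c / 2.0) / config.read_length
    if config.dispersion is None:
        counts = rng.poisson(lam)
    else:
        r = config.dispersion
        with np.errstate(divide="ignore", invalid="ignore"):
            pnb = np.where(lam > 0, r / (r + lam), 1.0)
        counts = np.where(lam > 0, rng.negative_binomial(r, pnb), 0)
    rd = counts * config.read_length / config.bin_size
    profile = RDProfile(config.chrom, config.bin_size, rd)
    truth = SimTruth(
        config.chrom,
        config.genome_length,
        config.bin_size,
        [TruthEvent(s + 1, s + l, cn, "gain" if cn > 2 else "loss")
         for s, l, cn in events],
    )
    return profile, truth


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def _merged_length(intervals) -> int:
    """Total positions covered by 1-based inclusive intervals."""
    if not intervals:
        return 0
    ivs = sorted((s, e + 1) for s, e in intervals)
    total, cur_s, cur_e = 0, *ivs[0]
    for s, e in ivs[1:]:
        if s > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    return total + (cur_e - cur_s)


def _intersection_length(a, b) -> int:
    """Positions covered by both interval sets (each 1-based inclusive)."""
    if not a or not b:
        return 0
    aa = _merge(sorted((s, e + 1) for s, e in a))
    bb = _merge(sorted((s, e + 1) for s, e in b))
    total, i, j = 0, 0, 0
    while i < len(aa) and j < len(bb):
        s = max(aa[i][0], bb[j][0])
        e = min(aa[i][1], bb[j][1])
        if s < e:
            total += e - s
        if aa[i][1] < bb[j][1]:
            i += 1
        else:
            j += 1
    return total


def _merge(half_open):
    out = []
    for s, e in half_open:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _as_intervals(obj):
    """Normalize calls / truth to (chrom, start, end, type) tuples."""
    if isinstance(obj, SimTruth):
        return obj.intervals()
    out = []
    for item in obj:
        if hasattr(item, "chrom"):
            out.append((item.chrom, item.start, item.end, getattr(item, "type", ".")))
        else:
            chrom, start, end = item[0], int(item[1]), int(item[2])
            typ = item[3] if len(item) > 3 else "."
            out.append((chrom, start, end, typ))
    return out


def evaluate_calls(calls, truth, match_type: bool = False) -> EvalResult:
    """Position-level precision / sensitivity / F1 of a call set against truth.

    Each genomic position is counted once. With ``match_type`` true positives
    are restricted to positions where the declared and true types agree.
    """
    call_iv = _as_intervals(calls)
    truth_iv = _as_intervals(truth)

    def keyed(ivs):
        groups: dict = {}
        for chrom, s, e, t in ivs:
            key = (chrom, t) if match_type else (chrom,)
            groups.setdefault(key, []).append((s, e))
        return groups

    gc, gt = keyed(call_iv), keyed(truth_iv)
    pp = sum(_merged_length(v) for v in gc.values())
    p = sum(_merged_length(v) for v in gt.values())
    tp = sum(_intersection_length(gc[k], gt[k]) for k in gc.keys() & gt.keys())
    return EvalResult.from_counts(tp, pp, p)


# ---------------------------------------------------------------------------
# benchmark
# ---------------------------------------------------------------------------

def run_benchmark(
    coverages,
    replicates: int,
    *,
    genome_length: int = 30_000_000,
    n_events: int = 20,
    bin_size: int = 1000,
    read_length: int = 100,
    seed: int = 0,
    detector_params: dict | None = None,
    match_type: bool = False,
    out_path=None,
) -> pd.DataFrame:
    """Full-pipeline precision/sensitivity/F1 averaged over seeded replicates.

    One row per coverage; replicate seeds are derived deterministically from
    the master seed. Optionally writes the summary as TSV.
    """
    from .estimators import CNVDetector

    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    detector_params = detector_params or {}
    rows = []
    for ci, cov in enumerate(coverages):
        metrics = np.zeros(3)
        for rep in range(replicates):
            child = int(np.random.SeedSequence([seed, ci, rep]).generate_state(1)[0]
                        % (2 ** 31))
            cfg = SimConfig(genome_length=genome_length, coverage=cov,
                            bin_size=bin_size, read_length=read_length,
                            n_events=n_events, seed=child)
            profile, truth = simulate_rd_profile(cfg)
            det = CNVDetector(bin_size=bin_size, **detector_params).fit(profile)
            res = evaluate_calls(det.calls_, truth, match_type=match_type)
            metrics += (res.precision, res.sensitivity, res.f1)
        metrics /= replicates
        rows.append({"coverage": cov, "precision": metrics[0],
                     "sensitivity": metrics[1], "f1": metrics[2],
                     "replicates": replicates})
    df = pd.DataFrame(rows)
    if out_path is not None:
        df.to_csv(out_path, sep="\t", index=False, float_format="%.6g")
    return df
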