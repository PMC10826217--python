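"""From alignments + reference to a clean, GC-corrected read-depth profile.

Pipeline: per-base coverage -> fixed-width binning -> removal of bins that
overlap unassembled (N) reference sequence -> GC-bias correction by
stratum-wise rescaling (each bin scaled by the ratio of the global mean RD
to the mean RD of all bins sharing its GC percentage).
"""

from __future__ import annotations

import logging

import numpy as np

from .profile import RDProfile

logger = logging.getLogger(__name__)

__all__ = [
    "bin_read_depth",
    "count_coverage",
    "mask_illegal_bins",
    "correct_gc_bias",
    "gc_fraction_per_bin",
    "profile_from_bam",
]


def bin_read_depth(per_base_counts, bin_size: int, chrom: str = "seq") -> RDProfile:
    """Average per-base read counts over non-overlapping fixed-width bins.

    A trailing partial bin shorter than ``bin_size`` is dropped to avoid a
    systematically biased final value.
    """
    if bin_size < 1:
        raise ValueError(f"bin_size must be positive, got {bin_size}")
    counts = np.asarray(per_base_counts, dtype=float)
    if counts.size == 0:
        raise ValueError("empty contig")
    if counts.size < bin_size:
        raise ValueError(
            f"contig of length {counts.size} shorter than one bin ({bin_size})"
        )
    if counts.min() < 0:
        raise ValueError("per-base counts must be non-negative")
    n_bins = counts.size // bin_size
    values = counts[: n_bins * bin_size].reshape(n_bins, bin_size).mean(axis=1)
    return RDProfile(chrom=chrom, bin_size=bin_size, values=values)


def count_coverage(
    bam_path,
    chrom: str,
    *,
    include_duplicates: bool = False,
    include_secondary: bool = False,
) -> np.ndarray:
    """Per-base coverage: number of reads whose aligned span covers each position.

    Requires a coordinate-sorted, indexed BAM. Secondary, supplementary and
    duplicate-flagged reads are excluded by default.
    """
    import pysam

    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        try:
            bam.check_index()
        except (ValueError, AttributeError) as exc:
            raise FileNotFoundError(
                f"BAM index not found for {bam_path}; expected {bam_path}.bai "
                "(run `samtools index`)"
            ) from exc
        if chrom not in bam.references:
            raise ValueError(f"chromosome {chrom!r} not in BAM header")
        length = bam.get_reference_length(chrom)
        counts = np.zeros(length, dtype=np.int64)
        for read in bam.fetch(chrom):
            if read.is_unmapped or read.reference_start is None:
                continue
            if not include_secondary and (read.is_secondary or read.is_supplementary):
                continue
            if not include_duplicates and read.is_duplicate:
                continue
            end = read.reference_end
            if end is None:
                continue
            counts[read.reference_start : end] += 1
    return counts


def mask_illegal_bins(
    profile: RDProfile, reference_bases, n_threshold: float = 0.0
) -> RDProfile:
    """Remove bins whose fraction of N (or other non-ACGT) bases exceeds a threshold.

    With the default threshold of 0 any N base masks its bin. Retained bins
    keep their values untouched; the mask records removed bins so genomic
    coordinates stay recoverable.
    """
    seq = str(reference_bases).upper()
    needed = profile.n_bins_total * profile.bin_size
    if len(seq) < needed:
        raise ValueError(
            f"reference of length {len(seq)} does not cover {profile.n_bins_total} "
            f"bins of {profile.bin_size} bp"
        )
    bs = profile.bin_size
    arr = np.frombuffer(seq[:needed].encode("ascii"), dtype="S1")
    legal = np.isin(arr, [b"A", b"C", b"G", b"T"])
    n_frac = 1.0 - legal.reshape(profile.n_bins_total, bs).mean(axis=1)
    newly_masked = n_frac > n_threshold

    retained = profile.retained_bins()
    keep = ~newly_masked[retained]
    new_mask = profile.mask.copy()
    new_mask[retained[~keep]] = True
    values = profile.values[keep]
    if values.size == 0:
        logger.warning("%s: all bins masked as illegal; empty profile", profile.chrom)
    return RDProfile(profile.chrom, bs, values, new_mask)


def gc_fraction_per_bin(reference_bases, profile: RDProfile) -> np.ndarray:
    """GC fraction (among ACGT bases) of each *retained* bin of ``profile``."""
    seq = str(reference_bases).upper()
    bs = profile.bin_size
    needed = profile.n_bins_total * bs
    if len(seq) < needed:
        raise ValueError("reference does not cover all bins")
    arr = np.frombuffer(seq[:needed].encode("ascii"), dtype="S1")
    gc = np.isin(arr, [b"G", b"C"]).reshape(-1, bs).sum(axis=1).astype(float)
    acgt = np.isin(arr, [b"A", b"C", b"G", b"T"]).reshape(-1, bs).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(acgt > 0, gc / np.maximum(acgt, 1), 0.0)
    return frac[profile.retained_bins()]


def correct_gc_bias(
    profile: RDProfile, gc_fraction, min_stratum_size: int = 10
) -> RDProfile:
    """Rescale each bin by (global mean RD) / (mean RD of its GC stratum).

    Strata are GC fractions rounded to the nearest percent. Strata with fewer
    than ``min_stratum_size`` bins, or with zero mean RD, are left uncorrected.
    """
    gc = np.asarray(gc_fraction, dtype=float)
    if gc.size != profile.n_bins:
        raise ValueError(
            f"need one GC fraction per retained bin ({profile.n_bins}), got {gc.size}"
        )
    if profile.n_bins == 0:
        return profile.with_values(profile.values)
    if gc.size and (gc.min() < 0 or gc.max() > 1):
        raise ValueError("GC fractions must lie in [0, 1]")
    values = profile.values.copy()
    global_mean = values.mean()
    strata = np.rint(gc * 100).astype(int)
    for s in np.unique(strata):
        members = strata == s
        n = int(members.sum())
        if n < min_stratum_size:
            continue
        stratum_mean = values[members].mean()
        if stratum_mean == 0:
            if values[members].max() > 0:  # pragma: no cover - defensive
                logger.warning("GC stratum %d%% has zero mean; left uncorrected", s)
            continue
        values[members] *= global_mean / stratum_mean
    return profile.with_values(values)


def profile_from_bam(
    bam_path,
    fasta_path,
    chrom: str,
    bin_size: int = 1000,
    *,
    n_threshold: float = 0.0,
    min_gc_stratum: int = 10,
) -> RDProfile:
    """Full preprocessing for one chromosome: coverage, binning, masking, GC correction."""
    import pysam

    counts = count_coverage(bam_path, chrom)
    prof = bin_read_depth(counts, bin_size, chrom=chrom)
    with pysam.FastaFile(str(fasta_path)) as fa:
        if chrom not in fa.references:
            raise ValueError(f"chromosome {chrom!r} not in reference {fasta_path}")
        seq = fa.fetch(chrom)
    prof = mask_illegal_bins(prof, seq, n_threshold=n_threshold)
    if prof.n_bins:
        gc = gc_fraction_per_bin(seq, prof)
        prof = correct_gc_bias(prof, gc, min_stratum_size=min_gc_stratum)
    return prof
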