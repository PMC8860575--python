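"""Nascent-RNA quantification from metabolic-labeling conversions.

After 4-thiouridine labeling and alkylation, reads derived from nascent
transcripts carry T>C mismatches on the transcript strand.  A read with at
least one such conversion inside a gene's 3'UTR counts as *labeled*; the
ratio labeled/total estimates the nascent fraction.  Steady-state (total)
counts are normalized with median-of-ratios size factors, and those same
factors are applied to the labeled counts (cross-normalization), so nascent
and total abundances live on a common scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import pysam

from ._errors import EstimationError, EvidenceError, ValidationError

DEFAULT_MIN_BASE_QUALITY = 27


@dataclass(frozen=True)
class UtrInterval:
    """Strand-aware 3'UTR interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(f"{self.gene_id}: start must be < end")
        if self.strand not in "+-":
            raise ValidationError(f"{self.gene_id}: strand must be + or -")


def utrs_from_bed(bed: pd.DataFrame) -> list[UtrInterval]:
    return [
        UtrInterval(r.chrom, int(r.start), int(r.end), r.strand, r.name)
        for r in bed.itertuples()
    ]


def count_read_conversions(
    read: pysam.AlignedSegment,
    utr: UtrInterval,
    snp_mask: set[tuple[str, int]] | None = None,
    min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
) -> int:
    """T>C conversion events of one read inside one UTR.

    On + strand genes a conversion is reference T read as C; on - strand
    genes it is reference A read as G (the transcript-strand T>C seen from
    the genome).  Positions in ``snp_mask`` (chrom, 0-based pos) and bases
    below ``min_base_quality`` are excluded.  Mismatches are resolved from
    the MD tag; reads without one raise :class:`EvidenceError`.
    """
    if not read.has_tag("MD"):
        raise EvidenceError(f"read {read.query_name} lacks an MD tag")
    if utr.strand == "+":
        ref_base, alt_base = "T", "C"
    else:
        ref_base, alt_base = "A", "G"
    quals = read.query_qualities
    n = 0
    for qpos, rpos, ref in read.get_aligned_pairs(with_seq=True, matches_only=True):
        if not utr.start <= rpos < utr.end:
            continue
        if ref.islower():  # mismatch: MD stores the reference base
            if snp_mask and (utr.chrom, rpos) in snp_mask:
                continue
            if quals is not None and quals[qpos] < min_base_quality:
                continue
            if ref.upper() == ref_base and read.query_sequence[qpos] == alt_base:
                n += 1
    return n


def _assign_utr(read: pysam.AlignedSegment, utrs: list[UtrInterval]) -> UtrInterval | None:
    """Largest-overlap assignment; ties to the lexicographically smaller gene."""
    best: UtrInterval | None = None
    best_ov = 0
    for utr in utrs:
        if utr.chrom != read.reference_name:
            continue
        ov = min(read.reference_end, utr.end) - max(read.reference_start, utr.start)
        if ov > best_ov or (ov == best_ov and ov > 0 and best and utr.gene_id < best.gene_id):
            best, best_ov = utr, ov
    return best


def quantify(
    reads: Iterable[pysam.AlignedSegment] | str | Path,
    utrs: list[UtrInterval] | pd.DataFrame,
    snp_mask: set[tuple[str, int]] | None = None,
    min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """Total and labeled read counts per gene x sample.

    ``reads`` may be a SAM/BAM path (sample identity read from the RG tag)
    or an iterable of aligned segments.  A read counts for the UTR it
    overlaps by at least one aligned base (largest overlap wins); it is
    *labeled* if it shows >= 1 T>C conversion inside that UTR.

    Returns a tidy frame with columns gene_id, sample_id, total_reads,
    labeled_reads, tc_events.  Genes never observed are present with zeros
    when ``samples`` is given, so the matrix shape is deterministic.
    """
    if isinstance(utrs, pd.DataFrame):
        utrs = utrs_from_bed(utrs)
    by_chrom: dict[str, list[UtrInterval]] = {}
    for u in utrs:
        by_chrom.setdefault(u.chrom, []).append(u)

    close_after = False
    if isinstance(reads, (str, Path)):
        fh = pysam.AlignmentFile(str(reads), "r")
        read_iter: Iterable[pysam.AlignedSegment] = fh
        if samples is None:
            samples = sorted(rg["ID"] for rg in fh.header.to_dict().get("RG", []))
        close_after = True
    else:
        read_iter = reads

    counts: dict[tuple[str, str], list[int]] = {}
    seen_samples: set[str] = set(samples or [])
    try:
        for read in read_iter:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            cands = by_chrom.get(read.reference_name, [])
            utr = _assign_utr(read, cands)
            if utr is None:
                continue
            sample = read.get_tag("RG") if read.has_tag("RG") else "sample"
            seen_samples.add(sample)
            key = (utr.gene_id, sample)
            tc = count_read_conversions(read, utr, snp_mask, min_base_quality)
            row = counts.setdefault(key, [0, 0, 0])
            row[0] += 1
            if tc >= 1:
                row[1] += 1
            row[2] += tc
    finally:
        if close_after:
            fh.close()

    gene_ids = sorted({u.gene_id for u in utrs})
    sample_ids = sorted(seen_samples) if seen_samples else ["sample"]
    rows = []
    for gene in gene_ids:
        for sample in sample_ids:
            total, labeled, tc = counts.get((gene, sample), (0, 0, 0))
            rows.append(
                {
                    "gene_id": gene,
                    "sample_id": sample,
                    "total_reads": total,
                    "labeled_reads": labeled,
                    "tc_events": tc,
                }
            )
    return pd.DataFrame(rows)


def conversion_matrix(tidy: pd.DataFrame, value: str = "labeled_reads") -> pd.DataFrame:
    """Pivot the tidy quantify() output into a genes x samples matrix."""
    return tidy.pivot(index="gene_id", columns="sample_id", values=value)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors (Anders & Huber).

    factor_s = median over genes (with positive counts in every sample) of
    count_gs / geometric-mean_g.  Raises :class:`EstimationError` when no
    gene is positive in all samples.
    """
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise EstimationError(
            "size factors undefined: no gene has positive counts in every sample"
        )
    sub = mat[positive]
    log_geo_mean = np.mean(np.log(sub), axis=1, keepdims=True)
    ratios = np.exp(np.log(sub) - log_geo_mean)
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """Divide each sample column by its size factor."""
    missing = set(counts.columns) - set(factors.index)
    if missing:
        raise KeyError(f"no size factor for samples: {sorted(missing)}")
    return counts / factors.reindex(counts.columns)


def cross_normalize(
    labeled_counts: pd.DataFrame, factors_from_total: pd.Series
) -> pd.DataFrame:
    """Normalize labeled (nascent) counts with factors learned on total RNA.

    The factors are *not* re-estimated on the labeled counts: nascent
    libraries inherit the steady-state sequencing-depth correction so both
    assays stay on one scale.
    """
    return normalize_counts(labeled_counts, factors_from_total)


def flagging_probabilities(
    genome: Mapping[str, str],
    utr: UtrInterval,
    read_length: int,
    conversion_rate: float,
    seq_error_rate: float,
    snp_mask: set[tuple[str, int]] | None = None,
) -> tuple[float, float]:
    """Per-read probabilities that a (labeled, unlabeled) read shows >= 1 conversion.

    Averaged over all read start positions within the UTR.  A labeled read
    converts each transcript-strand T with the conversion rate; any read can
    gain an apparent conversion through a sequencing error at a T position
    (error to the specific conversion base, rate/3).  Masked SNP positions
    do not count.  Used to invert the observed labeled-read rate into an
    estimate of the true labeled fraction.
    """
    src = "T" if utr.strand == "+" else "A"
    seq = genome[utr.chrom][utr.start : utr.end]
    is_t = np.array(
        [
            b == src and (snp_mask is None or (utr.chrom, utr.start + i) not in snp_mask)
            for i, b in enumerate(seq)
        ],
        dtype=float,
    )
    L = min(read_length, len(seq))
    window_t = np.convolve(is_t, np.ones(L), mode="valid")  # T count per start
    e = seq_error_rate / 3.0
    miss_unlabeled = (1.0 - e) ** window_t
    miss_labeled = ((1.0 - conversion_rate) * (1.0 - e)) ** window_t
    return float(np.mean(1.0 - miss_labeled)), float(np.mean(1.0 - miss_unlabeled))


def estimate_labeled_fraction(
    tidy: pd.DataFrame,
    utrs: list[UtrInterval] | pd.DataFrame,
    genome: Mapping[str, str],
    read_length: int,
    conversion_rate: float,
    seq_error_rate: float = 0.0,
    snp_mask: set[tuple[str, int]] | None = None,
) -> pd.DataFrame:
    """Detection-corrected labeled fraction per gene x sample.

    Inverts observed_rate = f * p_labeled + (1 - f) * p_unlabeled, where the
    flagging probabilities come from the reference T content of each UTR.
    Also reports the binomial standard error of the estimate.
    """
    if isinstance(utrs, pd.DataFrame):
        utrs = utrs_from_bed(utrs)
    probs = {
        u.gene_id: flagging_probabilities(
            genome, u, read_length, conversion_rate, seq_error_rate, snp_mask
        )
        for u in utrs
    }
    rows = []
    for r in tidy.itertuples():
        p_lab, p_unl = probs[r.gene_id]
        if r.total_reads == 0 or p_lab <= p_unl:
            continue
        rate = r.labeled_reads / r.total_reads
        frac = (rate - p_unl) / (p_lab - p_unl)
        se = np.sqrt(max(rate * (1 - rate), 1e-12) / r.total_reads) / (p_lab - p_unl)
        rows.append(
            {
                "gene_id": r.gene_id,
                "sample_id": r.sample_id,
                "labeled_fraction": frac,
                "se": se,
                "total_reads": r.total_reads,
            }
        )
    return pd.DataFrame(rows)


def replicate_average(
    matrix: pd.DataFrame, sample_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Average replicate columns (named ``<timepoint>_<rep>``) per time point."""
    if sample_map is None:
        sample_map = {c: c.rsplit("_", 1)[0] for c in matrix.columns}
    return matrix.T.groupby(matrix.columns.map(sample_map.__getitem__)).mean().T


__all__ = [
    "UtrInterval",
    "utrs_from_bed",
    "count_read_conversions",
    "quantify",
    "conversion_matrix",
    "size_factors",
    "normalize_counts",
    "cross_normalize",
    "replicate_average",
    "DEFAULT_MIN_BASE_QUALITY",
]
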