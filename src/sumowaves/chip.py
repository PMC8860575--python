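"""Differential SUMO ChIP landscapes over a union peak set.

Per-time-point peak calls are merged into a union set (BEDtools-merge
semantics: overlapping or bookended intervals coalesce), reads are counted
per union region by their 5'-most aligned base, libraries are normalized
with median-of-ratios size factors, and regions varying over the time
course are flagged with a negative-binomial likelihood-ratio test at
padj <= 0.05 and fold change > 1.5.  Peaks are annotated to genomic
features by summit position, and mean CPM coverage profiles are computed
around summits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from ._errors import ParameterError, ValidationError
from .modules import bh_adjust, nb_lrt
from .slam import size_factors as _size_factors

logger = logging.getLogger(__name__)

PROMOTER_WINDOW = (-1000, 100)  # relative to TSS, strand-aware
DISTANT_PROMOTER_WINDOW = (-10000, -1000)
ANNOTATION_CATEGORIES = ("promoter-TSS", "exon", "intron", "distant promoter", "intergenic")


def union_peaks(peak_sets: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Merge peak sets across time points into a sorted, disjoint union.

    Overlapping *or bookended* intervals merge (distance-0 semantics); the
    result is independent of input order and idempotent.
    """
    frames = [df for df in peak_sets if df is not None and len(df)]
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end", "name"])
    cat = pd.concat(frames, ignore_index=True)
    if (cat["start"] >= cat["end"]).any() or (cat["start"] < 0).any():
        raise ValidationError("malformed peak interval (start >= end or negative)")
    cat = cat.sort_values(["chrom", "start", "end"], kind="mergesort")
    rows = []
    cur = None  # [chrom, start, end, n_members]
    for r in cat.itertuples():
        if cur is not None and r.chrom == cur[0] and r.start <= cur[2]:
            cur[2] = max(cur[2], r.end)
            cur[3] += 1
        else:
            if cur is not None:
                rows.append(cur)
            cur = [r.chrom, int(r.start), int(r.end), 1]
    if cur is not None:
        rows.append(cur)
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_members"])
    out["name"] = [f"union{i + 1:05d}" for i in range(len(out))]
    return out[["chrom", "start", "end", "name", "n_members"]]


def _five_prime_pos(read: pysam.AlignedSegment) -> int:
    return read.reference_end - 1 if read.is_reverse else read.reference_start


def count_in_union(
    reads: str | Path | Iterable[pysam.AlignedSegment],
    union: pd.DataFrame,
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """Read counts per union peak x library (5'-most aligned base assignment)."""
    close_after = False
    if isinstance(reads, (str, Path)):
        fh = pysam.AlignmentFile(str(reads), "r")
        read_iter: Iterable[pysam.AlignedSegment] = fh
        if samples is None:
            samples = sorted(rg["ID"] for rg in fh.header.to_dict().get("RG", []))
        close_after = True
    else:
        read_iter = reads

    starts_by_chrom: dict[str, np.ndarray] = {}
    meta_by_chrom: dict[str, pd.DataFrame] = {}
    for chrom, grp in union.groupby("chrom"):
        grp = grp.sort_values("start")
        starts_by_chrom[chrom] = grp["start"].to_numpy()
        meta_by_chrom[chrom] = grp.reset_index(drop=True)

    counts: dict[tuple[str, str], int] = {}
    seen: set[str] = set(samples or [])
    try:
        for read in read_iter:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            chrom = read.reference_name
            if chrom not in starts_by_chrom:
                continue
            pos = _five_prime_pos(read)
            idx = int(np.searchsorted(starts_by_chrom[chrom], pos, side="right")) - 1
            if idx < 0:
                continue
            peak = meta_by_chrom[chrom].iloc[idx]
            if pos >= peak["end"]:
                continue
            sample = read.get_tag("RG") if read.has_tag("RG") else "sample"
            seen.add(sample)
            counts[(peak["name"], sample)] = counts.get((peak["name"], sample), 0) + 1
    finally:
        if close_after:
            fh.close()

    sample_ids = sorted(seen) if seen else ["sample"]
    mat = pd.DataFrame(
        0, index=union["name"], columns=sample_ids, dtype=int
    )
    for (name, sample), n in counts.items():
        mat.at[name, sample] = n
    mat.index.name = "peak_id"
    return mat


def normalize_union_counts(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Median-of-ratios normalization across ChIP libraries."""
    factors = _size_factors(counts)
    return counts / factors, factors


def differential_regions(
    normalized: pd.DataFrame,
    groups: Mapping[str, str],
    padj_threshold: float = 0.05,
    fc_threshold: float = 1.5,
    pseudocount: float = 1.0,
    counts: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Flag union regions varying over the time course.

    ``groups`` maps each library column to its time point.  P-values come
    from the negative-binomial LRT stand-in (full model: one mean per time
    point; reduced: grand mean), BH-adjusted.  A region is flagged iff
    padj <= ``padj_threshold`` and the max/min normalized time-point mean
    fold change (with ``pseudocount``) exceeds ``fc_threshold``.

    ``counts`` (raw integers) defaults to ``normalized`` rounded; the test
    wants count-scale data while the fold change uses normalized means.
    """
    cols = list(normalized.columns)
    labels = [groups[c] for c in cols]
    tps = sorted(set(labels))
    if len(tps) < 2:
        raise ParameterError("need >= 2 time points")
    for tp in tps:
        if labels.count(tp) < 2:
            raise ParameterError(
                f"time point {tp} has a single replicate; dispersion is inestimable"
            )
    test_mat = (counts if counts is not None else normalized.round()).to_numpy()
    group_idx = [np.array([i for i, l in enumerate(labels) if l == tp]) for tp in tps]
    pvals = np.array([nb_lrt(row, group_idx) for row in test_mat])
    padj = bh_adjust(pvals)
    tp_means = np.column_stack(
        [normalized.to_numpy()[:, idx].mean(axis=1) for idx in group_idx]
    )
    fc = (tp_means.max(axis=1) + pseudocount) / (tp_means.min(axis=1) + pseudocount)
    out = pd.DataFrame(
        {
            "peak_id": normalized.index,
            "pvalue": pvals,
            "padj": padj,
            "fold_change": fc,
        }
    )
    out["flagged"] = (out["padj"] <= padj_threshold) & (out["fold_change"] > fc_threshold)
    return out.reset_index(drop=True)


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    tss: int  # 0-based position of the transcription start site
    exons: tuple[tuple[int, int], ...]  # sorted, non-overlapping

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


def gene_models_from_table(table: pd.DataFrame) -> list[GeneModel]:
    """Build gene models from an exon table (gene_id, chrom, start, end, strand)."""
    models = []
    for (gene_id, chrom, strand), grp in table.groupby(["gene_id", "chrom", "strand"]):
        exons = tuple(sorted((int(r.start), int(r.end)) for r in grp.itertuples()))
        for (s1, e1), (s2, _) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValidationError(f"{gene_id}: overlapping exons")
        tss = exons[0][0] if strand == "+" else exons[-1][1] - 1
        models.append(GeneModel(gene_id, chrom, strand, tss, exons))
    return models


def _window_interval(tss: int, strand: str, window: tuple[int, int]) -> tuple[int, int]:
    lo, hi = window
    if strand == "+":
        return tss + lo, tss + hi + 1
    return tss - hi, tss - lo + 1


def annotate_peak(
    chrom: str,
    summit: int,
    models: Sequence[GeneModel],
    promoter_window: tuple[int, int] = PROMOTER_WINDOW,
    distant_window: tuple[int, int] = DISTANT_PROMOTER_WINDOW,
) -> tuple[str, str | None]:
    """Genomic category and nearest gene for one peak summit.

    Precedence: promoter-TSS > exon > intron > distant promoter > intergenic.
    Nearest gene by |summit - TSS|, ties to the smaller gene_id.
    """
    here = [m for m in models if m.chrom == chrom]
    nearest = None
    if here:
        nearest = min(here, key=lambda m: (abs(summit - m.tss), m.gene_id)).gene_id
    for window, label in ((promoter_window, "promoter-TSS"),):
        for m in here:
            lo, hi = _window_interval(m.tss, m.strand, window)
            if lo <= summit < hi:
                return label, nearest
    for m in here:
        if any(s <= summit < e for s, e in m.exons):
            return "exon", nearest
    for m in here:
        lo, hi = m.span
        if lo <= summit < hi:
            return "intron", nearest
    for m in here:
        lo, hi = _window_interval(m.tss, m.strand, distant_window)
        if lo <= summit < hi:
            return "distant promoter", nearest
    return "intergenic", nearest


def annotate_peaks(
    union: pd.DataFrame,
    models: Sequence[GeneModel],
    promoter_window: tuple[int, int] = PROMOTER_WINDOW,
    distant_window: tuple[int, int] = DISTANT_PROMOTER_WINDOW,
) -> pd.DataFrame:
    """Annotate every union peak; summit defaults to the interval midpoint."""
    rows = []
    for r in union.itertuples():
        summit = int(getattr(r, "summit", (r.start + r.end) // 2))
        category, nearest = annotate_peak(
            r.chrom, summit, models, promoter_window, distant_window
        )
        rows.append(
            {
                "peak_id": r.name,
                "chrom": r.chrom,
                "summit": summit,
                "category": category,
                "nearest_gene": nearest,
            }
        )
    return pd.DataFrame(rows)


def mean_profile(
    reads: str | Path | Iterable[pysam.AlignedSegment],
    anchors: Sequence[tuple[str, int]],
    contig_lengths: Mapping[str, int],
    window: int = 2000,
    step: int = 10,
) -> pd.DataFrame:
    """Mean CPM coverage around anchor positions, sampled every ``step`` nt.

    Coverage (reads overlapping each position) is scaled to counts per
    million mapped reads per library and averaged over anchors; anchors
    closer than window/2 to a contig edge are skipped with a log entry.
    Returns a frame indexed by offset (-window/2 .. window/2) with one
    column per library.
    """
    if window % step != 0:
        raise ParameterError("step must divide window")
    half = window // 2
    close_after = False
    if isinstance(reads, (str, Path)):
        fh = pysam.AlignmentFile(str(reads), "r")
        read_iter: Iterable[pysam.AlignedSegment] = fh
        close_after = True
    else:
        read_iter = reads

    diffs: dict[str, dict[str, np.ndarray]] = {}
    totals: dict[str, int] = {}
    try:
        for read in read_iter:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            sample = read.get_tag("RG") if read.has_tag("RG") else "sample"
            totals[sample] = totals.get(sample, 0) + 1
            chrom = read.reference_name
            per_sample = diffs.setdefault(sample, {})
            if chrom not in per_sample:
                per_sample[chrom] = np.zeros(contig_lengths[chrom] + 1)
            per_sample[chrom][read.reference_start] += 1
            per_sample[chrom][read.reference_end] -= 1
    finally:
        if close_after:
            fh.close()

    offsets = np.arange(-half, half + 1, step)
    usable = []
    for chrom, pos in anchors:
        if pos - half < 0 or pos + half >= contig_lengths.get(chrom, 0):
            logger.warning("anchor %s:%d within window/2 of contig edge; skipped", chrom, pos)
            continue
        usable.append((chrom, pos))
    data = {}
    for sample in sorted(totals):
        coverage = {c: np.cumsum(d)[:-1] for c, d in diffs[sample].items()}
        acc = np.zeros(offsets.size)
        for chrom, pos in usable:
            cov = coverage.get(chrom)
            if cov is None:
                continue
            acc += cov[pos + offsets]
        n = max(len(usable), 1)
        data[sample] = acc / n * 1e6 / max(totals[sample], 1)
    return pd.DataFrame(data, index=pd.Index(offsets, name="offset"))


__all__ = [
    "union_peaks",
    "count_in_union",
    "normalize_union_counts",
    "differential_regions",
    "GeneModel",
    "gene_models_from_table",
    "annotate_peak",
    "annotate_peaks",
    "mean_profile",
    "ANNOTATION_CATEGORIES",
    "PROMOTER_WINDOW",
    "DISTANT_PROMOTER_WINDOW",
]
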