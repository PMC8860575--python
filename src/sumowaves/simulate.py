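"""Synthetic fixtures with known ground truth for every pipeline stage.

The generators emulate the structure of a 3T3-L1 adipocyte-differentiation
time course: a toy genome with 3'UTR intervals for metabolic-labeling reads
(4sU labeling read out as T>C conversions), search-engine-style SUMO peptide
tables, negative-binomial count matrices with planted stage modules
(pre-adipocyte / clonal expansion / mature adipocyte), and per-time-point
ChIP peak sets with stage-specific occupancy.

Ground truth is never written into the analysis-facing files; it travels in
sidecar tables whose columns carry a ``truth_`` prefix.  All randomness flows
from ``SimConfig.seed``; each fixture family draws from its own child stream
so adding one generator does not perturb the others.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from ._errors import ParameterError, ValidationError
from ._io import write_bed, write_fasta, write_vcf_mask

# child-stream codes, fixed so streams are stable across releases
_STREAM_REFERENCE = 1
_STREAM_SLAM = 2
_STREAM_PEPTIDES = 3
_STREAM_COUNTS = 4
_STREAM_PEAKS = 5

DEFAULT_TIME_POINTS = ("d-2", "d1", "d3", "d7")
DEFAULT_STAGE_MAP = {"d-2": "PA", "d1": "CE", "d3": "CE", "d7": "MA"}

# mature SUMO-2 (mouse), used both as a FASTA entry and as the source of
# SUMO-derived peptides; the conjugation remnant after Lys-C/Asp-N is DVFQQQTGG
SUMO2_MATURE = (
    "MADEKPKEGVKTENNDHINLKVAGQDGSVVQFKIKRHTPLSKLMKAYCERQGLSMRQIRFRFDGQPINETDTPAQLEMEDEDTIDVFQQQTGG"
)
SUMO2_PRO_TAIL = "VY"
SUMO3_PRO_TAIL = "SASRGSVPTPNRCP"
REMNANT = "DVFQQQTGG"
DIAGNOSTIC_IONS = (
    "b2-DV", "b3-DVF", "b4-DVFQ", "b5-DVFQQ", "b6-DVFQQQ",
    "b7-DVFQQQT", "b9-DVFQQQTGG", "QQ", "FQ", "FQQ",
)

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class ProteomicsSpec:
    """Counts of planted peptide records per truth category."""

    n_true: int = 40
    n_loc_fail: int = 10
    n_ion_fail: int = 10
    n_decoy: int = 10
    n_delta_fail: int = 10
    n_multi_supported: int = 5
    n_multi_unsupported: int = 5
    n_free_mature: int = 8
    n_immature_sumo2: int = 8
    n_immature_sumo3: int = 8
    n_internal: int = 8
    n_chain: int = 8


@dataclass(frozen=True)
class PeakSpec:
    """Planted union-region layout for the ChIP fixture."""

    n_flat: int = 40
    n_per_stage: int = 8
    base_intensity: float = 60.0
    stage_intensity: float = 240.0
    peak_length: int = 400
    gap: int = 600


@dataclass(frozen=True)
class ModuleSpec:
    stage: str
    n_genes: int
    profile: tuple[float, ...]


def default_module_spec(
    n_genes: int, time_points: Sequence[str] = DEFAULT_TIME_POINTS
) -> tuple[ModuleSpec, ...]:
    """Three stage modules: each elevated 8x at its stage's time points."""
    stage_map = DEFAULT_STAGE_MAP if tuple(time_points) == DEFAULT_TIME_POINTS else None
    if stage_map is None:
        raise ParameterError("default_module_spec needs the default time points")
    base, high = 100.0, 800.0
    per = n_genes // 3
    specs = []
    for stage, n in (("PA", per), ("CE", per), ("MA", n_genes - 2 * per)):
        profile = tuple(high if stage_map[tp] == stage else base for tp in time_points)
        specs.append(ModuleSpec(stage, n, profile))
    return tuple(specs)


@dataclass(frozen=True)
class SimConfig:
    """Master configuration; one seed drives every fixture family."""

    seed: int = 0
    n_genes: int = 60
    time_points: tuple[str, ...] = DEFAULT_TIME_POINTS
    n_replicates: int = 3
    module_spec: tuple[ModuleSpec, ...] | None = None
    nb_dispersion: float = 0.05
    labeled_fraction: float | Mapping[str, float] = 0.3
    conversion_rate: float = 0.02
    seq_error_rate: float = 0.001
    read_length: int = 50
    depth: float = 100.0
    n_snps: int = 0
    utr_length_range: tuple[int, int] = (300, 1500)
    max_contig_length: int = 100_000
    max_contigs: int = 50
    proteomics_spec: ProteomicsSpec = field(default_factory=ProteomicsSpec)
    peak_spec: PeakSpec = field(default_factory=PeakSpec)
    size_factors: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.time_points) < 2:
            raise ParameterError("need at least 2 time points")
        for name in ("conversion_rate", "seq_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}={v} outside [0, 1]")
        fracs = (
            self.labeled_fraction.values()
            if isinstance(self.labeled_fraction, Mapping)
            else [self.labeled_fraction]
        )
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ParameterError("labeled_fraction outside [0, 1]")
        if self.module_spec is not None:
            if sum(m.n_genes for m in self.module_spec) != self.n_genes:
                raise ParameterError("module gene counts must sum to n_genes")

    @property
    def samples(self) -> list[str]:
        return [f"{tp}_{r}" for tp in self.time_points for r in range(1, self.n_replicates + 1)]

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stream])


# ---------------------------------------------------------------------------
# reference genome + 3'UTR intervals


def gen_reference(cfg: SimConfig) -> tuple[dict[str, str], pd.DataFrame]:
    """Toy genome and one non-overlapping 3'UTR per gene (BED6-shaped frame).

    The transcript-strand sequence is drawn with 30% T so conversions are
    observable (>=20% enforced); minus-strand genes are reverse-complemented
    into the genome.
    """
    rng = cfg.rng(_STREAM_REFERENCE)
    lo, hi = cfg.utr_length_range
    gap = 100
    capacity = cfg.max_contigs * (cfg.max_contig_length // (hi + gap))
    if cfg.n_genes > capacity:
        raise ParameterError(
            f"n_genes={cfg.n_genes} exceeds toy-genome capacity {capacity}"
        )
    bases = np.array(list("ACGT"))
    utr_rows = []
    contigs: dict[str, str] = {}
    contig_idx, cursor = 0, 0
    parts: list[str] = []

    def _flush() -> None:
        nonlocal contig_idx, cursor, parts
        if parts:
            contigs[f"chr{contig_idx + 1}"] = "".join(parts)
            contig_idx += 1
            cursor = 0
            parts = []

    strands = ["+" if rng.random() < 0.5 else "-" for _ in range(cfg.n_genes)]
    if cfg.n_genes >= 2 and len(set(strands)) == 1:  # both strands must be represented
        strands[-1] = "-" if strands[0] == "+" else "+"
    for g in range(cfg.n_genes):
        length = int(rng.integers(lo, hi + 1))
        strand = strands[g]
        while True:  # transcript strand, T-rich
            tx = rng.choice(bases, size=length, p=[0.2333, 0.2333, 0.2334, 0.3])
            tx[rng.random(length) < 0.3] = "T"  # guarantee dense T coverage
            tx = "".join(tx)
            if tx.count("T") / length >= 0.2:
                break
        genomic = tx if strand == "+" else _revcomp(tx)
        if cursor + gap + length > cfg.max_contig_length:
            _flush()
        lead = "".join(rng.choice(bases, size=gap))
        parts.append(lead)
        cursor += gap
        start = cursor
        parts.append(genomic)
        cursor += length
        utr_rows.append(
            {
                "chrom": f"chr{contig_idx + 1}",
                "start": start,
                "end": start + length,
                "name": f"gene{g + 1:04d}",
                "score": 0,
                "strand": strand,
            }
        )
    _flush()
    utrs = pd.DataFrame(utr_rows)
    return contigs, utrs


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


# ---------------------------------------------------------------------------
# SLAM-seq reads


@dataclass
class SimRead:
    qname: str
    chrom: str
    pos: int  # 0-based leftmost
    seq: str
    sample_id: str
    truth_labeled: bool


def gen_slam_reads(
    cfg: SimConfig, genome: dict[str, str], utrs: pd.DataFrame
) -> tuple[list[SimRead], pd.DataFrame, set[tuple[str, int]]]:
    """Reads with metabolic-labeling T>C conversions plus sequencing noise.

    Each read is internally tagged labeled/unlabeled; labeled reads convert
    each transcript-strand T (genomic T on + genes, genomic A on - genes)
    with probability ``conversion_rate``.  Every read then picks up random
    errors at ``seq_error_rate`` per base.  Optionally ``n_snps`` genomic
    variant positions are planted (every read shows the variant base) and
    returned as a mask set.

    Returns (reads, truth table, snp position set).
    """
    if cfg.conversion_rate == 0 and _max_fraction(cfg.labeled_fraction) > 0:
        warnings.warn(
            "conversion_rate=0 with labeled_fraction>0: labeled reads are "
            "indistinguishable from unlabeled reads",
            stacklevel=2,
        )
    rng = cfg.rng(_STREAM_SLAM)
    bases = np.array(list("ACGT"))

    snps: dict[tuple[str, int], str] = {}
    if cfg.n_snps > 0:
        candidates = []
        for utr in utrs.itertuples():
            want = "T" if utr.strand == "+" else "A"
            seq = genome[utr.chrom][utr.start : utr.end]
            candidates.extend(
                (utr.chrom, utr.start + i) for i, b in enumerate(seq) if b == want
            )
        picked = rng.choice(len(candidates), size=min(cfg.n_snps, len(candidates)), replace=False)
        for idx in sorted(picked):
            chrom, pos = candidates[idx]
            ref = genome[chrom][pos]
            snps[(chrom, pos)] = "C" if ref == "T" else "G"

    reads: list[SimRead] = []
    truth_rows = []
    for utr in utrs.itertuples():
        contig = genome[utr.chrom]
        utr_len = utr.end - utr.start
        read_len = min(cfg.read_length, utr_len)
        for tp in cfg.time_points:
            frac_tp = _fraction_for(cfg.labeled_fraction, tp)
            for rep in range(1, cfg.n_replicates + 1):
                sample = f"{tp}_{rep}"
                n_reads = int(rng.poisson(cfg.depth))
                for i in range(n_reads):
                    start = int(rng.integers(utr.start, utr.end - read_len + 1))
                    seq = list(contig[start : start + read_len])
                    for j in range(read_len):
                        alt = snps.get((utr.chrom, start + j))
                        if alt is not None:
                            seq[j] = alt
                    labeled = bool(rng.random() < frac_tp)
                    if labeled and cfg.conversion_rate > 0:
                        if utr.strand == "+":
                            src, dst = "T", "C"
                        else:
                            src, dst = "A", "G"
                        for j in range(read_len):
                            if contig[start + j] == src and (utr.chrom, start + j) not in snps:
                                if rng.random() < cfg.conversion_rate:
                                    seq[j] = dst
                    if cfg.seq_error_rate > 0:
                        for j in range(read_len):
                            if rng.random() < cfg.seq_error_rate:
                                others = [b for b in "ACGT" if b != seq[j]]
                                seq[j] = others[int(rng.integers(3))]
                    qname = f"{utr.name}|{sample}|{i}"
                    reads.append(
                        SimRead(qname, utr.chrom, start, "".join(seq), sample, labeled)
                    )
                    truth_rows.append(
                        {
                            "read_id": qname,
                            "gene_id": utr.name,
                            "sample_id": sample,
                            "truth_labeled": labeled,
                            "truth_fraction": frac_tp,
                        }
                    )
    truth = pd.DataFrame(truth_rows)
    return reads, truth, set(snps)


def _max_fraction(frac: float | Mapping[str, float]) -> float:
    return max(frac.values()) if isinstance(frac, Mapping) else frac


def _fraction_for(frac: float | Mapping[str, float], tp: str | None) -> float:
    if isinstance(frac, Mapping):
        return frac[tp] if tp is not None else max(frac.values())
    return frac


def _md_and_nm(read_seq: str, ref_seq: str) -> tuple[str, int]:
    """MD tag and NM count for an ungapped alignment."""
    md_parts: list[str] = []
    run = 0
    nm = 0
    for q, r in zip(read_seq, ref_seq):
        if q == r:
            run += 1
        else:
            md_parts.append(str(run))
            md_parts.append(r)
            run = 0
            nm += 1
    md_parts.append(str(run))
    return "".join(md_parts), nm


def write_sam(
    reads: Sequence[SimRead], genome: dict[str, str], path: str | Path
) -> None:
    """Write reads as coordinate-sorted SAM with MD/NM tags and RG=sample."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": len(seq)} for name, seq in genome.items()],
        "RG": [{"ID": s} for s in sorted({r.sample_id for r in reads})],
    }
    order = {name: i for i, name in enumerate(genome)}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for read in sorted(reads, key=lambda r: (order[r.chrom], r.pos, r.qname)):
            ref = genome[read.chrom][read.pos : read.pos + len(read.seq)]
            md, nm = _md_and_nm(read.seq, ref)
            a = pysam.AlignedSegment(fh.header)
            a.query_name = read.qname
            a.query_sequence = read.seq
            a.flag = 0
            a.reference_id = fh.header.get_tid(read.chrom)
            a.reference_start = read.pos
            a.mapping_quality = 60
            a.cigarstring = f"{len(read.seq)}M"
            a.query_qualities = pysam.qualitystring_to_array("I" * len(read.seq))
            a.set_tag("MD", md)
            a.set_tag("NM", nm)
            a.set_tag("RG", read.sample_id)
            fh.write(a)


# ---------------------------------------------------------------------------
# peptide evidence table


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(_AA))[rng.integers(0, len(_AA), size=length)])


def _intensities(
    rng: np.random.Generator, samples: Sequence[str], scale: float = 1e7
) -> dict[str, float]:
    return {s: float(np.round(scale * rng.lognormal(0.0, 0.5), 1)) for s in samples}


def gen_peptide_table(
    cfg: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str]]:
    """Search-output-shaped SUMO peptide evidence with exhaustive truth labels.

    Plants records that pass every manual filter, records that each fail
    exactly one rule (localization probability <= 75%, no diagnostic remnant
    ions, decoy hit, delta score <= 40 on a C-terminal K not preceding D/E),
    multiply-SUMOylated peptides with and without single-site support, and
    SUMO-2/3-derived peptides of every equilibrium class.

    Returns (peptide table, truth sidecar, protein FASTA dict).
    """
    rng = cfg.rng(_STREAM_PEPTIDES)
    spec = cfg.proteomics_spec
    samples = cfg.samples

    proteins: dict[str, str] = {
        "SUMO2_SYNTH": SUMO2_MATURE,
        "SUMO3_SYNTH": SUMO2_MATURE[:-9] + REMNANT,  # same remnant-bearing mature end
    }
    rows: list[dict] = []
    truth: list[dict] = []
    rid = 0

    def _target_protein(next_after_k: str | None = None) -> tuple[str, int]:
        """New random protein with an internal K; optionally fix the residue after K."""
        nonlocal rng
        length = int(rng.integers(60, 120))
        seq = list(_random_protein(rng, length))
        kpos = int(rng.integers(10, length - 10))  # 0-based
        seq[kpos] = "K"
        if next_after_k is not None:
            seq[kpos + 1] = next_after_k
        elif seq[kpos + 1] in "DE":
            seq[kpos + 1] = "A"
        pid = f"PROT{len(proteins) + 1:04d}"
        proteins[pid] = "".join(seq)
        return pid, kpos + 1  # 1-based K position

    def _emit(row: dict, **truth_fields) -> None:
        nonlocal rid
        rid += 1
        row = {"record_id": f"pep{rid:04d}", **row}
        rows.append(row)
        truth.append({"record_id": row["record_id"], **truth_fields})

    def _ions(k: int | None = None) -> str:
        n = int(rng.integers(2, 6)) if k is None else k
        chosen = rng.choice(len(DIAGNOSTIC_IONS), size=n, replace=False)
        return ";".join(DIAGNOSTIC_IONS[i] for i in sorted(chosen))

    def _peptide_around(pid: str, kpos1: int, c_terminal_k: bool = False) -> tuple[str, int, int]:
        """Peptide substring covering the K; returns (sequence, start1, mod pos in peptide)."""
        seq = proteins[pid]
        if c_terminal_k:
            start1 = max(1, kpos1 - int(rng.integers(6, 12)))
            end1 = kpos1
        else:
            start1 = max(1, kpos1 - int(rng.integers(3, 8)))
            end1 = min(len(seq), kpos1 + int(rng.integers(3, 8)))
        pep = seq[start1 - 1 : end1]
        return pep, start1, kpos1 - start1 + 1

    def _base_row(pid, pep, start1, mods, probs, delta, ions, decoy=False, is_sumo=False):
        return {
            "sequence": pep,
            "protein_id": pid,
            "peptide_start": start1,
            "sumo_positions": ";".join(str(m) for m in mods),
            "sumo_loc_probs": ";".join(f"{p:.4f}" for p in probs),
            "delta_score": round(float(delta), 2),
            "decoy": int(decoy),
            "diagnostic_ions": ions,
            "source_is_sumo": int(is_sumo),
            **{f"intensity_{s}": v for s, v in _intensities(rng, samples).items()},
        }

    # --- fully accepted target-site records (a few exercise the C-term-K branch)
    true_sites: list[tuple[str, int]] = []
    for i in range(spec.n_true):
        cterm = i % 5 == 0
        pid, kpos1 = _target_protein(next_after_k="A" if cterm else None)
        pep, start1, mpos = _peptide_around(pid, kpos1, c_terminal_k=cterm)
        true_sites.append((pid, kpos1))
        _emit(
            _base_row(pid, pep, start1, [mpos], [rng.uniform(0.80, 1.0)],
                      rng.uniform(50, 150), _ions()),
            truth_accept=True, truth_reason="pass", truth_survives=True,
            truth_class="conjugated_to_targets",
            truth_site=f"{pid}:{kpos1}",
        )

    # --- one-rule failures, in the documented rule order
    for _ in range(spec.n_loc_fail):
        pid, kpos1 = _target_protein()
        pep, start1, mpos = _peptide_around(pid, kpos1)
        _emit(
            _base_row(pid, pep, start1, [mpos], [rng.uniform(0.30, 0.75)],
                      rng.uniform(50, 150), _ions()),
            truth_accept=False, truth_reason="localization", truth_survives=False,
            truth_class="", truth_site="",
        )
    for _ in range(spec.n_ion_fail):
        pid, kpos1 = _target_protein()
        pep, start1, mpos = _peptide_around(pid, kpos1)
        _emit(
            _base_row(pid, pep, start1, [mpos], [rng.uniform(0.80, 1.0)],
                      rng.uniform(50, 150), ""),
            truth_accept=False, truth_reason="diagnostic_ions", truth_survives=False,
            truth_class="", truth_site="",
        )
    for _ in range(spec.n_decoy):
        pid, kpos1 = _target_protein()
        pep, start1, mpos = _peptide_around(pid, kpos1)
        _emit(
            _base_row(pid, pep, start1, [mpos], [rng.uniform(0.80, 1.0)],
                      rng.uniform(50, 150), _ions(), decoy=True),
            truth_accept=False, truth_reason="decoy", truth_survives=False,
            truth_class="", truth_site="",
        )
    for _ in range(spec.n_delta_fail):
        pid, kpos1 = _target_protein(next_after_k="A")
        pep, start1, mpos = _peptide_around(pid, kpos1, c_terminal_k=True)
        _emit(
            _base_row(pid, pep, start1, [mpos], [rng.uniform(0.80, 1.0)],
                      rng.uniform(5.0, 39.9), _ions()),
            truth_accept=False, truth_reason="delta", truth_survives=False,
            truth_class="", truth_site="",
        )

    # --- multiply-SUMOylated peptides
    def _double_site_protein() -> tuple[str, int, int]:
        length = int(rng.integers(80, 120))
        seq = list(_random_protein(rng, length))
        k1 = int(rng.integers(15, 30))
        k2 = k1 + int(rng.integers(5, 10))
        seq[k1], seq[k2] = "K", "K"
        for k in (k1, k2):
            if seq[k + 1] in "DE":
                seq[k + 1] = "A"
        pid = f"PROT{len(proteins) + 1:04d}"
        proteins[pid] = "".join(seq)
        return pid, k1 + 1, k2 + 1

    for supported in (True, False):
        n = spec.n_multi_supported if supported else spec.n_multi_unsupported
        for _ in range(n):
            pid, p1, p2 = _double_site_protein()
            if supported:  # singly-modified evidence for both sites
                for kpos1 in (p1, p2):
                    pep, start1, mpos = _peptide_around(pid, kpos1)
                    true_sites.append((pid, kpos1))
                    _emit(
                        _base_row(pid, pep, start1, [mpos], [rng.uniform(0.80, 1.0)],
                                  rng.uniform(50, 150), _ions()),
                        truth_accept=True, truth_reason="pass", truth_survives=True,
                        truth_class="conjugated_to_targets", truth_site=f"{pid}:{kpos1}",
                    )
            start1 = max(1, p1 - 3)
            end1 = min(len(proteins[pid]), p2 + 3)
            pep = proteins[pid][start1 - 1 : end1]
            mods = [p1 - start1 + 1, p2 - start1 + 1]
            _emit(
                _base_row(pid, pep, start1, mods,
                          [rng.uniform(0.80, 1.0), rng.uniform(0.80, 1.0)],
                          rng.uniform(50, 150), _ions()),
                truth_accept=True, truth_reason="pass", truth_survives=supported,
                truth_class="conjugated_to_targets" if supported else "",
                truth_site=f"{pid}:{p1};{pid}:{p2}" if supported else "",
            )

    # --- SUMO chain formation: SUMO-2 modified on one of its own lysines
    sumo_seq = proteins["SUMO2_SYNTH"]
    sumo_ks = [i + 1 for i, aa in enumerate(sumo_seq) if aa == "K"]
    for _ in range(spec.n_chain):
        kpos1 = int(rng.choice([k for k in sumo_ks if 5 < k < len(sumo_seq) - 5]))
        pep, start1, mpos = _peptide_around("SUMO2_SYNTH", kpos1)
        true_sites.append(("SUMO2_SYNTH", kpos1))
        _emit(
            _base_row("SUMO2_SYNTH", pep, start1, [mpos], [rng.uniform(0.80, 1.0)],
                      rng.uniform(50, 150), _ions(), is_sumo=True),
            truth_accept=True, truth_reason="pass", truth_survives=True,
            truth_class="chains", truth_site=f"SUMO2_SYNTH:{kpos1}",
        )

    # --- SUMO-derived (unmodified) peptides: the equilibrium pools
    derived = [
        ("free_mature", REMNANT, spec.n_free_mature),
        ("immature_sumo2", REMNANT + SUMO2_PRO_TAIL, spec.n_immature_sumo2),
        ("immature_sumo3", REMNANT + SUMO3_PRO_TAIL, spec.n_immature_sumo3),
    ]
    for klass, seq, n in derived:
        for _ in range(n):
            _emit(
                _base_row("SUMO2_SYNTH", seq, len(sumo_seq) - 8, [], [],
                          rng.uniform(50, 150), _ions(), is_sumo=True),
                truth_accept=True, truth_reason="pass", truth_survives=True,
                truth_class=klass, truth_site="",
            )
    for _ in range(spec.n_internal):
        start1 = int(rng.integers(1, 30))
        pep = sumo_seq[start1 - 1 : start1 - 1 + int(rng.integers(8, 15))]
        _emit(
            _base_row("SUMO2_SYNTH", pep, start1, [], [],
                      rng.uniform(50, 150), _ions(), is_sumo=True),
            truth_accept=True, truth_reason="pass", truth_survives=True,
            truth_class="internal", truth_site="",
        )

    table = pd.DataFrame(rows)
    sidecar = pd.DataFrame(truth)
    return table, sidecar, proteins


# ---------------------------------------------------------------------------
# time-course count matrices with planted stage modules


def gen_timecourse_counts(
    cfg: SimConfig, poisson: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Negative-binomial counts with planted PA/CE/MA module structure.

    counts_gs ~ NB(mean = sizefactor_s * profile_g(t), dispersion); pass
    ``poisson=True`` for the dispersion->0 limit.  Returns (counts genes x
    samples, truth table with stage labels, true size factors).
    """
    spec = cfg.module_spec or default_module_spec(cfg.n_genes, cfg.time_points)
    if not spec:
        raise ParameterError("module_spec must be non-empty")
    if not poisson and cfg.nb_dispersion <= 0:
        raise ParameterError("nb_dispersion must be positive")
    rng = cfg.rng(_STREAM_COUNTS)
    samples = cfg.samples
    if cfg.size_factors is not None:
        if len(cfg.size_factors) != len(samples):
            raise ParameterError("size_factors length must match sample count")
        sf = np.asarray(cfg.size_factors, dtype=float)
    else:
        sf = rng.lognormal(0.0, 0.25, size=len(samples))
        sf /= np.exp(np.mean(np.log(sf)))  # geometric mean 1

    genes, stages, mus = [], [], []
    g = 0
    for mod_idx, mod in enumerate(spec):
        if len(mod.profile) != len(cfg.time_points):
            raise ParameterError("module profile length must match time points")
        for _ in range(mod.n_genes):
            g += 1
            genes.append(f"gene{g:04d}")
            stages.append((mod_idx, mod.stage))
            per_gene = rng.lognormal(0.0, 0.2)  # gene-level expression offset
            mu = np.repeat(np.asarray(mod.profile, float), cfg.n_replicates) * sf * per_gene
            mus.append(mu)
    mu = np.vstack(mus)
    if poisson:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / cfg.nb_dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    counts_df = pd.DataFrame(counts, index=genes, columns=samples)
    counts_df.index.name = "gene_id"
    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "truth_module": [m for m, _ in stages],
            "truth_stage": [s for _, s in stages],
        }
    )
    sf_series = pd.Series(sf, index=samples, name="truth_size_factor")
    return counts_df, truth, sf_series


# ---------------------------------------------------------------------------
# ChIP peak sets and reads


def gen_peak_fixture(
    cfg: SimConfig, stage_map: Mapping[str, str] = DEFAULT_STAGE_MAP
) -> tuple[dict[str, pd.DataFrame], list[SimRead], dict[str, str], pd.DataFrame]:
    """Per-time-point peak sets plus reads with stage-specific occupancy.

    Flat regions carry ``base_intensity`` mean reads per library at every
    time point; each stage gets ``n_per_stage`` regions elevated to
    ``stage_intensity`` at that stage's time points.  Peak calls per time
    point jitter the region edges by a few bp so union-merging is exercised.

    Returns (peaks per time point, reads, genome, region truth).
    """
    rng = cfg.rng(_STREAM_PEAKS)
    spec = cfg.peak_spec
    stages = sorted(set(stage_map.values()))
    regions = []
    for i in range(spec.n_flat):
        regions.append(("flat", None))
    for stage in stages:
        for _ in range(spec.n_per_stage):
            regions.append(("stage", stage))
    order = rng.permutation(len(regions))
    regions = [regions[i] for i in order]

    span = spec.peak_length + spec.gap
    n_per_contig = max(1, (cfg.max_contig_length - spec.gap) // span)
    bases = np.array(list("ACGT"))
    genome: dict[str, str] = {}
    rows = []
    for i, (kind, stage) in enumerate(regions):
        contig = f"chrP{i // n_per_contig + 1}"
        offset = (i % n_per_contig) * span + spec.gap
        rows.append(
            {
                "region_id": f"region{i + 1:03d}",
                "chrom": contig,
                "start": offset,
                "end": offset + spec.peak_length,
                "truth_differential": kind == "stage",
                "truth_stage": stage or "",
            }
        )
    truth = pd.DataFrame(rows)
    for contig, grp in truth.groupby("chrom"):
        length = int(grp["end"].max()) + spec.gap
        genome[contig] = "".join(rng.choice(bases, size=length))

    read_len = 50
    reads: list[SimRead] = []
    peaks_by_tp: dict[str, list[dict]] = {tp: [] for tp in cfg.time_points}
    n_rep = max(2, cfg.n_replicates)
    for region in truth.itertuples():
        for tp in cfg.time_points:
            hot = region.truth_differential and stage_map[tp] == region.truth_stage
            lam = spec.stage_intensity if hot else spec.base_intensity
            if (not region.truth_differential) or hot:
                jitter = int(rng.integers(-20, 21))
                peaks_by_tp[tp].append(
                    {
                        "chrom": region.chrom,
                        "start": max(0, region.start + jitter),
                        "end": region.end + int(rng.integers(-20, 21)),
                        "name": f"{region.region_id}@{tp}",
                        "score": int(lam),
                        "strand": ".",
                    }
                )
            for rep in range(1, n_rep + 1):
                sample = f"{tp}_{rep}"
                n = int(rng.poisson(lam))
                starts = rng.integers(region.start, region.end - read_len, size=n)
                for j, s in enumerate(sorted(map(int, starts))):
                    qname = f"{region.region_id}|{sample}|{j}"
                    seq = genome[region.chrom][s : s + read_len]
                    reads.append(SimRead(qname, region.chrom, s, seq, sample, False))
    peak_frames = {tp: pd.DataFrame(v) for tp, v in peaks_by_tp.items()}
    return peak_frames, reads, genome, truth


def gen_gene_models(cfg: SimConfig, genome: dict[str, str]) -> pd.DataFrame:
    """Simple two-exon gene models on the peak contigs, for peak annotation."""
    rng = cfg.rng(_STREAM_PEAKS + 100)
    rows = []
    g = 0
    for contig, seq in sorted(genome.items()):
        pos = 2000
        while pos + 4000 < len(seq):
            g += 1
            strand = "+" if rng.random() < 0.5 else "-"
            e1 = (pos, pos + 800)
            e2 = (pos + 2000, pos + 2600)
            for start, end in (e1, e2):
                rows.append(
                    {
                        "gene_id": f"pgene{g:03d}",
                        "chrom": contig,
                        "start": start,
                        "end": end,
                        "strand": strand,
                    }
                )
            pos += int(rng.integers(6000, 9000))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fixture bundle writer (used by the CLI `simulate` and `run` commands)


def write_fixture_bundle(cfg: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and write every fixture family under ``outdir``.

    Returns a name->path manifest of the written files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    genome, utrs = gen_reference(cfg)
    paths["genome_fasta"] = outdir / "genome.fa"
    write_fasta(genome, paths["genome_fasta"])
    paths["utrs_bed"] = outdir / "utrs.bed"
    write_bed(utrs, paths["utrs_bed"])

    reads, slam_truth, snps = gen_slam_reads(cfg, genome, utrs)
    paths["slam_sam"] = outdir / "slam_reads.sam"
    write_sam(reads, genome, paths["slam_sam"])
    paths["slam_truth"] = outdir / "slam_truth.tsv"
    slam_truth.to_csv(paths["slam_truth"], sep="\t", index=False)
    paths["snp_mask_vcf"] = outdir / "snp_mask.vcf"
    write_vcf_mask(snps, paths["snp_mask_vcf"])

    peptides, pep_truth, proteins = gen_peptide_table(cfg)
    paths["peptides_tsv"] = outdir / "peptides.tsv"
    peptides.to_csv(paths["peptides_tsv"], sep="\t", index=False)
    paths["peptides_truth"] = outdir / "peptides_truth.tsv"
    pep_truth.to_csv(paths["peptides_truth"], sep="\t", index=False)
    paths["proteins_fasta"] = outdir / "proteins.fa"
    write_fasta(proteins, paths["proteins_fasta"])

    counts, count_truth, sf = gen_timecourse_counts(cfg)
    paths["counts_tsv"] = outdir / "timecourse_counts.tsv"
    counts.to_csv(paths["counts_tsv"], sep="\t")
    paths["counts_truth"] = outdir / "timecourse_truth.tsv"
    count_truth.to_csv(paths["counts_truth"], sep="\t", index=False)
    paths["size_factor_truth"] = outdir / "size_factor_truth.tsv"
    sf.rename_axis("sample_id").to_frame().to_csv(paths["size_factor_truth"], sep="\t")

    peak_frames, chip_reads, chip_genome, peak_truth = gen_peak_fixture(cfg)
    for tp, frame in peak_frames.items():
        p = outdir / f"peaks_{tp}.bed"
        write_bed(frame, p)
        paths[f"peaks_{tp}"] = p
    paths["chip_genome_fasta"] = outdir / "chip_genome.fa"
    write_fasta(chip_genome, paths["chip_genome_fasta"])
    paths["chip_sam"] = outdir / "chip_reads.sam"
    write_sam(chip_reads, chip_genome, paths["chip_sam"])
    paths["peak_truth"] = outdir / "peak_truth.tsv"
    peak_truth.to_csv(paths["peak_truth"], sep="\t", index=False)
    gene_models = gen_gene_models(cfg, chip_genome)
    paths["gene_models_tsv"] = outdir / "gene_models.tsv"
    gene_models.to_csv(paths["gene_models_tsv"], sep="\t", index=False)
    return paths


__all__ = [
    "SimConfig",
    "ProteomicsSpec",
    "PeakSpec",
    "ModuleSpec",
    "SimRead",
    "default_module_spec",
    "gen_reference",
    "gen_slam_reads",
    "gen_peptide_table",
    "gen_timecourse_counts",
    "gen_peak_fixture",
    "gen_gene_models",
    "write_sam",
    "write_fixture_bundle",
    "DIAGNOSTIC_IONS",
    "REMNANT",
]
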