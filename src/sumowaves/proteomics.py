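"""Post-processing of search-engine SUMO peptide evidence.

Endogenous SUMO-2/3 proteomics (Lys-C + Asp-N digestion) leaves the remnant
DVFQQQTGG on modified lysines.  Starting from search-output-shaped peptide
tables this module applies the manual filtering rules (localization
probability, diagnostic remnant ions, decoy removal, delta-score rule for
C-terminal lysines), collapses evidence to protein-position-resolved SUMO
sites, and computes two global summaries: SUMO *density* (total site ion
current per mg of input protein) and the SUMO *equilibrium* (how total
cellular SUMO partitions among target conjugates, chains, free mature SUMO,
immature propeptide-bearing SUMO-2/-3 and internal peptides).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._errors import EvidenceError, ParameterError, ValidationError

logger = logging.getLogger(__name__)

# monoisotopic residue masses (Da) of the 20 standard amino acids
# (residue = amino acid minus water, i.e. the in-chain mass)
RESIDUE_MONO_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276, "V": 99.06841,
    "T": 101.04768, "C": 103.00919, "L": 113.08406, "I": 113.08406,
    "N": 114.04293, "D": 115.02694, "Q": 128.05858, "K": 128.09496,
    "E": 129.04259, "M": 131.04049, "H": 137.05891, "F": 147.06841,
    "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

# residue elemental compositions (no water)
RESIDUE_COMPOSITION = {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1}, "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2}, "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1}, "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1}, "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2}, "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2}, "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3}, "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1}, "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1}, "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
}

REMNANT_SEQUENCE = "DVFQQQTGG"
SUMO2_PRO_TAIL = "VY"
SUMO3_PRO_TAIL = "SASRGSVPTPNRCP"

EQUILIBRIUM_CLASSES = (
    "conjugated_to_targets",
    "chains",
    "free_mature",
    "immature_sumo2",
    "immature_sumo3",
    "internal",
)

FILTER_RULES = ("localization", "diagnostic_ions", "decoy", "delta")


def remnant_mass(remnant_sequence: str) -> tuple[float, str]:
    """Monoisotopic mass (Da) and elemental composition of a conjugated remnant.

    The remnant is an isopeptide-linked modification, so the mass is the sum
    of residue (in-chain) masses with no terminal water.  Returns
    ``(mass, formula)`` with the formula in Hill-ish CHNOS order.
    """
    mass = 0.0
    comp: dict[str, int] = {}
    for aa in remnant_sequence:
        if aa not in RESIDUE_MONO_MASS:
            raise ValidationError(f"unknown amino-acid letter {aa!r}")
        mass += RESIDUE_MONO_MASS[aa]
        for el, n in RESIDUE_COMPOSITION[aa].items():
            comp[el] = comp.get(el, 0) + n
    formula = "".join(
        f"{el}{comp[el]}" for el in ("C", "H", "N", "O", "S") if comp.get(el, 0)
    )
    return round(mass, 4), formula


@dataclass(frozen=True)
class PeptideRecord:
    """One row of search-engine modified-peptide evidence."""

    record_id: str
    sequence: str
    protein_id: str
    peptide_start: int  # 1-based position of the peptide in the protein
    sumo_mods: tuple[tuple[int, float], ...]  # (1-based pos in peptide, loc. prob)
    delta_score: float = 0.0
    decoy: bool = False
    diagnostic_ions: frozenset[str] = frozenset()
    source_protein_is_sumo_family: bool = False
    intensity: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pos, prob in self.sumo_mods:
            if not 1 <= pos <= len(self.sequence):
                raise ValidationError(
                    f"{self.record_id}: mod position {pos} outside peptide"
                )
            if not 0.0 <= prob <= 1.0:
                raise ValidationError(
                    f"{self.record_id}: localization probability {prob} outside [0, 1]"
                )

    @property
    def site_positions(self) -> tuple[int, ...]:
        """1-based protein positions of the SUMO-modified residues."""
        return tuple(self.peptide_start + pos - 1 for pos, _ in self.sumo_mods)


def records_from_table(table: pd.DataFrame) -> list[PeptideRecord]:
    """Parse a peptide TSV frame (the simulator's / a MaxQuant-like schema)."""
    intensity_cols = [c for c in table.columns if c.startswith("intensity_")]
    records = []
    for d in table.to_dict(orient="records"):
        positions = [int(x) for x in str(d["sumo_positions"]).split(";") if x not in ("", "nan")]
        probs = [float(x) for x in str(d["sumo_loc_probs"]).split(";") if x not in ("", "nan")]
        ions = frozenset(
            x for x in str(d.get("diagnostic_ions", "") or "").split(";") if x and x != "nan"
        )
        records.append(
            PeptideRecord(
                record_id=str(d["record_id"]),
                sequence=str(d["sequence"]),
                protein_id=str(d["protein_id"]),
                peptide_start=int(d["peptide_start"]),
                sumo_mods=tuple(zip(positions, probs)),
                delta_score=float(d["delta_score"]),
                decoy=bool(int(d["decoy"])),
                diagnostic_ions=ions,
                source_protein_is_sumo_family=bool(int(d["source_is_sumo"])),
                intensity={c[len("intensity_"):]: float(d[c]) for c in intensity_cols},
            )
        )
    return records


def filter_peptides(
    records: Iterable[PeptideRecord],
    proteins: Mapping[str, str],
    loc_prob: float = 0.75,
    delta: float = 40.0,
    min_diagnostic_ions: int = 1,
) -> tuple[list[PeptideRecord], list[tuple[PeptideRecord, str]]]:
    """Manual evidence filters; returns (accepted, rejected with primary reason).

    A SUMO-modified record is accepted iff every SUMO localization
    probability exceeds ``loc_prob``, at least ``min_diagnostic_ions``
    diagnostic remnant ions were observed, it is not a decoy hit, and — when
    a SUMO modification sits on the peptide's C-terminal lysine and the next
    residue in the protein is not Asp/Glu (so Asp-N/Glu-N cleavage cannot
    vouch for the position) — its delta score exceeds ``delta``.  The first
    failing rule, in that order, is the rejection reason.  Records without
    SUMO modifications (SUMO-derived peptides) only face the decoy rule.
    """
    accepted: list[PeptideRecord] = []
    rejected: list[tuple[PeptideRecord, str]] = []
    for rec in records:
        reason = _first_failure(rec, proteins, loc_prob, delta, min_diagnostic_ions)
        if reason is None:
            accepted.append(rec)
        else:
            rejected.append((rec, reason))
    return accepted, rejected


def _first_failure(
    rec: PeptideRecord,
    proteins: Mapping[str, str],
    loc_prob: float,
    delta: float,
    min_ions: int,
) -> str | None:
    if rec.sumo_mods:
        if any(prob <= loc_prob for _, prob in rec.sumo_mods):
            return "localization"
        if len(rec.diagnostic_ions) < min_ions:
            return "diagnostic_ions"
    if rec.decoy:
        return "decoy"
    if rec.sumo_mods and _needs_delta_rule(rec, proteins):
        if rec.delta_score <= delta:
            return "delta"
    return None


def _needs_delta_rule(rec: PeptideRecord, proteins: Mapping[str, str]) -> bool:
    """True when a SUMO mod sits on the C-terminal K and no D/E follows in the protein."""
    cterm = len(rec.sequence)
    if not any(pos == cterm for pos, _ in rec.sumo_mods):
        return False
    if rec.sequence[-1] != "K":
        return False
    if rec.protein_id not in proteins:
        raise EvidenceError(
            f"{rec.record_id}: protein sequence for {rec.protein_id} required "
            "by the C-terminal-lysine delta rule"
        )
    protein = proteins[rec.protein_id]
    next_pos0 = rec.peptide_start - 1 + cterm  # 0-based residue after the peptide
    if next_pos0 >= len(protein):  # K is the protein C-terminus: nothing follows
        return True
    return protein[next_pos0] not in "DE"


def resolve_multiply_sumoylated(
    accepted: Sequence[PeptideRecord],
) -> list[PeptideRecord]:
    """Keep multiply-SUMOylated peptides only when all sites have single support."""
    singly = {
        (rec.protein_id, rec.site_positions[0])
        for rec in accepted
        if len(rec.sumo_mods) == 1
    }
    out = []
    for rec in accepted:
        if len(rec.sumo_mods) <= 1:
            out.append(rec)
        elif all((rec.protein_id, p) in singly for p in rec.site_positions):
            out.append(rec)
        else:
            logger.info("discarding multiply-SUMOylated peptide %s", rec.record_id)
    return out


def map_sites(
    accepted: Sequence[PeptideRecord],
    proteins: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, set[str]]:
    """Collapse peptide evidence to SUMO sites and the target-protein set.

    Site position = peptide_start + mod-position-in-peptide - 1 (1-based in
    the protein); site intensity per sample is the sum over supporting
    peptides.  Every protein with >= 1 site is a SUMO target.
    """
    sites: dict[tuple[str, int], dict] = {}
    for rec in accepted:
        for protein_pos in rec.site_positions:
            if proteins is not None:
                seq = proteins.get(rec.protein_id)
                if seq is None or not 1 <= protein_pos <= len(seq):
                    raise ValidationError(
                        f"{rec.record_id}: site {rec.protein_id}:{protein_pos} "
                        "outside the protein sequence"
                    )
                if seq[protein_pos - 1] != "K":
                    raise ValidationError(
                        f"{rec.record_id}: residue at {rec.protein_id}:{protein_pos} "
                        f"is {seq[protein_pos - 1]}, not K"
                    )
            key = (rec.protein_id, protein_pos)
            entry = sites.setdefault(
                key, {"intensity": {}, "supporting_peptides": []}
            )
            entry["supporting_peptides"].append(rec.record_id)
            for sample, value in rec.intensity.items():
                entry["intensity"][sample] = entry["intensity"].get(sample, 0.0) + value
    rows = []
    for (protein_id, pos), entry in sorted(sites.items()):
        rows.append(
            {
                "protein_id": protein_id,
                "residue_position": pos,
                "n_peptides": len(entry["supporting_peptides"]),
                "supporting_peptides": ";".join(sorted(entry["supporting_peptides"])),
                **{f"intensity_{s}": v for s, v in sorted(entry["intensity"].items())},
            }
        )
    site_table = pd.DataFrame(rows)
    targets = set(site_table["protein_id"]) if not site_table.empty else set()
    return site_table, targets


def sumo_density(
    site_table: pd.DataFrame, input_mg: Mapping[str, float]
) -> pd.DataFrame:
    """Total SUMO site intensity (arb. units) per mg input protein, per replicate.

    Returns one row per replicate plus mean and SD rows appended as columns
    ``density``; mean/SD follow the average ± standard deviation convention.
    """
    rows = []
    for sample, mg in input_mg.items():
        if mg <= 0:
            raise ParameterError(f"input protein amount for {sample} must be > 0 mg")
        col = f"intensity_{sample}"
        total = float(site_table[col].sum()) if col in site_table.columns else 0.0
        rows.append({"sample_id": sample, "total_intensity": total, "input_mg": mg,
                     "density": total / mg})
    out = pd.DataFrame(rows)
    out.attrs["mean"] = float(out["density"].mean()) if len(out) else 0.0
    out.attrs["sd"] = float(out["density"].std(ddof=1)) if len(out) > 1 else 0.0
    return out


def classify_record(rec: PeptideRecord) -> str | None:
    """Equilibrium class of one record; None when the record carries no SUMO signal.

    SUMO-modified peptides are *chains* when the host protein is itself a
    SUMO family member, otherwise *conjugated_to_targets*.  SUMO-derived
    (unmodified) peptides ending in QQTGG are *free_mature*; those containing
    QQTGG internally are immature SUMO-2 (propeptide tail starting VY) or
    immature SUMO-3 (tail starting SASRGSVPTPNRCP); anything else from a
    SUMO protein is *internal*.
    """
    if rec.sumo_mods:
        return "chains" if rec.source_protein_is_sumo_family else "conjugated_to_targets"
    if not rec.source_protein_is_sumo_family:
        return None
    seq = rec.sequence
    if seq.endswith("QQTGG"):
        return "free_mature"
    idx = seq.find("QQTGG")
    if idx >= 0:
        tail = seq[idx + 5 :]
        if tail.startswith(SUMO2_PRO_TAIL):
            return "immature_sumo2"
        if tail.startswith(SUMO3_PRO_TAIL):
            return "immature_sumo3"
        logger.warning("%s: unclassifiable post-QQTGG tail %r", rec.record_id, tail)
        return "internal"
    return "internal"


def classify_equilibrium(
    records: Iterable[PeptideRecord], time_points: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-time-point intensity fractions of the six SUMO equilibrium classes.

    Sample keys are expected as ``<timepoint>_<replicate>``; intensities are
    summed over replicates within a time point before taking fractions.
    Fractions sum to 1 per time point (all-zero time points excluded).
    """
    totals: dict[str, dict[str, float]] = {}
    for rec in records:
        klass = classify_record(rec)
        if klass is None:
            logger.info("%s carries no SUMO signal; excluded from equilibrium", rec.record_id)
            continue
        for sample, value in rec.intensity.items():
            tp = sample.rsplit("_", 1)[0]
            totals.setdefault(tp, dict.fromkeys(EQUILIBRIUM_CLASSES, 0.0))
            totals[tp][klass] += value
    tps = list(time_points) if time_points is not None else sorted(totals)
    rows = []
    for tp in tps:
        class_totals = totals.get(tp, dict.fromkeys(EQUILIBRIUM_CLASSES, 0.0))
        grand = sum(class_totals.values())
        if grand <= 0:
            logger.warning("time point %s has zero SUMO intensity; skipped", tp)
            continue
        rows.append({"time_point": tp, **{k: v / grand for k, v in class_totals.items()}})
    return pd.DataFrame(rows)


def lfq_summarize(
    site_matrix: pd.DataFrame,
    sample_map: Mapping[str, str] | None = None,
    seed: int = 0,
    impute_width: float = 0.3,
    impute_downshift: float = 1.8,
) -> pd.DataFrame:
    """Replicate-average, log2, impute and row-Z a site intensity matrix.

    Zeros are treated as missing.  Replicates (columns ``<tp>_<rep>``) are
    averaged per time point over their observed values; the average is log2
    transformed; remaining missing entries are drawn from a downshifted
    Gaussian (mean - ``impute_downshift``*SD, width ``impute_width``*SD, of
    the row's observed log2 values; matrix-wide SD when a row has < 2
    observations); finally each row is Z-scored with the sample SD.
    All-missing rows are dropped with a log entry.
    """
    mat = site_matrix.replace(0.0, np.nan)
    if sample_map is None:
        sample_map = {c: c.rsplit("_", 1)[0] for c in mat.columns}
    grouped = mat.T.groupby(mat.columns.map(sample_map.__getitem__)).mean().T
    log2 = np.log2(grouped)

    all_missing = log2.isna().all(axis=1)
    for fid in log2.index[all_missing]:
        logger.warning("feature %s has no quantified values; dropped", fid)
    log2 = log2.loc[~all_missing]

    rng = np.random.default_rng(seed)
    values = log2.to_numpy()
    global_sd = float(np.nanstd(values, ddof=1)) if np.isfinite(values).sum() > 1 else 1.0
    for i in range(values.shape[0]):
        row = values[i]
        missing = np.isnan(row)
        if not missing.any():
            continue
        observed = row[~missing]
        mean = float(observed.mean())
        sd = float(observed.std(ddof=1)) if observed.size > 1 else global_sd
        if not math.isfinite(sd) or sd == 0.0:
            sd = global_sd
        row[missing] = rng.normal(
            mean - impute_downshift * sd, impute_width * sd, size=int(missing.sum())
        )
    imputed = pd.DataFrame(values, index=log2.index, columns=log2.columns)

    centered = imputed.sub(imputed.mean(axis=1), axis=0)
    sd = imputed.std(axis=1, ddof=1)
    z = centered.div(sd.replace(0.0, np.nan), axis=0).fillna(0.0)
    return z


__all__ = [
    "PeptideRecord",
    "records_from_table",
    "remnant_mass",
    "filter_peptides",
    "resolve_multiply_sumoylated",
    "map_sites",
    "sumo_density",
    "classify_record",
    "classify_equilibrium",
    "lfq_summarize",
    "EQUILIBRIUM_CLASSES",
    "FILTER_RULES",
    "REMNANT_SEQUENCE",
    "RESIDUE_MONO_MASS",
]
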