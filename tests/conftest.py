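import numpy as np
import pandas as pd
import pytest

from sumowaves import proteomics, simulate


@pytest.fixture(scope="session")
def peptide_bundle():
    """Peptide table + truth + proteins at the default proteomics spec (>= 200 records)."""
    cfg = simulate.SimConfig(
        seed=11,
        proteomics_spec=simulate.ProteomicsSpec(
            n_true=60, n_loc_fail=15, n_ion_fail=15, n_decoy=15, n_delta_fail=15,
            n_multi_supported=8, n_multi_unsupported=8,
            n_free_mature=10, n_immature_sumo2=10, n_immature_sumo3=10,
            n_internal=10, n_chain=10,
        ),
    )
    table, truth, proteins = simulate.gen_peptide_table(cfg)
    records = proteomics.records_from_table(table)
    return cfg, table, truth.set_index("record_id"), proteins, records


@pytest.fixture(scope="session")
def slam_bundle(tmp_path_factory):
    """Toy genome, UTRs and ~2k reads with planted labeled fraction 0.3 and SNPs."""
    cfg = simulate.SimConfig(
        seed=7, n_genes=2, depth=500, n_replicates=1, time_points=("d-2", "d1"),
        labeled_fraction=0.3, conversion_rate=0.02, seq_error_rate=0.001, n_snps=6,
    )
    genome, utrs = simulate.gen_reference(cfg)
    reads, truth, snps = simulate.gen_slam_reads(cfg, genome, utrs)
    sam = tmp_path_factory.mktemp("slam") / "reads.sam"
    simulate.write_sam(reads, genome, sam)
    return cfg, genome, utrs, reads, truth, snps, sam


@pytest.fixture(scope="session")
def chip_bundle(tmp_path_factory):
    """Per-time-point peak sets and reads with planted stage-specific occupancy."""
    cfg = simulate.SimConfig(
        seed=13, n_replicates=2,
        peak_spec=simulate.PeakSpec(n_flat=30, n_per_stage=6),
    )
    peaks, reads, genome, truth = simulate.gen_peak_fixture(cfg)
    sam = tmp_path_factory.mktemp("chip") / "reads.sam"
    simulate.write_sam(reads, genome, sam)
    return cfg, peaks, reads, genome, truth, sam


def naive_union(intervals):
    """O(n^2) fixpoint merge oracle: merge any overlapping/bookended pair until stable."""
    items = [list(t) for t in intervals]
    changed = True
    while changed:
        changed = False
        out = []
        while items:
            cur = items.pop()
            merged = False
            for other in items:
                if cur[0] == other[0] and cur[1] <= other[2] and other[1] <= cur[2]:
                    other[1] = min(cur[1], other[1])
                    other[2] = max(cur[2], other[2])
                    merged = changed = True
                    break
            if not merged:
                out.append(cur)
        items = out
    return sorted(map(tuple, items))
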