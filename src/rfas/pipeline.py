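"""End-to-end driver: subsampling, FS screening, aggregation, RFS check."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import rfs_validate as rfs
from .fs_core import AlgorithmSettings, FSRunResult, ReplicabilityReport, fs_aggregate, fs_run
from .rfs_validate import RFSReport
from .synthgen import Dataset, split_subsamples

__all__ = ["RFASResult", "run_rfas"]


@dataclass
class RFASResult:
    report: ReplicabilityReport
    rfs: RFSReport | None
    structure: dict[str, str] | None
    cfa_k: int  # factor count of the final CFA (may be below the modal k)
    runs: list[FSRunResult]


def run_rfas(data: Dataset, settings: AlgorithmSettings) -> RFASResult:
    """Full two-stage procedure on one dataset.

    Stage 1 runs the FS screening loop on each of R training subsamples and
    aggregates the retention evidence.  Stage 2 assigns the surviving
    variables to factors via a full-sample EFA and re-estimates the implied
    congeneric CFA on every validation subsample.  If the modal factor count
    cannot be identified with 3 indicators per factor among the survivors,
    the CFA factor count is decremented until it can.
    """
    master = np.random.SeedSequence(settings.seed)
    split_seed, *run_seeds = [
        int(s.generate_state(1)[0] % (2**31 - 1))
        for s in master.spawn(settings.R + 1)
    ]
    splits = split_subsamples(data, settings.R, settings.train_fraction, split_seed)
    runs = [
        fs_run(data.rows(train), settings, seed=run_seeds[i])
        for i, (train, _) in enumerate(splits)
    ]
    report = fs_aggregate(runs, settings)

    structure = None
    rfs_report = None
    cfa_k = report.final_k
    if len(report.final_variables) >= 3:
        while cfa_k >= 1:
            try:
                structure = rfs.build_cfa_structure(
                    report.final_variables, cfa_k, data, settings
                )
                break
            except ValueError:
                cfa_k -= 1
        if structure is not None:
            rfs_report = rfs.rfs_validate(splits, structure, data, settings)
    return RFASResult(
        report=report, rfs=rfs_report, structure=structure, cfa_k=cfa_k, runs=runs
    )
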