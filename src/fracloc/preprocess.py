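"""Transcript- and sample-level filters applied before beta estimation.

All filters subset rows of a :class:`~fracloc.io_quant.FractionQuantSet`
without touching the surviving numeric values (CPM/FPKM are computed once,
on the unfiltered tables).
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from fracloc.errors import DegenerateDataError, FormatError
from fracloc.io_quant import FractionQuantSet, TranscriptMeta

logger = logging.getLogger(__name__)


def _require_column(fqs: FractionQuantSet, name: str, hint: str) -> None:
    for label, df in fqs.fractions.items():
        if df[name].isna().any():
            raise FormatError(
                f"{name} not computed for fraction {label!r}; run {hint} first"
            )


def filter_by_cpm(fqs: FractionQuantSet, threshold: float = 1.0) -> FractionQuantSet:
    """Keep transcripts with whole-cell CPM >= threshold and at least one of
    the nuclear/cytosolic CPMs >= threshold (inclusive comparisons)."""
    _require_column(fqs, "cpm", "compute_cpm")
    cpm = fqs.column("cpm")
    keep = (cpm["whole_cell"] >= threshold) & (
        (cpm["nuclear"] >= threshold) | (cpm["cytosolic"] >= threshold)
    )
    logger.info(
        "filter_by_cpm: retained %d/%d transcripts (threshold=%g)",
        int(keep.sum()), len(keep), threshold,
    )
    return fqs.subset(fqs.transcript_ids[keep])


def filter_mitochondrial(
    fqs: FractionQuantSet, meta: Sequence[TranscriptMeta]
) -> FractionQuantSet:
    """Drop transcripts encoded on the mitochondrial chromosome.

    Chromosome names {chrM, chrMT, MT, M} are matched case-insensitively.
    Every transcript in ``fqs`` must have a metadata record.
    """
    by_id = {m.transcript_id: m for m in meta}
    missing = [t for t in fqs.transcript_ids if t not in by_id]
    if missing:
        raise FormatError(
            f"{len(missing)} transcripts lack metadata, e.g. {missing[:5]}"
        )
    keep = [t for t in fqs.transcript_ids if not by_id[t].is_mitochondrial]
    n_dropped = len(fqs) - len(keep)
    if n_dropped:
        logger.info("filter_mitochondrial: removed %d transcripts", n_dropped)
    return fqs.subset(keep)


def filter_replicate_presence(
    reps: Sequence[FractionQuantSet],
) -> list[FractionQuantSet]:
    """Restrict every replicate to the transcripts present in all replicates.

    A surrogate for the npIDR reproducibility filter: run the transcript-level
    filters per replicate first, then intersect. A single replicate passes
    through unchanged.
    """
    if not reps:
        raise DegenerateDataError("no replicates given")
    if len(reps) == 1:
        return list(reps)
    common = reps[0].transcript_ids
    for rep in reps[1:]:
        common = common.intersection(rep.transcript_ids)
    logger.info(
        "filter_replicate_presence: %d transcripts present in all %d replicates",
        len(common), len(reps),
    )
    return [rep.subset(common) for rep in reps]


def apply_keep_list(fqs: FractionQuantSet, keep_ids: Iterable[str]) -> FractionQuantSet:
    """Restrict to an externally computed keep-list (e.g. npIDR < 0.1 ids)."""
    return fqs.subset(pd.Index(list(keep_ids)))


def read_keep_list(path) -> list[str]:
    """Read a plain-text keep-list: one transcript id per line."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def dai_outlier_filter(fqs: FractionQuantSet) -> FractionQuantSet:
    """Keep transcripts whose whole-cell FPKM lies within the closed interval
    spanned by their nuclear and cytosolic FPKMs (boundaries inclusive)."""
    _require_column(fqs, "fpkm", "compute_fpkm")
    fpkm = fqs.column("fpkm")
    lo = np.minimum(fpkm["nuclear"], fpkm["cytosolic"])
    hi = np.maximum(fpkm["nuclear"], fpkm["cytosolic"])
    keep = (fpkm["whole_cell"] >= lo) & (fpkm["whole_cell"] <= hi)
    logger.info(
        "dai_outlier_filter: retained %d/%d transcripts", int(keep.sum()), len(keep)
    )
    return fqs.subset(fqs.transcript_ids[keep])


def exclude_high_beta_samples(
    estimates: Mapping[str, float], cutoff: float = 0.95
) -> list[str]:
    """Samples with estimated beta > cutoff (strictly) are excluded; returns
    the retained sample ids in input order."""
    for sample, beta in estimates.items():
        if not 0.0 <= beta <= 1.0:
            raise FormatError(f"sample {sample!r}: beta {beta} outside [0, 1]")
    retained = [s for s, b in estimates.items() if b <= cutoff]
    excluded = [s for s in estimates if s not in retained]
    if excluded:
        logger.info("exclude_high_beta_samples: excluded %s", excluded)
    return retained
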