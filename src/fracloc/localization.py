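"""Per-transcript localization index (LI) and localization classification.

LI(i) = beta * fpkm_c(i) / ((1 - beta) * fpkm_n(i) + beta * fpkm_c(i))
estimates the proportion of transcript i's molecules that reside in the
cytosol. The naive LI, fpkm_c / (fpkm_n + fpkm_c), coincides with LI only
when beta = 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from fracloc.errors import DegenerateDataError, FormatError
from fracloc.io_quant import FractionQuantSet

logger = logging.getLogger(__name__)

CLASS_SCHEMES = ("threshold_04_06", "halfline")


@dataclass
class LocalizationTable:
    """Per-transcript LI values for one sample (or replicate average).

    ``data`` is indexed by transcript_id with columns ``li``, ``naive_li``
    and ``class_label`` (NaN / "unassigned" until classified). ``beta_used``
    is None for averaged tables; the per-replicate betas live in
    ``provenance``.
    """

    data: pd.DataFrame
    beta_used: float | None = None
    sample_id: str = "sample"
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def li(self) -> pd.Series:
        return self.data["li"]

    @property
    def naive_li(self) -> pd.Series:
        return self.data["naive_li"]

    def write_tsv(self, path) -> None:
        out = self.data.copy()
        out["beta_used"] = self.beta_used if self.beta_used is not None else np.nan
        out.to_csv(path, sep="\t", float_format="%.17g")


def _as_arrays(fpkm_n, fpkm_c):
    n = np.asarray(fpkm_n, float)
    c = np.asarray(fpkm_c, float)
    if (n < 0).any() or (c < 0).any():
        raise FormatError("fpkm values must be non-negative")
    return n, c


def localization_index(fpkm_n, fpkm_c, beta: float):
    """LI for scalar or vector FPKMs; NaN where both FPKMs are zero."""
    if not 0.0 < beta < 1.0:
        raise FormatError(f"beta must be in (0, 1), got {beta}")
    scalar = np.isscalar(fpkm_n) and np.isscalar(fpkm_c)
    n, c = _as_arrays(np.atleast_1d(fpkm_n), np.atleast_1d(fpkm_c))
    denom = (1.0 - beta) * n + beta * c
    with np.errstate(invalid="ignore", divide="ignore"):
        li = np.where(denom > 0, beta * c / denom, np.nan)
    n_undef = int(np.isnan(li).sum())
    if n_undef:
        logger.info("localization_index: %d transcripts with both FPKMs zero", n_undef)
    return float(li[0]) if scalar else li


def naive_li(fpkm_n, fpkm_c):
    """fpkm_c / (fpkm_n + fpkm_c); NaN where both FPKMs are zero."""
    scalar = np.isscalar(fpkm_n) and np.isscalar(fpkm_c)
    n, c = _as_arrays(np.atleast_1d(fpkm_n), np.atleast_1d(fpkm_c))
    denom = n + c
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, c / denom, np.nan)
    return float(out[0]) if scalar else out


def li_table(fqs: FractionQuantSet, beta: float) -> LocalizationTable:
    """Vectorized LI and naive LI over all transcripts of one replicate."""
    fn = fqs.fpkm("nuclear").to_numpy()
    fc = fqs.fpkm("cytosolic").to_numpy()
    if len(fqs) and (np.isnan(fn).any() or np.isnan(fc).any()):
        raise FormatError("fpkm not computed; run compute_fpkm first")
    data = pd.DataFrame(
        {
            "li": localization_index(fn, fc, beta) if len(fqs) else [],
            "naive_li": naive_li(fn, fc) if len(fqs) else [],
            "class_label": "unassigned",
        },
        index=fqs.transcript_ids,
    )
    return LocalizationTable(
        data=data,
        beta_used=float(beta),
        sample_id=fqs.sample_id,
        provenance={"replicate_id": fqs.replicate_id, "beta": float(beta)},
    )


def average_li_across_replicates(
    tables: Sequence[LocalizationTable],
) -> LocalizationTable:
    """Arithmetic mean of LI (and naive LI) across replicate tables sharing a
    transcript index. Missing values propagate as missing."""
    if not tables:
        raise DegenerateDataError("no tables given")
    if len(tables) == 1:
        return tables[0]
    index = tables[0].data.index
    for t in tables[1:]:
        if not t.data.index.equals(index):
            raise FormatError(
                "replicate tables have mismatched transcript indices; apply "
                "filter_replicate_presence first"
            )
    li = np.mean([t.data["li"].to_numpy() for t in tables], axis=0)
    nli = np.mean([t.data["naive_li"].to_numpy() for t in tables], axis=0)
    data = pd.DataFrame(
        {"li": li, "naive_li": nli, "class_label": "unassigned"}, index=index
    )
    return LocalizationTable(
        data=data,
        beta_used=None,
        sample_id=tables[0].sample_id,
        provenance={"replicate_betas": [t.beta_used for t in tables]},
    )


def classify_localization(
    table: LocalizationTable, scheme: str = "threshold_04_06"
) -> LocalizationTable:
    """Label transcripts nuclear/cytosolic/unassigned from their LI.

    ``threshold_04_06``: nuclear if LI < 0.4, cytosolic if LI > 0.6, else
    unassigned. ``halfline``: cytosolic if LI >= 0.5, else nuclear.
    Missing LI stays unassigned.
    """
    if scheme not in CLASS_SCHEMES:
        raise FormatError(f"unknown scheme {scheme!r}; choose from {CLASS_SCHEMES}")
    li = table.data["li"].to_numpy()
    labels = np.full(li.shape, "unassigned", dtype=object)
    defined = ~np.isnan(li)
    if scheme == "threshold_04_06":
        labels[defined & (li < 0.4)] = "nuclear"
        labels[defined & (li > 0.6)] = "cytosolic"
    else:
        labels[defined & (li >= 0.5)] = "cytosolic"
        labels[defined & (li < 0.5)] = "nuclear"
    data = table.data.copy()
    data["class_label"] = labels
    return LocalizationTable(
        data=data,
        beta_used=table.beta_used,
        sample_id=table.sample_id,
        provenance={**table.provenance, "scheme": scheme},
    )


def consistency_by_breadth(
    tables: Mapping[str, LocalizationTable],
) -> pd.DataFrame:
    """Cross-sample localization consistency, aggregated by expression breadth.

    For each transcript: the number of samples where it is expressed
    (LI defined), whether LI >= 0.5 in every such sample (always cytosolic)
    and whether LI <= 0.5 in every such sample (always nuclear). LI exactly
    0.5 counts toward both (boundary inclusive on both sides; occurrences
    are logged). Returns one row per breadth with counts and proportions.
    """
    if len(tables) < 2:
        raise FormatError("need at least 2 samples")
    li_wide = pd.DataFrame({name: t.data["li"] for name, t in tables.items()})
    expressed = li_wide.notna()
    n_expr = expressed.sum(axis=1)
    always_cyt = ((li_wide >= 0.5) | ~expressed).all(axis=1) & (n_expr > 0)
    always_nuc = ((li_wide <= 0.5) | ~expressed).all(axis=1) & (n_expr > 0)
    n_boundary = int((li_wide == 0.5).sum().sum())
    if n_boundary:
        logger.info(
            "consistency_by_breadth: %d LI values exactly 0.5 counted in both "
            "categories", n_boundary,
        )
    rows = []
    for breadth in range(1, len(tables) + 1):
        mask = n_expr == breadth
        total = int(mask.sum())
        ncyt = int((always_cyt & mask).sum())
        nnuc = int((always_nuc & mask).sum())
        rows.append(
            {
                "n_samples_expressed": breadth,
                "n_transcripts": total,
                "n_always_cytosolic": ncyt,
                "n_always_nuclear": nnuc,
                "prop_always_cytosolic": ncyt / total if total else np.nan,
                "prop_always_nuclear": nnuc / total if total else np.nan,
            }
        )
    return pd.DataFrame(rows)


def strong_localization_sets(
    tables: Mapping[str, LocalizationTable],
    min_samples: int = 5,
    cyt_cut: float = 0.9,
    nuc_cut: float = 0.3,
) -> tuple[list[str], list[str]]:
    """Strongly localized transcripts: expressed in >= min_samples samples and
    LI > cyt_cut (or < nuc_cut, strictly) in every sample where expressed."""
    li_wide = pd.DataFrame({name: t.data["li"] for name, t in tables.items()})
    expressed = li_wide.notna()
    broad = expressed.sum(axis=1) >= min_samples
    cyt = broad & ((li_wide > cyt_cut) | ~expressed).all(axis=1)
    nuc = broad & ((li_wide < nuc_cut) | ~expressed).all(axis=1)
    return list(li_wide.index[cyt]), list(li_wide.index[nuc])


def li_error(
    table: LocalizationTable, truth: pd.Series, column: str = "li"
) -> tuple[pd.Series, dict]:
    """Signed error of the (naive) LI against the true per-transcript
    cytosolic molecule proportion; returns (errors, summary)."""
    li = table.data[column]
    defined = li.dropna()
    missing = defined.index.difference(truth.index)
    if len(missing):
        raise FormatError(
            f"{len(missing)} transcripts lack ground truth, e.g. {list(missing[:5])}"
        )
    err = defined - truth.loc[defined.index]
    q1, q3 = np.percentile(err, [25, 75])
    summary = {
        "mean": float(err.mean()),
        "median": float(err.median()),
        "iqr": float(q3 - q1),
        "n": int(err.size),
    }
    return err, summary
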