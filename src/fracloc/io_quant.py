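"""Quantification table I/O and normalized abundance units (CPM, FPKM).

A per-fraction quantification is represented as a :class:`pandas.DataFrame`
with the columns ``transcript_id``, ``expected_count``, ``effective_length``,
``cpm`` and ``fpkm`` (the last two are NaN until computed). Matched fractions
of one replicate are bundled in a :class:`FractionQuantSet`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from fracloc.errors import DegenerateDataError, FormatError

logger = logging.getLogger(__name__)

FRACTIONS = ("whole_cell", "nuclear", "cytosolic")

QUANT_COLUMNS = ["transcript_id", "expected_count", "effective_length", "cpm", "fpkm"]

#: column aliases accepted for RSEM-style tables, in priority order
_COLUMN_ALIASES = {
    "transcript_id": ["transcript_id"],
    "effective_length": ["effective_length"],
    "expected_count": ["expected_count"],
}

_MITO_CHROMS = frozenset({"chrm", "chrmt", "mt", "m"})


def read_rsem_quant(path: str | Path, fraction_label: str | None = None) -> pd.DataFrame:
    """Read an RSEM ``isoforms.results``-style TSV into a quant frame.

    Only the ``transcript_id``, ``effective_length`` and ``expected_count``
    columns are required; ``cpm`` and ``fpkm`` are left unset (NaN) and are
    computed later by :func:`compute_cpm` / :func:`compute_fpkm`. File row
    order is preserved.

    Raises
    ------
    FormatError
        If a required column is missing, a count/length value does not
        parse as a number (the error names the line), or a transcript id
        is duplicated.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    for col, aliases in _COLUMN_ALIASES.items():
        if not any(a in raw.columns for a in aliases):
            raise FormatError(f"{path}: missing required column {col!r}")

    out = pd.DataFrame({"transcript_id": raw["transcript_id"].astype(str)})
    for col in ("expected_count", "effective_length"):
        numeric = pd.to_numeric(raw[col], errors="coerce")
        bad = numeric.isna() & raw[col].notna()
        if bad.any():
            # +2: header line plus 1-based numbering
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise FormatError(
                f"{path}: non-numeric value {raw[col][bad].iloc[0]!r} in column "
                f"{col!r} at line {line}"
            )
        out[col] = numeric.astype(float)

    dups = out["transcript_id"].duplicated()
    if dups.any():
        raise FormatError(
            f"{path}: duplicated transcript_id {out['transcript_id'][dups].iloc[0]!r}"
        )
    if (out["expected_count"] < 0).any():
        raise FormatError(f"{path}: negative expected_count")

    out["cpm"] = np.nan
    out["fpkm"] = np.nan
    if fraction_label is not None:
        out.attrs["fraction"] = fraction_label
    return out


def compute_cpm(quants: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with ``cpm = expected_count / sum(expected_count) * 1e6``.

    The denominator is the sum over *all* rows given, so CPM must be computed
    before any filtering subsets the table.
    """
    total = float(quants["expected_count"].sum())
    if total <= 0:
        raise DegenerateDataError("all expected counts are zero; CPM undefined")
    out = quants.copy()
    out["cpm"] = out["expected_count"] / total * 1e6
    return out


def compute_fpkm(quants: pd.DataFrame, library_size: float | None = None) -> pd.DataFrame:
    """Return a copy with ``fpkm = count * 1e9 / (effective_length * library_size)``.

    ``library_size`` defaults to the total expected count of the table
    (computed before any filtering). Rows with zero count get FPKM 0
    regardless of effective length.
    """
    if library_size is None:
        library_size = float(quants["expected_count"].sum())
    if library_size <= 0:
        raise DegenerateDataError("library_size must be positive")
    counts = quants["expected_count"].to_numpy(float)
    efflen = quants["effective_length"].to_numpy(float)
    bad = (counts > 0) & (efflen <= 0)
    if bad.any():
        tid = quants["transcript_id"].iloc[int(np.flatnonzero(bad)[0])]
        raise FormatError(
            f"transcript {tid!r} has expected_count > 0 but effective_length <= 0"
        )
    out = quants.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        fpkm = counts * 1e9 / (efflen * library_size)
    fpkm[counts == 0] = 0.0
    out["fpkm"] = fpkm
    return out


@dataclass
class FractionQuantSet:
    """Aligned per-transcript quantifications for one replicate.

    ``fractions`` maps each label in :data:`FRACTIONS` to a quant frame
    indexed by ``transcript_id``; all three frames share the same index in
    the same order.
    """

    sample_id: str
    replicate_id: str
    fractions: Mapping[str, pd.DataFrame]

    def __post_init__(self) -> None:
        missing = set(FRACTIONS) - set(self.fractions)
        if missing:
            raise FormatError(f"missing fractions: {sorted(missing)}")
        ref = self.fractions[FRACTIONS[0]].index
        if ref.has_duplicates:
            raise FormatError("duplicate transcript ids in fraction set")
        for label in FRACTIONS[1:]:
            if not self.fractions[label].index.equals(ref):
                raise FormatError(
                    f"fraction {label!r} index differs from {FRACTIONS[0]!r}"
                )

    @property
    def transcript_ids(self) -> pd.Index:
        return self.fractions[FRACTIONS[0]].index

    def __len__(self) -> int:
        return len(self.transcript_ids)

    def column(self, name: str) -> pd.DataFrame:
        """One column (e.g. ``fpkm``) across fractions as a wide frame."""
        return pd.DataFrame(
            {label: self.fractions[label][name] for label in FRACTIONS}
        )

    def fpkm(self, label: str) -> pd.Series:
        return self.fractions[label]["fpkm"]

    def cpm(self, label: str) -> pd.Series:
        return self.fractions[label]["cpm"]

    def subset(self, transcript_ids: Sequence[str] | pd.Index) -> "FractionQuantSet":
        """New set restricted to ``transcript_ids`` (original order kept)."""
        keep = self.transcript_ids.intersection(pd.Index(transcript_ids))
        keep = self.transcript_ids[self.transcript_ids.isin(keep)]
        return FractionQuantSet(
            self.sample_id,
            self.replicate_id,
            {label: df.loc[keep] for label, df in self.fractions.items()},
        )

    def to_tidy(self) -> pd.DataFrame:
        rows = []
        for label in FRACTIONS:
            df = self.fractions[label].reset_index()
            df.insert(1, "fraction", label)
            rows.append(df)
        return pd.concat(rows, ignore_index=True)

    def write_tsv(self, path: str | Path) -> None:
        self.to_tidy().to_csv(path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def read_tsv(
        cls, path: str | Path, sample_id: str = "sample", replicate_id: str = "1"
    ) -> "FractionQuantSet":
        tidy = pd.read_csv(path, sep="\t")
        fractions = {}
        for label, grp in tidy.groupby("fraction"):
            fractions[label] = (
                grp.drop(columns="fraction").set_index("transcript_id").astype(float)
            )
        return cls(sample_id, replicate_id, fractions)


def _indexed(quants: pd.DataFrame) -> pd.DataFrame:
    df = quants.set_index("transcript_id") if "transcript_id" in quants.columns else quants
    if df.index.has_duplicates:
        raise FormatError("duplicate transcript ids")
    return df


def assemble_fraction_set(
    whole: pd.DataFrame,
    nuclear: pd.DataFrame,
    cytosolic: pd.DataFrame,
    sample_id: str = "sample",
    replicate_id: str = "1",
) -> FractionQuantSet:
    """Align the three fraction tables on their common transcripts.

    Transcripts absent from any fraction are dropped (count logged); the
    output keeps the whole-cell file order.
    """
    frames = {
        "whole_cell": _indexed(whole),
        "nuclear": _indexed(nuclear),
        "cytosolic": _indexed(cytosolic),
    }
    common = frames["whole_cell"].index
    for df in frames.values():
        common = common.intersection(df.index)
    if len(common) == 0:
        raise DegenerateDataError("no transcripts shared by all three fractions")
    order = frames["whole_cell"].index
    order = order[order.isin(common)]
    dropped = sum(len(df) - len(order) for df in frames.values())
    if dropped:
        logger.info("assemble_fraction_set: dropped %d fraction rows outside the "
                    "3-way intersection (%d transcripts kept)", dropped, len(order))
    return FractionQuantSet(
        sample_id, replicate_id, {k: df.loc[order] for k, df in frames.items()}
    )


@dataclass
class TranscriptMeta:
    """Minimal transcript annotation: location, biotype and exon structure.

    Coordinates are 1-based inclusive, as in GTF.
    """

    transcript_id: str
    gene_id: str
    biotype: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        for start, end in self.exons:
            if start > end:
                raise FormatError(
                    f"{self.transcript_id}: exon start {start} > end {end}"
                )
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise FormatError(f"{self.transcript_id}: overlapping exons")
        if self.cds is not None:
            self.cds = sorted((int(s), int(e)) for s, e in self.cds)

    @property
    def is_mitochondrial(self) -> bool:
        return self.chromosome.lower() in _MITO_CHROMS


def read_gtf_metadata(path: str | Path) -> list[TranscriptMeta]:
    """Parse transcript metadata from a GTF file (GENCODE/Ensembl dialects).

    Biotype is taken from ``transcript_type``, falling back to
    ``transcript_biotype``. Exons come back sorted by start.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    records: dict[str, dict] = {}
    for ftype in ("exon", "CDS"):
        for feat in db.features_of_type(ftype):
            if "transcript_id" not in feat.attributes:
                raise FormatError(
                    f"{path}: {ftype} feature at {feat.seqid}:{feat.start} lacks "
                    "a transcript_id attribute"
                )
            tid = feat.attributes["transcript_id"][0]
            rec = records.setdefault(
                tid,
                {
                    "gene_id": feat.attributes.get("gene_id", [""])[0],
                    "biotype": (
                        feat.attributes.get("transcript_type")
                        or feat.attributes.get("transcript_biotype")
                        or [""]
                    )[0],
                    "chromosome": feat.seqid,
                    "strand": feat.strand,
                    "exons": [],
                    "cds": [],
                },
            )
            key = "exons" if ftype == "exon" else "cds"
            rec[key].append((feat.start, feat.end))
    return [
        TranscriptMeta(
            transcript_id=tid,
            gene_id=rec["gene_id"],
            biotype=rec["biotype"],
            chromosome=rec["chromosome"],
            strand=rec["strand"],
            exons=rec["exons"],
            cds=rec["cds"] or None,
        )
        for tid, rec in records.items()
    ]


def quant_frame(
    transcript_ids: Iterable[str],
    expected_count: np.ndarray,
    effective_length: np.ndarray,
) -> pd.DataFrame:
    """Build a quant frame from arrays (helper for the simulator and tests)."""
    return pd.DataFrame(
        {
            "transcript_id": list(transcript_ids),
            "expected_count": np.asarray(expected_count, float),
            "effective_length": np.asarray(effective_length, float),
            "cpm": np.nan,
            "fpkm": np.nan,
        }
    )
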