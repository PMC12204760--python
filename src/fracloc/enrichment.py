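"""Downstream statistics: transcript features, class comparisons, and
enrichment of splicing-efficiency categories in localization-specific
exon/intron sets."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from fracloc.errors import DegenerateDataError, FormatError
from fracloc.io_quant import TranscriptMeta

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = [
    "total_intron_length",
    "total_exon_length",
    "n_introns",
    "gc_content",
    "utr5_length",
    "utr3_length",
]


@dataclass
class EnrichmentResult:
    set_name: str
    k_hits_in_set: int
    n_set: int
    K_hits_total: int
    N_total: int
    enrichment_ratio: float
    p_value: float
    p_adjusted: float

    def to_dict(self) -> dict:
        return {
            "set_name": self.set_name,
            "k_hits_in_set": self.k_hits_in_set,
            "n_set": self.n_set,
            "K_hits_total": self.K_hits_total,
            "N_total": self.N_total,
            "enrichment_ratio": self.enrichment_ratio,
            "p_value": self.p_value,
            "p_adjusted": self.p_adjusted,
        }


def _spliced_sequence(meta: TranscriptMeta, chrom_seq: str) -> str:
    parts = []
    for start, end in meta.exons:
        if end > len(chrom_seq):
            raise FormatError(
                f"{meta.transcript_id}: exon ({start},{end}) outside chromosome "
                f"{meta.chromosome} (length {len(chrom_seq)})"
            )
        parts.append(chrom_seq[start - 1 : end])
    return "".join(parts)


def _utr_lengths(meta: TranscriptMeta) -> tuple[float, float]:
    """Exonic nucleotides upstream/downstream of the CDS, strand-aware.

    Returns (utr5, utr3); NaN when no CDS is annotated.
    """
    if not meta.cds:
        return (np.nan, np.nan)
    cds_start = min(s for s, _ in meta.cds)
    cds_end = max(e for _, e in meta.cds)
    left = sum(
        max(0, min(e, cds_start - 1) - s + 1) for s, e in meta.exons if s < cds_start
    )
    right = sum(
        max(0, e - max(s, cds_end + 1) + 1) for s, e in meta.exons if e > cds_end
    )
    if meta.strand == "-":
        left, right = right, left
    return (float(left), float(right))


def compute_transcript_features(
    metas: Sequence[TranscriptMeta],
    sequences: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-transcript structural features from exon/CDS annotation.

    total_exon_length sums exon spans (1-based inclusive), total_intron_length
    is the genomic span minus the exonic length, UTR lengths come from CDS
    bounds when present, and GC content is computed over the spliced sequence
    when ``sequences`` (a chromosome -> sequence mapping, e.g. pyfaidx.Fasta)
    is provided.
    """
    rows = []
    for meta in metas:
        if not meta.exons:
            raise FormatError(f"{meta.transcript_id}: no exons")
        exon_len = sum(e - s + 1 for s, e in meta.exons)
        span = meta.exons[-1][1] - meta.exons[0][0] + 1
        utr5, utr3 = _utr_lengths(meta)
        gc = np.nan
        if sequences is not None:
            if meta.chromosome not in sequences:
                raise FormatError(
                    f"{meta.transcript_id}: chromosome {meta.chromosome!r} "
                    "missing from sequences"
                )
            seq = _spliced_sequence(meta, str(sequences[meta.chromosome])).upper()
            gc = (seq.count("G") + seq.count("C")) / len(seq) if seq else np.nan
        rows.append(
            {
                "transcript_id": meta.transcript_id,
                "total_intron_length": span - exon_len,
                "total_exon_length": exon_len,
                "n_introns": len(meta.exons) - 1,
                "gc_content": gc,
                "utr5_length": utr5,
                "utr3_length": utr3,
            }
        )
    return pd.DataFrame(rows).set_index("transcript_id")


def compare_features_by_class(
    features: pd.DataFrame, classes: pd.Series
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum test per feature between nuclear and
    cytosolic transcripts; reports p-value and cytosolic-minus-nuclear
    median difference."""
    nuclear = features.loc[classes[classes == "nuclear"].index.intersection(features.index)]
    cytosolic = features.loc[classes[classes == "cytosolic"].index.intersection(features.index)]
    if len(nuclear) < 2 or len(cytosolic) < 2:
        raise DegenerateDataError("need at least 2 transcripts per class")
    rows = []
    for col in features.columns:
        x = cytosolic[col].dropna().to_numpy()
        y = nuclear[col].dropna().to_numpy()
        if len(x) < 2 or len(y) < 2:
            continue
        stat = stats.mannwhitneyu(x, y, alternative="two-sided")
        rows.append(
            {
                "feature": col,
                "median_cytosolic": float(np.median(x)),
                "median_nuclear": float(np.median(y)),
                "median_diff": float(np.median(x) - np.median(y)),
                "p_value": float(stat.pvalue),
            }
        )
    return pd.DataFrame(rows).set_index("feature")


def localization_specific_sets(
    feature_to_transcripts: Mapping[str, Sequence[str]],
    classes: pd.Series,
) -> tuple[list[str], list[str]]:
    """Features (exons/introns) hosted exclusively by nuclear or exclusively
    by cytosolic transcripts. Any unassigned or unclassified host transcript
    disqualifies the feature (strict reading of "only")."""
    nuclear_specific, cytosolic_specific = [], []
    for feature_id, hosts in feature_to_transcripts.items():
        if not hosts:
            continue
        labels = {classes.get(t, "unassigned") for t in hosts}
        if labels == {"nuclear"}:
            nuclear_specific.append(feature_id)
        elif labels == {"cytosolic"}:
            cytosolic_specific.append(feature_id)
    return nuclear_specific, cytosolic_specific


def enrichment_test(
    hits_in_set: int,
    set_size: int,
    hits_total: int,
    universe: int,
    n_tests: int = 1,
    set_name: str = "",
) -> EnrichmentResult:
    """Over-representation of a hit category inside a feature set.

    enrichment_ratio = (k/n) / (K/N); p-value is the upper-tail
    hypergeometric P(X >= k) for X ~ Hypergeom(N, K, n); Bonferroni
    adjustment multiplies by n_tests and caps at 1.
    """
    k, n, K, N = hits_in_set, set_size, hits_total, universe
    if not (0 <= k <= min(n, K) and 0 < n <= N and 0 <= K <= N):
        raise FormatError(
            f"invalid counts: k={k}, n={n}, K={K}, N={N} violate hypergeometric bounds"
        )
    ratio = (k / n) / (K / N) if K > 0 else np.inf if k > 0 else np.nan
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return EnrichmentResult(
        set_name=set_name,
        k_hits_in_set=k,
        n_set=n,
        K_hits_total=K,
        N_total=N,
        enrichment_ratio=float(ratio),
        p_value=p,
        p_adjusted=min(1.0, p * n_tests),
    )


def splicing_enrichment(
    score_table: pd.DataFrame,
    specific_ids: Sequence[str],
    score_column: str,
    hit_rule: str,
    threshold: float = 0.5,
    n_tests: int = 1,
    set_name: str = "",
) -> EnrichmentResult:
    """Enrichment of low-PSI exons (hit_rule="lt") or high-IR introns
    (hit_rule="gt") inside a localization-specific feature set.

    ``score_table`` is indexed by feature id with the score in
    ``score_column``; comparisons against ``threshold`` are strict.
    """
    if hit_rule not in ("lt", "gt"):
        raise FormatError("hit_rule must be 'lt' or 'gt'")
    scores = score_table[score_column]
    hits = scores < threshold if hit_rule == "lt" else scores > threshold
    in_set = scores.index.isin(set(specific_ids))
    return enrichment_test(
        hits_in_set=int((hits & in_set).sum()),
        set_size=int(in_set.sum()),
        hits_total=int(hits.sum()),
        universe=int(len(scores)),
        n_tests=n_tests,
        set_name=set_name,
    )
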