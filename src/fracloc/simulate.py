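"""Synthetic matched whole-cell/nuclear/cytosolic datasets with known beta.

The generator (i) allocates a fixed pool of molecules across transcripts
with Zipf-like probabilities, (ii) splits each transcript's molecules
between nucleus and cytosol so that the realized length-weighted cytosolic
volume fraction hits a target beta, and (iii) sequences each fraction by
multinomial sampling with per-transcript probabilities proportional to
molecules x length. Every source of randomness flows from a single seed
through named `numpy.random.SeedSequence` children, so outputs are
bit-reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from fracloc.errors import DegenerateDataError, FormatError
from fracloc.io_quant import (
    FractionQuantSet,
    assemble_fraction_set,
    compute_cpm,
    compute_fpkm,
    quant_frame,
)

logger = logging.getLogger(__name__)

SPLIT_SCHEMES = ("beta-binomial", "nb-difference")

#: tolerance on |realized beta - target beta| after calibration
BETA_TOLERANCE = 0.002


@dataclass
class SimConfig:
    """Simulation settings. Desk-scale defaults; full-scale runs use
    total_molecules=5e6 and depth around 5e7."""

    n_transcripts: int = 5000
    total_molecules: int = 100_000
    zipf_exponent: float = 0.8
    length_distribution: tuple = ("lognormal", 7.0, 0.7)  # or ("fixed", L)
    target_beta: float = 0.7
    split_scheme: str = "beta-binomial"
    split_concentration: float = 10.0   # Beta concentration (heterogeneity knob)
    nb_mean: float = 20.0               # nb-difference scheme only
    nb_dispersion: float = 0.5
    depth: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.target_beta < 1.0:
            raise FormatError("target_beta must be in (0, 1)")
        if self.zipf_exponent <= 0:
            raise FormatError("zipf_exponent must be positive")
        for name in ("n_transcripts", "total_molecules", "depth"):
            if getattr(self, name) <= 0:
                raise FormatError(f"{name} must be positive")
        if self.split_scheme not in SPLIT_SCHEMES:
            raise FormatError(
                f"unknown split_scheme {self.split_scheme!r}; "
                f"choose from {SPLIT_SCHEMES}"
            )


@dataclass
class SimulatedTranscriptome:
    """Ground-truth molecule counts per transcript and fraction."""

    transcript_ids: np.ndarray
    lengths: np.ndarray                      # nt, positive integers
    m_w: np.ndarray                          # whole-cell molecules
    m_n: np.ndarray | None = None
    m_c: np.ndarray | None = None
    true_beta: float | None = None           # realized length-weighted fraction
    seed: int | None = None

    @property
    def true_li(self) -> np.ndarray:
        """Per-transcript cytosolic molecule proportion; NaN where m_w = 0."""
        if self.m_c is None:
            raise FormatError("fractions not split yet")
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.m_w > 0, self.m_c / self.m_w, np.nan)

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "transcript_id": self.transcript_ids,
                "length": self.lengths,
                "m_w": self.m_w,
                "m_n": self.m_n,
                "m_c": self.m_c,
                "true_li": self.true_li,
                "true_beta": self.true_beta,
            }
        )


@dataclass
class SimulatedReads:
    """Read counts of one fraction-wise sequencing experiment."""

    fraction: str
    depth: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        if int(self.counts.sum()) != self.depth:
            raise FormatError("read counts do not sum to depth")


def cytosolic_volume_fraction(m_c, m_w, lengths) -> float:
    """Length-weighted cytosolic share of total RNA volume:
    sum(m_c * l) / sum(m_w * l)."""
    m_c = np.asarray(m_c, float)
    m_w = np.asarray(m_w, float)
    lengths = np.asarray(lengths, float)
    total = float(np.dot(m_w, lengths))
    if total <= 0:
        raise DegenerateDataError("whole-cell transcriptome is empty")
    return float(np.dot(m_c, lengths) / total)


def _draw_lengths(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    kind = config.length_distribution[0]
    if kind == "fixed":
        return np.full(config.n_transcripts, int(config.length_distribution[1]))
    if kind == "lognormal":
        _, mu, sd = config.length_distribution
        lengths = np.rint(rng.lognormal(mu, sd, size=config.n_transcripts))
        return np.maximum(lengths, 100).astype(int)
    raise FormatError(f"unknown length distribution {kind!r}")


def simulate_whole_cell(config: SimConfig) -> SimulatedTranscriptome:
    """Allocate total_molecules across transcripts by a multinomial draw with
    Zipf-like probabilities (rank^-exponent under a random rank permutation)."""
    root = np.random.SeedSequence(config.seed)
    rng_len, rng_expr = (np.random.default_rng(s) for s in root.spawn(2))
    lengths = _draw_lengths(config, rng_len)
    ranks = rng_expr.permutation(config.n_transcripts) + 1
    probs = ranks.astype(float) ** -config.zipf_exponent
    probs /= probs.sum()
    m_w = rng_expr.multinomial(config.total_molecules, probs)
    ids = np.array([f"SIM{i:06d}" for i in range(config.n_transcripts)])
    return SimulatedTranscriptome(
        transcript_ids=ids, lengths=lengths, m_w=m_w, seed=config.seed
    )


def _realize_beta_binomial(u, v, m_w, mu, concentration):
    """Common-random-number draw of the cytosolic counts at Beta mean mu.

    Inverse-CDF sampling keeps the realized beta monotone in mu for fixed
    uniforms, which makes the calibration bisection well behaved.
    """
    a = np.clip(mu * concentration, 1e-6, None)
    b = np.clip((1.0 - mu) * concentration, 1e-6, None)
    p = stats.beta.ppf(u, a, b)
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    m_c = np.zeros_like(m_w)
    pos = m_w > 0
    m_c[pos] = stats.binom.ppf(v[pos], m_w[pos], p[pos]).astype(np.int64)
    return m_c


def _realize_nb_difference(u, v, m_w, q, nb_mean, nb_dispersion):
    """Alternative split: |m_c - m_n| gaps from a negative binomial, with the
    gap pointing toward the cytosol with probability q; clipped to [0, m_w]."""
    size = 1.0 / nb_dispersion
    p_nb = size / (size + nb_mean)
    gap = stats.nbinom.ppf(u, size, p_nb)
    sign = np.where(v < q, 1.0, -1.0)
    m_c = np.rint((m_w + sign * gap) / 2.0)
    return np.clip(m_c, 0, m_w).astype(np.int64)


def split_fractions(
    tx: SimulatedTranscriptome, config: SimConfig
) -> SimulatedTranscriptome:
    """Split whole-cell molecules into nuclear and cytosolic counts.

    Default scheme draws a per-transcript cytosolic proportion from a Beta
    distribution (mean calibrated, concentration = heterogeneity knob) and
    the cytosolic count from a Binomial; the calibration bisection moves the
    Beta mean until the realized length-weighted beta is within
    :data:`BETA_TOLERANCE` of the target. The "nb-difference" scheme instead
    draws the nucleo-cytosolic gap from a negative binomial and calibrates
    its cytosol-pointing sign bias.
    """
    if tx.m_w is None:
        raise FormatError("whole-cell molecules not simulated yet")
    root = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(root.spawn(3)[2])
    n = tx.m_w.size
    u = rng.uniform(size=n)
    v = rng.uniform(size=n)
    weights = tx.m_w.astype(float) * tx.lengths
    total = weights.sum()
    if total <= 0:
        raise DegenerateDataError("whole-cell transcriptome is empty")

    if config.split_scheme == "beta-binomial":
        realize = lambda x: _realize_beta_binomial(
            u, v, tx.m_w, x, config.split_concentration
        )
    else:
        realize = lambda x: _realize_nb_difference(
            u, v, tx.m_w, x, config.nb_mean, config.nb_dispersion
        )

    def realized_beta(m_c):
        return cytosolic_volume_fraction(m_c, tx.m_w, tx.lengths)

    lo, hi = 1e-6, 1.0 - 1e-6
    b_lo, b_hi = realized_beta(realize(lo)), realized_beta(realize(hi))
    if not b_lo - BETA_TOLERANCE <= config.target_beta <= b_hi + BETA_TOLERANCE:
        raise DegenerateDataError(
            f"target beta {config.target_beta} unreachable under "
            f"{config.split_scheme}; achievable range [{b_lo:.3f}, {b_hi:.3f}]"
        )
    x = config.target_beta  # Beta mean equals expected realized beta
    m_c = realize(x)
    for _ in range(80):
        b = realized_beta(m_c)
        if abs(b - config.target_beta) <= BETA_TOLERANCE:
            break
        if b < config.target_beta:
            lo = x
        else:
            hi = x
        x = 0.5 * (lo + hi)
        m_c = realize(x)
    else:
        raise DegenerateDataError(
            f"calibration failed: best realized beta {realized_beta(m_c):.4f} "
            f"for target {config.target_beta}"
        )

    m_n = tx.m_w - m_c
    assert (m_n >= 0).all()
    return SimulatedTranscriptome(
        transcript_ids=tx.transcript_ids,
        lengths=tx.lengths,
        m_w=tx.m_w,
        m_n=m_n,
        m_c=m_c,
        true_beta=realized_beta(m_c),
        seed=tx.seed,
    )


def simulate_reads(
    tx: SimulatedTranscriptome,
    fraction: str,
    depth: int,
    seed: int | np.random.Generator | None = None,
) -> SimulatedReads:
    """Sequence one fraction: multinomial over probabilities prop. to
    molecules x length, so expected reads follow the proportional read model."""
    m = {"whole_cell": tx.m_w, "nuclear": tx.m_n, "cytosolic": tx.m_c}[fraction]
    if m is None:
        raise FormatError(f"fraction {fraction!r} has no molecule counts")
    weights = m.astype(float) * tx.lengths
    total = weights.sum()
    if total <= 0:
        raise DegenerateDataError(f"fraction {fraction!r} contains no RNA volume")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    counts = rng.multinomial(depth, weights / total)
    return SimulatedReads(fraction=fraction, depth=depth, counts=counts)


def fpkm_from_reads(reads: SimulatedReads, lengths: np.ndarray) -> np.ndarray:
    """fpkm(i) = reads(i) * 1e9 / (length(i) * depth)."""
    lengths = np.asarray(lengths, float)
    if (lengths <= 0).any():
        raise FormatError("lengths must be positive")
    return reads.counts * 1e9 / (lengths * reads.depth)


def expected_reads(tx: SimulatedTranscriptome, fraction: str, depth: int) -> np.ndarray:
    """Noise-free expected read counts of the proportional read model."""
    m = {"whole_cell": tx.m_w, "nuclear": tx.m_n, "cytosolic": tx.m_c}[fraction]
    weights = m.astype(float) * tx.lengths
    return weights / weights.sum() * depth


def generate_dataset(
    config: SimConfig,
) -> tuple[FractionQuantSet, SimulatedTranscriptome]:
    """Full pipeline: whole-cell transcriptome -> fraction split -> sequencing
    of each fraction -> aligned quantification set with CPM and FPKM."""
    tx = split_fractions(simulate_whole_cell(config), config)
    root = np.random.SeedSequence(config.seed)
    read_seeds = root.spawn(6)[3:]
    frames = {}
    for label, sseq in zip(("whole_cell", "nuclear", "cytosolic"), read_seeds):
        reads = simulate_reads(
            tx, label, config.depth, np.random.default_rng(sseq)
        )
        qf = quant_frame(tx.transcript_ids, reads.counts, tx.lengths)
        qf = compute_fpkm(compute_cpm(qf), library_size=float(config.depth))
        frames[label] = qf
    fqs = assemble_fraction_set(
        frames["whole_cell"],
        frames["nuclear"],
        frames["cytosolic"],
        sample_id=f"sim_beta{config.target_beta:g}",
        replicate_id=str(config.seed),
    )
    return fqs, tx


def write_dataset(
    fqs: FractionQuantSet,
    tx: SimulatedTranscriptome,
    config: SimConfig,
    outdir: str | Path,
) -> None:
    """Write per-fraction quant TSVs, ground truth and a config echo."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for label, df in fqs.fractions.items():
        df.reset_index().to_csv(
            outdir / f"{label}.quant.tsv", sep="\t", index=False, float_format="%.17g"
        )
    tx.truth_frame().to_csv(
        outdir / "ground_truth.tsv", sep="\t", index=False, float_format="%.17g"
    )
    with open(outdir / "sim_config.json", "w") as fh:
        json.dump(asdict(config), fh, indent=2, default=list)
    logger.info("wrote simulated dataset to %s", outdir)
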