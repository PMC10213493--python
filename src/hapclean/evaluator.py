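"""Scoring of estimated genotypes.

Against simulated truth: correct / miscall / missing call rates and accuracy
(correct over nonmissing).  For real-like data without truth: masked-call
concordance, recombination breakpoints and segment lengths, and per-marker
segregation distortion (chi-square against the 1:2:1 F2 expectation divided
by the nonmissing call count).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_vcf import Dataset

logger = logging.getLogger(__name__)

__all__ = [
    "MetricsReport",
    "call_metrics",
    "naive_genotypes",
    "mask_and_concordance",
    "breakpoints_and_segments",
    "segregation_distortion",
    "expected_double_crossovers",
]


@dataclass
class MetricsReport:
    """Per-offspring call-rate fractions; correct + miscall + missing == 1."""

    correct: np.ndarray
    miscall: np.ndarray
    missing: np.ndarray
    accuracy: np.ndarray  # correct / (correct + miscall); NaN when all missing

    @property
    def mean_correct(self) -> float:
        return float(self.correct.mean())

    @property
    def mean_miscall(self) -> float:
        return float(self.miscall.mean())

    @property
    def mean_missing(self) -> float:
        return float(self.missing.mean())

    @property
    def mean_accuracy(self) -> float:
        return float(np.nanmean(self.accuracy))

    def summary(self) -> dict:
        return {
            "correct_call_rate": self.mean_correct,
            "miscall_rate": self.mean_miscall,
            "missing_call_rate": self.mean_missing,
            "accuracy": self.mean_accuracy,
            "sd_correct": float(self.correct.std(ddof=1)) if len(self.correct) > 1 else 0.0,
        }


def call_metrics(est: np.ndarray, truth: np.ndarray) -> MetricsReport:
    """Call-rate metrics per offspring; ``est`` uses -1 for missing calls."""
    if est.shape != truth.shape:
        raise ValueError("estimated and true genotype matrices must match in shape")
    n_markers = est.shape[0]
    missing = (est < 0).sum(axis=0) / n_markers
    correct = ((est == truth) & (est >= 0)).sum(axis=0) / n_markers
    miscall = 1.0 - correct - missing
    with np.errstate(invalid="ignore", divide="ignore"):
        accuracy = np.where(
            missing < 1.0, correct / np.maximum(correct + miscall, 1e-300), np.nan
        )
    return MetricsReport(correct=correct, miscall=miscall, missing=missing, accuracy=accuracy)


def naive_genotypes(reads: np.ndarray) -> np.ndarray:
    """Raw read-based calls: 0/2 when only one allele observed, 1 when both,
    -1 when no reads."""
    ref = reads[..., 0]
    alt = reads[..., 1]
    geno = np.full(ref.shape, -1, dtype=np.int64)
    geno[(ref > 0) & (alt == 0)] = 0
    geno[(ref > 0) & (alt > 0)] = 1
    geno[(ref == 0) & (alt > 0)] = 2
    return geno


def mask_and_concordance(
    ds: Dataset,
    est_fn,
    depth_gt: int = 6,
    miss_lt: float = 0.20,
    maf_gt: float = 0.40,
) -> dict:
    """Concordance of re-estimated genotypes at masked high-confidence calls.

    Offspring calls supported by strictly more than ``depth_gt`` reads, at
    markers whose naive-call missing rate is below ``miss_lt`` and minor
    allele frequency above ``maf_gt``, have their reads zeroed; estimation is
    re-run on the masked data and the estimated genotypes are compared with
    the pre-mask naive calls.  Estimated-missing cells count as discordant and
    are also reported separately.
    """
    naive = naive_genotypes(ds.offspring_reads)  # (M, N_o)
    miss_rate = (naive < 0).mean(axis=1)
    with np.errstate(invalid="ignore"):
        nonmiss = (naive >= 0).sum(axis=1)
        alt_freq = np.where(nonmiss > 0, naive.clip(0).sum(axis=1) / (2.0 * nonmiss), np.nan)
    maf = np.minimum(alt_freq, 1.0 - alt_freq)
    marker_ok = (miss_rate < miss_lt) & (maf > maf_gt)
    total = ds.offspring_reads.sum(axis=2)
    mask = marker_ok[:, None] & (total > depth_gt)
    if not mask.any():
        logger.warning("no genotype calls eligible for masking")
        return {"n_masked": 0, "concordance": np.nan, "masked_missing": np.nan}
    masked = ds.reads.copy()
    o_idx = np.flatnonzero(~ds.founder_mask)
    mm, nn = np.nonzero(mask)
    masked[mm, o_idx[nn]] = 0
    from dataclasses import replace

    est = est_fn(replace(ds, reads=masked))  # (M, N_o) with -1 missing
    concord = float((est[mask] == naive[mask]).mean())
    est_missing = float((est[mask] < 0).mean())
    return {"n_masked": int(mask.sum()), "concordance": concord, "masked_missing": est_missing}


@dataclass
class SegmentReport:
    breakpoints: list  # per offspring, array of bp midpoints
    segments: list  # per offspring, list of (start_bp, end_bp, genotype)
    bin_counts: dict = field(default_factory=dict)  # {"0-1Mb": n, "1-2Mb": n}
    double_crossovers: dict = field(default_factory=dict)


def breakpoints_and_segments(est: np.ndarray, pos: np.ndarray) -> SegmentReport:
    """Recombination breakpoints and segment-length tabulation per offspring.

    A genotype switch between adjacent nonmissing markers places a breakpoint
    at their bp midpoint.  Double crossovers are heterozygous segments flanked
    on both sides by the same homozygous genotype.
    """
    mb = 1_000_000
    all_bp, all_segments = [], []
    bins = {"0-1Mb": 0, "1-2Mb": 0}
    dxo = {"0-1Mb": 0, "1-2Mb": 0}
    for i in range(est.shape[1]):
        obs = np.flatnonzero(est[:, i] >= 0)
        if obs.size == 0:
            all_bp.append(np.zeros(0))
            all_segments.append([])
            continue
        g = est[obs, i]
        p = pos[obs]
        switch = np.flatnonzero(np.diff(g) != 0)
        bp = (p[switch] + p[switch + 1]) / 2.0
        all_bp.append(bp)
        bounds = np.concatenate([[p[0]], bp, [p[-1]]])
        seg_geno = np.concatenate([g[switch], [g[-1]]]) if switch.size else [g[-1]]
        segments = [
            (bounds[k], bounds[k + 1], int(seg_geno[k])) for k in range(len(bounds) - 1)
        ]
        all_segments.append(segments)
        for k, (a, b, sg) in enumerate(segments):
            length = b - a
            key = "0-1Mb" if length <= mb else ("1-2Mb" if length <= 2 * mb else None)
            if key is None:
                continue
            bins[key] += 1
            if (
                sg == 1
                and 0 < k < len(segments) - 1
                and segments[k - 1][2] == segments[k + 1][2]
                and segments[k - 1][2] in (0, 2)
            ):
                dxo[key] += 1
    return SegmentReport(
        breakpoints=all_bp, segments=all_segments, bin_counts=bins, double_crossovers=dxo
    )


def segregation_distortion(est: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-marker distortion chi2/n against a 1:2:1 ratio; chromosome sum.

    Markers with no nonmissing calls contribute 0.
    """
    counts = np.stack([(est == g).sum(axis=1) for g in range(3)], axis=1).astype(float)
    n = counts.sum(axis=1)
    expected = np.stack([n / 4, n / 2, n / 4], axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = ((counts - expected) ** 2 / expected).sum(axis=1)
        level = chi2 / n
    level = np.where(n > 0, level, 0.0)
    n_empty = int((n == 0).sum())
    if n_empty:
        logger.debug("%d markers with no nonmissing calls contribute 0 distortion", n_empty)
    return level, float(level.sum())


def expected_double_crossovers(
    map_cm_per_mb: float = 4.0, window_mb: float = 1.0, gametes: int = 1
) -> tuple[float, float]:
    """Poisson probability and expectation of >= 2 crossovers in a window.

    With genetic window length ``d`` Morgans, ``P = 1 - e^{-d}(1 + d)``.
    """
    if map_cm_per_mb < 0 or window_mb < 0 or gametes < 0:
        raise ValueError("inputs must be nonnegative")
    d = map_cm_per_mb * window_mb / 100.0
    p = 1.0 - np.exp(-d) * (1.0 + d)
    return float(p), float(gametes * p)
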