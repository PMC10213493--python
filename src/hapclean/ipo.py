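"""Iterative parameter optimization (IPO) for allele read bias and mismapping.

After each genotype-estimation cycle, the estimated genotypes of founders and
offspring classify every read as coming from a ref or alt allele copy, which
gives method-of-moments estimates of the per-marker allele read bias ``w_m``
and the mismapping rates ``(e_ref, e_alt)``.  Re-running estimation with the
updated parameters lets the HMM stop mistaking systematically biased markers
for heterozygous or recombinant signal.

``E^ref`` is the expected number of reference reads generated per reference
allele copy: a homozygote contributes two copies, a het one copy of each
allele.  The bias is the alt share of per-copy read generation,
``w = E^alt / (E^ref + E^alt)``, matching the emission model in which a read
at a het is alternative with probability ``w``.
"""

from __future__ import annotations

import logging

import numpy as np

from .emission import ModelParams, read_likelihood_matrix
from .estimator import EstimationResult, correct_dataset
from .scheme import MatingDesign

logger = logging.getLogger(__name__)

__all__ = [
    "estimate_bias",
    "estimate_mismap",
    "informative_copies",
    "run_ipo",
]

#: post-estimation clamp keeping het emissions nondegenerate (w=0 or 1 would
#: make one allele unobservable at hets forever)
W_CLAMP = (0.02, 0.98)
#: het-probability threshold flagging a mismapping-induced genotype conflict
MISMAP_HET_PROB = 0.99


def _copy_sums(reads: np.ndarray, genotypes: np.ndarray):
    """Read sums r^x(g) and allele-copy counts n(g) per marker per genotype."""
    n_markers = reads.shape[0]
    r_ref = np.zeros((n_markers, 3))
    r_alt = np.zeros((n_markers, 3))
    n_copies = np.zeros((n_markers, 3))
    for g in range(3):
        sel = genotypes == g
        r_ref[:, g] = np.where(sel, reads[..., 0], 0).sum(axis=1)
        r_alt[:, g] = np.where(sel, reads[..., 1], 0).sum(axis=1)
        n_copies[:, g] = (2 if g != 1 else 1) * sel.sum(axis=1)
    return r_ref, r_alt, n_copies


def estimate_bias(
    reads: np.ndarray, genotypes: np.ndarray, prev_w: np.ndarray
) -> np.ndarray:
    """Per-marker allele read bias from estimated genotypes.

    Parameters
    ----------
    reads
        ``(M, N, 2)`` read counts for all samples, founders included.
    genotypes
        ``(M, N)`` estimated genotypes in {0, 1, 2}, ``-1`` for missing;
        missing calls contribute to neither numerator nor denominator.
    prev_w
        Previous cycle's bias, carried forward where the estimate is
        undefined (no informative copies on one side).

    Returns the updated ``w`` clamped to [0.02, 0.98].
    """
    r_ref, r_alt, n = _copy_sums(reads, genotypes)
    ref_copies = n[:, 0] + n[:, 1]
    alt_copies = n[:, 2] + n[:, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        e_ref = (r_ref[:, 0] + r_ref[:, 1]) / ref_copies
        e_alt = (r_alt[:, 2] + r_alt[:, 1]) / alt_copies
        w = e_alt / (e_ref + e_alt)
    defined = (ref_copies > 0) & (alt_copies > 0) & ((e_ref + e_alt) > 0)
    n_undefined = int((~defined).sum())
    if n_undefined:
        logger.debug("bias undefined at %d markers; carrying previous values", n_undefined)
    w = np.where(defined, w, prev_w)
    return np.clip(w, *W_CLAMP)


def informative_copies(genotypes: np.ndarray) -> np.ndarray:
    """Allele copies informing the bias estimate at each marker.

    Sum of the ref-side and alt-side copy denominators,
    ``(n(0)+n(1)) + (n(2)+n(1))``, over nonmissing genotype calls.
    """
    counts = np.stack([(genotypes == g).sum(axis=1) for g in range(3)], axis=1)
    return (2 * counts[:, 0] + counts[:, 1]) + (2 * counts[:, 2] + counts[:, 1])


def estimate_mismap(
    reads: np.ndarray,
    genotypes: np.ndarray,
    params: ModelParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-marker mismapping rates from het-read/homozygous-call conflicts.

    A sample whose reads alone say "heterozygous" with normalized probability
    above 0.99 while the HMM called it homozygous is counted as a mismapping
    casualty; the rate is the count over all samples with that homozygous
    call.  Markers with no homozygous calls keep their previous rates.
    """
    p_obs = read_likelihood_matrix(reads, params.e_seq, params.w)
    het_conf = p_obs[..., 1] > MISMAP_HET_PROB
    out = []
    for g, prev in ((0, params.e_ref), (2, params.e_alt)):
        sel = genotypes == g
        denom = sel.sum(axis=1)
        num = (het_conf & sel).sum(axis=1)
        with np.errstate(invalid="ignore"):
            rate = num / denom
        out.append(np.where(denom > 0, rate, prev))
    return out[0], out[1]


def _full_genotype_matrix(ds, result: EstimationResult) -> np.ndarray:
    """Estimated genotypes for every sample (founders + offspring), -1 missing."""
    geno = np.full((ds.n_markers, len(ds.samples)), -1, dtype=np.int64)
    geno[:, np.flatnonzero(ds.founder_mask)] = result.founder_genotypes.sum(axis=2)
    geno[:, np.flatnonzero(~ds.founder_mask)] = result.genotypes
    return geno


def run_ipo(
    ds,
    design: MatingDesign,
    params: ModelParams,
    cycles: int = 4,
    rng: np.random.Generator | None = None,
    fix_bias: bool = False,
    fix_mismap: bool = False,
) -> tuple[EstimationResult, ModelParams]:
    """Alternate genotype estimation and parameter re-estimation.

    ``cycles=1`` runs a single estimation with the initial parameters
    (w=0.5, e_mmap=(0.005, 0.005) unless overridden), i.e. no IPO.
    """
    if cycles < 1:
        raise ValueError("cycles must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    params = params.copy()
    result = None
    for cycle in range(cycles):
        result = correct_dataset(ds, design, params, rng)
        if cycle == cycles - 1:
            break
        geno = _full_genotype_matrix(ds, result)
        e_ref, e_alt = estimate_mismap(ds.reads, geno, params)
        if not fix_bias:
            params.w = estimate_bias(ds.reads, geno, params.w)
        if not fix_mismap:
            params.e_ref, params.e_alt = e_ref, e_alt
    assert result is not None
    return result, params
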