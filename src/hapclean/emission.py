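"""Observation likelihoods from allele read counts.

Reads at a marker are modelled per observable genotype ``x' in {0, 1, 2}``
(ref-homozygote, het, alt-homozygote):

* ``P(y | x'=0) ∝ (1-e_seq)^y_ref * e_seq^y_alt``
* ``P(y | x'=1) ∝ (1-w_m)^y_ref * w_m^y_alt``
* ``P(y | x'=2) ∝ e_seq^y_ref * (1-e_seq)^y_alt``

``e_seq`` is the global sequencing-error rate; ``w_m`` is the marker-specific
allele read bias — the probability that a read drawn at a heterozygous site
carries the alternative allele (0.5 when amplification is even).  Mismapping
converts the true genotype ``x`` into the observable genotype ``x'`` with the
marker-specific rates ``e_ref`` (ref-homozygote observed het) and ``e_alt``
(alt-homozygote observed het).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import xlogy

__all__ = [
    "ModelParams",
    "mismap_matrix",
    "read_likelihood",
    "read_likelihood_matrix",
    "genotype_likelihoods",
    "offspring_emission",
    "founder_emission",
    "founder_emission_matrix",
]

#: additive floor applied when any of the three genotype likelihoods is exactly 0
ZERO_FLOOR = 0.005
#: per-founder genotype probabilities below this are pruned to exactly 0
FOUNDER_PRUNE = 0.01


@dataclass
class ModelParams:
    """Global and per-marker model parameters.

    ``w`` is initialized to 0.5 (no bias) and ``e_ref``/``e_alt`` to 0.005 at
    every marker; iterative parameter optimization re-estimates them.
    """

    n_markers: int
    e_seq: float = 0.0025
    ed: float = 0.04  # Morgans per Mb; 1 Mb == 4 cM
    p_call: float = 0.9
    w: np.ndarray = field(default=None)  # type: ignore[assignment]
    e_ref: np.ndarray = field(default=None)  # type: ignore[assignment]
    e_alt: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not 0 < self.e_seq < 0.5:
            raise ValueError("e_seq must lie in (0, 0.5)")
        if not 0 < self.p_call <= 1:
            raise ValueError("P_call must lie in (0, 1]")
        if self.w is None:
            self.w = np.full(self.n_markers, 0.5)
        if self.e_ref is None:
            self.e_ref = np.full(self.n_markers, 0.005)
        if self.e_alt is None:
            self.e_alt = np.full(self.n_markers, 0.005)
        for name in ("w", "e_ref", "e_alt"):
            v = np.asarray(getattr(self, name), dtype=np.float64)
            if v.shape != (self.n_markers,):
                raise ValueError(f"{name} must have length n_markers")
            setattr(self, name, v)

    def copy(self) -> "ModelParams":
        return replace(
            self, w=self.w.copy(), e_ref=self.e_ref.copy(), e_alt=self.e_alt.copy()
        )


def mismap_matrix(e_ref: float, e_alt: float) -> np.ndarray:
    """3x3 matrix ``P(x' | x)``: rows true genotype, columns observable genotype.

    A het never changes class (extra mismapped reads of either allele leave it
    het); a homozygote is observed het when opposite-allele reads mismap in.
    """
    return np.array(
        [
            [1.0 - e_ref, e_ref, 0.0],
            [0.0, 1.0, 0.0],
            [0.0, e_alt, 1.0 - e_alt],
        ]
    )


def read_likelihood_matrix(
    reads: np.ndarray, e_seq: float, w: np.ndarray
) -> np.ndarray:
    """Normalized ``P(y | x')`` for every (marker, sample) cell.

    Parameters
    ----------
    reads
        ``(M, N, 2)`` nonnegative integer ref/alt read counts.
    e_seq
        Global sequencing-error rate.
    w
        ``(M,)`` per-marker allele read bias.

    Returns
    -------
    ``(M, N, 3)`` array summing to 1 over the last axis.  If any of the three
    unnormalized likelihoods is exactly zero (including numerical underflow),
    0.005 is added to all three before normalizing, so no class is ever
    impossible once reads are present.
    """
    y_ref = np.asarray(reads[..., 0], dtype=np.float64)
    y_alt = np.asarray(reads[..., 1], dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)[:, None]
    # xlogy gives y*log(p) with the 0*log(0) = 0 convention (no reads of an
    # allele contribute no factor, even when its probability is 0)
    log_p = np.stack(
        [
            xlogy(y_ref, 1.0 - e_seq) + xlogy(y_alt, e_seq),
            xlogy(y_ref, 1.0 - w) + xlogy(y_alt, w),
            xlogy(y_ref, e_seq) + xlogy(y_alt, 1.0 - e_seq),
        ],
        axis=-1,
    )
    p = np.exp(log_p)  # raw scale: values <= 1, may underflow to 0
    zero_any = (p == 0).any(axis=-1, keepdims=True)
    p = np.where(zero_any, p + ZERO_FLOOR, p)
    return p / p.sum(axis=-1, keepdims=True)


def read_likelihood(
    y: tuple[int, int], e_seq: float, w: float
) -> np.ndarray:
    """Normalized genotype-likelihood triple for a single cell."""
    reads = np.asarray(y, dtype=np.int64).reshape(1, 1, 2)
    return read_likelihood_matrix(reads, e_seq, np.array([w]))[0, 0]


def genotype_likelihoods(reads: np.ndarray, params: ModelParams) -> np.ndarray:
    """``P(y | x)`` per cell: read likelihoods mixed over mismapping.

    ``P(y|x) = sum_{x'} P(y|x') P(x'|x)`` with the per-marker mismap matrix.
    Shape ``(M, N, 3)`` indexed by true genotype; rows need not sum to 1 over
    genotypes (they are likelihoods, not posteriors).
    """
    p_obs = read_likelihood_matrix(reads, params.e_seq, params.w)
    mm = np.stack(
        [mismap_matrix(er, ea) for er, ea in zip(params.e_ref, params.e_alt)]
    )  # (M, 3, 3)
    return np.einsum("mnj,mxj->mnx", p_obs, mm)


def offspring_emission(
    y: tuple[int, int],
    h: tuple[int, int],
    founder_combo: np.ndarray,
    params: ModelParams,
    m: int,
    inbred: bool = True,
) -> float:
    """Emission likelihood for one offspring cell given its hidden state.

    The pair ``(h, founder_combo)`` determines the offspring genotype exactly
    (each inherited ancestral chromosome carries one allele), so the sum over
    true genotypes collapses to a single term of the mismap mixture.
    """
    combo = np.asarray(founder_combo)
    anc = combo[:, 0] if inbred else combo.reshape(-1)
    genotype = int(anc[h[0]] + anc[h[1]])
    p_obs = read_likelihood(y, params.e_seq, float(params.w[m]))
    mm = mismap_matrix(float(params.e_ref[m]), float(params.e_alt[m]))
    return float(p_obs @ mm[genotype])


def _founder_factors(
    founder_reads: np.ndarray, params: ModelParams
) -> np.ndarray:
    """Per-founder genotype probabilities, pruned: ``(M, N_f, 3)``.

    Each founder's likelihood triple (same mismap mixture as offspring) is
    normalized over the three genotype classes; entries below 0.01 are set to
    exactly 0 to drop improbable founder genotypes.
    """
    lik = genotype_likelihoods(founder_reads, params)
    norm = lik / lik.sum(axis=-1, keepdims=True)
    return np.where(norm < FOUNDER_PRUNE, 0.0, norm)


def founder_emission_matrix(
    founder_reads: np.ndarray, founder_classes: np.ndarray, params: ModelParams
) -> np.ndarray:
    """Normalized founder-combination likelihood ``l^f``: shape ``(M, C)``.

    ``l^f(combo) ∝ prod_j P(y_j | genotype class of founder j under combo)``.
    Markers where every admissible combination scores 0 (all founder factors
    pruned) fall back to the uniform distribution: the founders carry no
    usable information there.
    """
    factors = _founder_factors(founder_reads, params)  # (M, N_f, 3)
    m, n_f, _ = factors.shape
    per = factors[:, np.arange(n_f)[None, :], founder_classes]
    # per: (M, C, N_f) after fancy indexing; use log to avoid underflow
    with np.errstate(divide="ignore"):
        log_lf = np.log(per).sum(axis=2)
    dead = np.isneginf(log_lf).all(axis=1)
    lf = np.zeros_like(log_lf)
    alive = ~dead
    if alive.any():
        shifted = log_lf[alive] - log_lf[alive].max(axis=1, keepdims=True)
        lf[alive] = np.exp(shifted)
        lf[alive] /= lf[alive].sum(axis=1, keepdims=True)
    if dead.any():
        lf[dead] = 1.0 / log_lf.shape[1]
    return lf


def founder_emission(
    founder_reads_at_m: np.ndarray,
    founder_classes: np.ndarray,
    params: ModelParams,
    m: int,
) -> np.ndarray:
    """Founder-combination likelihood at one marker: shape ``(C,)``."""
    single = ModelParams(
        1,
        e_seq=params.e_seq,
        ed=params.ed,
        p_call=params.p_call,
        w=params.w[m : m + 1],
        e_ref=params.e_ref[m : m + 1],
        e_alt=params.e_alt[m : m + 1],
    )
    reads = np.asarray(founder_reads_at_m, dtype=np.int64)[None, :, :]
    return founder_emission_matrix(reads, founder_classes, single)[0]
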