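"""Joint founder/offspring decoding and genotype calling.

The integrated Viterbi algorithm maximizes the joint probability of offspring
haplotype sequences, founder genotype sequences and the observed reads.  The
founder genotype combination at each marker is not itself Markovian; it is
chosen by scoring, for every candidate combination at marker ``m``, the best
combination at ``m-1`` using the offspring trellises summed over haplotype
states.  Two rounds are run (forward along the chromosome, then reverse with
the forward round's final founder combination imposed) and merged at the
midpoint, which repairs early-chromosome founder decisions made before enough
evidence had accumulated.

Genotype posteriors are then computed per offspring by the forward-backward
algorithm conditional on the estimated founder genotype sequence, and calls
whose posterior falls below ``P_call`` are reported missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .emission import ModelParams, founder_emission_matrix, genotype_likelihoods
from .scheme import MatingDesign, StateSpace, TransitionModel, build_transition_model

logger = logging.getLogger(__name__)

__all__ = [
    "EstimationResult",
    "viterbi_pass",
    "two_round_estimate",
    "merge_rounds",
    "marginal_probabilities",
    "call_genotypes",
    "estimate_chromosome",
    "correct_dataset",
]


@dataclass
class EstimationResult:
    """Decoded founder genotypes, offspring haplotypes and genotype calls."""

    combo_path: np.ndarray  # (M,) index into StateSpace.founder_combos
    founder_genotypes: np.ndarray  # (M, N_f, 2) phased alleles
    haplotypes: np.ndarray  # (M, N_o, 2) ancestral-chromosome ids
    viterbi_genotypes: np.ndarray  # (M, N_o) in {0,1,2}, pre-threshold
    genotypes: np.ndarray  # (M, N_o) in {0,1,2} or -1 (missing)
    marginal: np.ndarray  # (M, N_o) posterior of the called genotype
    posteriors: np.ndarray  # (M, N_o, 3) genotype posteriors


def _tie_argmax(values: np.ndarray, axis: int, rng: np.random.Generator) -> np.ndarray:
    """argmax with uniform random tie-breaking (ties are exact score equalities)."""
    vmax = values.max(axis=axis, keepdims=True)
    ties = values == vmax
    keys = np.where(ties, rng.random(values.shape), -1.0)
    return keys.argmax(axis=axis)


def viterbi_pass(
    log_pyx: np.ndarray,
    gmap: np.ndarray,
    log_lf: np.ndarray,
    log_trans: list[np.ndarray],
    log_pi: np.ndarray,
    rng: np.random.Generator,
    fixed_first_combo: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One directional pass of the integrated Viterbi algorithm.

    Parameters
    ----------
    log_pyx
        ``(M, N, 3)`` log-likelihood of each offspring cell's reads per true
        genotype, already in the marker order of this pass.
    gmap
        ``(C, S)`` genotype implied by (founder combination, haplotype pair).
    log_lf
        ``(M, C)`` log founder-combination likelihoods (``-inf`` for pruned
        combinations).
    log_trans
        ``M-1`` log transition matrices for the pass's marker order.
    log_pi
        ``(S,)`` log initial distribution.
    fixed_first_combo
        If given, the pass's first marker is constrained to this founder
        combination (used by the reverse round).

    Returns
    -------
    ``(combo_path, haplotype_states)``: founder-combination index per marker
    and haplotype-pair state index per marker per offspring.
    """
    n_markers, n_off, _ = log_pyx.shape
    n_combos, n_states = gmap.shape
    log_prior = -np.log(n_combos)  # uniform P(x^f); constant but kept explicit

    active: list[np.ndarray] = []
    for m in range(n_markers):
        idx = np.flatnonzero(np.isfinite(log_lf[m]))
        if idx.size == 0:  # founder_emission guards against this; belt and braces
            idx = np.arange(n_combos)
        active.append(idx)
    if fixed_first_combo is not None:
        active[0] = np.array([fixed_first_combo])

    # initialization: v_1(h | x^f) = l_1 * pi
    cur = active[0]
    v = log_pyx[0][:, gmap[cur]].transpose(1, 2, 0) + log_pi[None, :, None]

    psi_f: list[np.ndarray] = [np.zeros(0, dtype=np.int64)]
    psi_o: list[np.ndarray] = [np.zeros((len(cur), n_states, n_off), dtype=np.int16)]

    for m in range(1, n_markers):
        prev, cur = active[m - 1], active[m]
        log_t = log_trans[m - 1]
        # tau: best predecessor haplotype state per (prev combo, state, offspring)
        tmp = log_t[None, :, :, None] + v[:, :, None, :]
        tau_max = tmp.max(axis=1)  # (P, S, N)
        tau_arg = _tie_argmax(tmp, 1, rng).astype(np.int16)
        log_lo = log_pyx[m][:, gmap[cur]].transpose(1, 2, 0)  # (Cc, S, N)

        n_cur, n_prev = len(cur), len(prev)
        if n_cur * n_prev * n_states * n_off <= 5e7:
            big = log_lo[:, None] + tau_max[None]  # (Cc, P, S, N)
            vf = logsumexp(big, axis=2).sum(axis=2)  # (Cc, P)
        else:  # chunk over current combos to bound memory on large state spaces
            vf = np.empty((n_cur, n_prev))
            for c in range(n_cur):
                vf[c] = logsumexp(log_lo[c][None] + tau_max, axis=1).sum(axis=1)
        vf += log_prior + log_lf[m - 1, prev][None, :]
        best_prev = _tie_argmax(vf, 1, rng)  # (Cc,) indices into prev
        v = log_lo + tau_max[best_prev]  # (Cc, S, N)
        v -= v.max(axis=(0, 1), keepdims=True)  # renormalize per offspring
        psi_f.append(best_prev)
        psi_o.append(tau_arg[best_prev])

    # termination at the last marker
    cur = active[-1]
    scores = (
        log_prior
        + log_lf[n_markers - 1, cur]
        + logsumexp(v, axis=1).sum(axis=1)
    )
    c_idx = int(_tie_argmax(scores[None, :], 1, rng)[0])
    h_states = np.empty((n_markers, n_off), dtype=np.int64)
    h_states[-1] = _tie_argmax(v[c_idx], 0, rng)
    combo_path = np.empty(n_markers, dtype=np.int64)
    combo_path[-1] = cur[c_idx]

    for m in range(n_markers - 1, 0, -1):
        h_states[m - 1] = psi_o[m][c_idx, h_states[m], np.arange(n_off)]
        c_idx = int(psi_f[m][c_idx])
        combo_path[m - 1] = active[m - 1][c_idx]
    return combo_path, h_states


def two_round_estimate(
    log_pyx: np.ndarray,
    gmap: np.ndarray,
    log_lf: np.ndarray,
    model: TransitionModel,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Forward and reverse integrated-Viterbi rounds, merged at the midpoint.

    The reverse round runs over reversed marker order (and hence reversed
    inter-marker distances) with the forward round's last-marker founder
    combination imposed.  Markers with 1-based index ``m <= floor(M/2)`` are
    taken from the reverse round, the rest from the forward round.
    """
    n_markers = log_pyx.shape[0]
    with np.errstate(divide="ignore"):
        log_trans = [np.log(t) for t in model.matrices]
        log_pi = np.log(model.initial)
    combo_f, haps_f = viterbi_pass(log_pyx, gmap, log_lf, log_trans, log_pi, rng)
    if n_markers == 1:
        return combo_f, haps_f
    combo_r, haps_r = viterbi_pass(
        log_pyx[::-1],
        gmap,
        log_lf[::-1],
        log_trans[::-1],
        log_pi,
        rng,
        fixed_first_combo=int(combo_f[-1]),
    )
    combo_r, haps_r = combo_r[::-1], haps_r[::-1]
    return merge_rounds(combo_r, combo_f), merge_rounds(haps_r, haps_f)


def merge_rounds(reverse: np.ndarray, forward: np.ndarray) -> np.ndarray:
    """Take 1-based markers ``m <= floor(M/2)`` from the reverse round.

    The reverse round is more reliable early in the chromosome (its founder
    decisions there have seen the whole chromosome's evidence), the forward
    round late.
    """
    half = len(forward) // 2
    return np.concatenate([reverse[:half], forward[half:]])


def marginal_probabilities(
    pyx: np.ndarray,
    gmap: np.ndarray,
    combo_path: np.ndarray,
    model: TransitionModel,
) -> np.ndarray:
    """Genotype posteriors per cell by forward-backward, founders fixed.

    Returns ``(M, N, 3)`` with each cell summing to 1.
    """
    n_markers, n_off, _ = pyx.shape
    n_states = gmap.shape[1]
    emis = np.empty((n_markers, n_states, n_off))
    for m in range(n_markers):
        emis[m] = pyx[m][:, gmap[combo_path[m]]].T
    alpha = np.empty_like(emis)
    scale = np.empty((n_markers, n_off))
    a = model.initial[:, None] * emis[0]
    scale[0] = a.sum(axis=0)
    alpha[0] = a / scale[0]
    for m in range(1, n_markers):
        a = (model.matrices[m - 1].T @ alpha[m - 1]) * emis[m]
        scale[m] = a.sum(axis=0)
        alpha[m] = a / scale[m]
    beta = np.ones_like(emis)
    for m in range(n_markers - 2, -1, -1):
        beta[m] = model.matrices[m] @ (emis[m + 1] * beta[m + 1]) / scale[m + 1]
    post_h = alpha * beta
    post_h /= post_h.sum(axis=1, keepdims=True)

    post_x = np.zeros((n_markers, n_off, 3))
    for m in range(n_markers):
        g = gmap[combo_path[m]]  # (S,)
        for x in range(3):
            sel = g == x
            if sel.any():
                post_x[m, :, x] = post_h[m, sel].sum(axis=0)
    return post_x


def call_genotypes(
    viterbi_genotypes: np.ndarray, posteriors: np.ndarray, p_call: float
) -> tuple[np.ndarray, np.ndarray]:
    """Mask Viterbi-implied genotypes whose posterior is below ``P_call``."""
    m_idx, n_idx = np.indices(viterbi_genotypes.shape)
    marginal = posteriors[m_idx, n_idx, viterbi_genotypes]
    called = np.where(marginal < p_call, -1, viterbi_genotypes)
    return called, marginal


def estimate_chromosome(
    offspring_reads: np.ndarray,
    founder_reads: np.ndarray,
    pos: np.ndarray,
    space: StateSpace,
    params: ModelParams,
    rng: np.random.Generator,
) -> EstimationResult:
    """Full estimation for one chromosome: decode, posteriors, calls."""
    model = build_transition_model(space.design, pos, params.ed)
    pyx = genotype_likelihoods(offspring_reads, params)
    lf = founder_emission_matrix(founder_reads, space.founder_classes, params)
    with np.errstate(divide="ignore"):
        log_pyx = np.log(pyx)
        log_lf = np.log(lf)
    combo_path, h_states = two_round_estimate(log_pyx, space.genotype_map, log_lf, model, rng)
    posteriors = marginal_probabilities(pyx, space.genotype_map, combo_path, model)
    viterbi_geno = space.genotype_map[combo_path[:, None], h_states]
    called, marginal = call_genotypes(viterbi_geno, posteriors, params.p_call)
    return EstimationResult(
        combo_path=combo_path,
        founder_genotypes=space.founder_combos[combo_path],
        haplotypes=space.haplotype_pairs[h_states],
        viterbi_genotypes=viterbi_geno,
        genotypes=called,
        marginal=marginal,
        posteriors=posteriors,
    )


def correct_dataset(
    ds,
    design: MatingDesign,
    params: ModelParams,
    rng: np.random.Generator,
) -> EstimationResult:
    """Run estimation chromosome by chromosome and concatenate the results."""
    space = StateSpace(design)
    parts = []
    for c in ds.chromosomes:
        sel = ds.chrom == c
        parts.append(
            estimate_chromosome(
                ds.offspring_reads[sel],
                ds.founder_reads[sel],
                ds.pos[sel],
                space,
                _slice_params(params, sel),
                rng,
            )
        )
    return EstimationResult(
        combo_path=np.concatenate([p.combo_path for p in parts]),
        founder_genotypes=np.concatenate([p.founder_genotypes for p in parts]),
        haplotypes=np.concatenate([p.haplotypes for p in parts]),
        viterbi_genotypes=np.concatenate([p.viterbi_genotypes for p in parts]),
        genotypes=np.concatenate([p.genotypes for p in parts]),
        marginal=np.concatenate([p.marginal for p in parts]),
        posteriors=np.concatenate([p.posteriors for p in parts]),
    )


def _slice_params(params: ModelParams, sel: np.ndarray) -> ModelParams:
    return ModelParams(
        int(sel.sum()),
        e_seq=params.e_seq,
        ed=params.ed,
        p_call=params.p_call,
        w=params.w[sel],
        e_ref=params.e_ref[sel],
        e_alt=params.e_alt[sel],
    )
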