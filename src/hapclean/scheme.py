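"""Mating designs, hidden-state enumeration, and the recombination transition model.

The hidden state of the offspring HMM at a marker is an ordered pair of
ancestral-haplotype origins ``(h1, h2)``.  Each coordinate names one of the
``K`` ancestral chromosomes carried by the founders: ``K = N_f`` when every
founder is inbred (one distinct chromosome each) and ``K = 2*N_f`` when the
founders are outbred.  Along the chromosome each lineage switches ancestor at
crossover events, modelled as a continuous-time Markov chain on the ``K**2``
ordered pairs with genetic distance as time.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

__all__ = [
    "MatingDesign",
    "StateSpace",
    "TransitionModel",
    "genetic_distances",
    "build_rate_matrix",
    "transition_matrix",
    "initial_distribution",
    "build_transition_model",
]

#: scenario label -> (n_founders, inbred, default ancestor-switch rate per Morgan)
SCENARIOS = {
    "homoP2_F2": (2, True, 1.0),
    "hetP2_F1": (2, False, 1.0),
    "homoP8_RIL": (8, True, 1.5),
}


@dataclass(frozen=True)
class MatingDesign:
    """Crossing design: founder count, inbredness and the map-expansion knob.

    Parameters
    ----------
    scenario
        One of ``homoP2_F2``, ``hetP2_F1``, ``homoP8_RIL`` or ``custom``.
    n_founders
        Number of founder individuals (``N_f >= 2``).
    inbred
        Whether all founders are fully inbred (homozygous everywhere).
    rho
        Per-Morgan rate at which a single offspring lineage leaves its
        current ancestor.  ``rho=1`` matches one expected switch per Morgan;
        multi-generation designs (RILs) accumulate meioses, which is exposed
        as a larger ``rho`` (map expansion).
    """

    scenario: str
    n_founders: int
    inbred: bool
    rho: float = 1.0

    def __post_init__(self) -> None:
        if self.n_founders < 2:
            raise ValueError("a mating design needs at least 2 founders")
        if self.rho <= 0:
            raise ValueError("ancestor-switch rate rho must be positive")

    @property
    def n_ancestors(self) -> int:
        """K: distinct ancestral chromosomes (N_f inbred, 2*N_f outbred)."""
        return self.n_founders if self.inbred else 2 * self.n_founders

    @classmethod
    def from_scenario(cls, scenario: str, rho: float | None = None) -> "MatingDesign":
        if scenario not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {scenario!r}; expected one of {sorted(SCENARIOS)}"
            )
        n_f, inbred, default_rho = SCENARIOS[scenario]
        return cls(scenario, n_f, inbred, default_rho if rho is None else rho)


# phased founder genotypes admitted per founder
_INBRED_GENOTYPES = ((0, 0), (1, 1))
_OUTBRED_GENOTYPES = ((0, 0), (0, 1), (1, 0), (1, 1))


@dataclass
class StateSpace:
    """Enumerated hidden states: haplotype pairs and founder-genotype combinations.

    ``haplotype_pairs`` lists all ordered ancestor pairs ``(h1, h2)`` (K**2 of
    them, 0-based).  ``founder_combos`` lists every assignment of phased
    genotypes to the founders, excluding assignments in which all founders
    carry an identical genotype (those make the marker monomorphic-in-design
    and carry no linkage information).
    """

    design: MatingDesign
    haplotype_pairs: np.ndarray = field(init=False)  # (S, 2) int
    founder_combos: np.ndarray = field(init=False)  # (C, N_f, 2) int
    founder_classes: np.ndarray = field(init=False)  # (C, N_f) in {0,1,2}
    genotype_map: np.ndarray = field(init=False)  # (C, S) in {0,1,2}

    def __post_init__(self) -> None:
        k = self.design.n_ancestors
        self.haplotype_pairs = np.array(
            list(itertools.product(range(k), repeat=2)), dtype=np.int64
        )
        per_founder = _INBRED_GENOTYPES if self.design.inbred else _OUTBRED_GENOTYPES
        combos = [
            c
            for c in itertools.product(per_founder, repeat=self.design.n_founders)
            if len(set(c)) > 1
        ]
        self.founder_combos = np.array(combos, dtype=np.int64)
        self.founder_classes = self.founder_combos.sum(axis=2)
        # allele carried by each ancestral chromosome under each combination
        if self.design.inbred:
            anc_alleles = self.founder_combos[:, :, 0]  # (C, K)
        else:
            anc_alleles = self.founder_combos.reshape(len(combos), -1)  # (C, 2*N_f)
        h1 = self.haplotype_pairs[:, 0]
        h2 = self.haplotype_pairs[:, 1]
        self.genotype_map = anc_alleles[:, h1] + anc_alleles[:, h2]

    @property
    def n_states(self) -> int:
        return len(self.haplotype_pairs)

    @property
    def n_combos(self) -> int:
        return len(self.founder_combos)


def genetic_distances(pos: np.ndarray, ed: float) -> np.ndarray:
    """Inter-marker genetic distances in Morgans.

    ``d_m = 1e-6 * (p_m - p_{m-1}) * Ed`` for physical positions ``p`` in bp
    and expected genetic distance ``Ed`` in Morgans per megabase.
    """
    pos = np.asarray(pos, dtype=np.float64)
    if ed <= 0:
        raise ValueError("expected genetic distance Ed must be positive")
    diffs = np.diff(pos)
    if np.any(diffs <= 0):
        raise ValueError("marker positions must be strictly increasing")
    return 1e-6 * diffs * ed


def build_rate_matrix(design: MatingDesign) -> np.ndarray:
    """Transition-rate matrix Q over ordered ancestor pairs.

    Each lineage independently leaves its ancestor at rate ``rho`` per Morgan
    and jumps uniformly to one of the other ``K-1``; simultaneous two-lineage
    jumps have rate 0.  Rows sum to zero.
    """
    k = design.n_ancestors
    rho = design.rho
    pairs = list(itertools.product(range(k), repeat=2))
    s = len(pairs)
    q = np.zeros((s, s))
    rate = rho / (k - 1)
    for a, (a1, a2) in enumerate(pairs):
        for b, (b1, b2) in enumerate(pairs):
            ndiff = (a1 != b1) + (a2 != b2)
            if ndiff == 1:
                q[a, b] = rate
        q[a, a] = -2.0 * rho
    return q


def transition_matrix(q: np.ndarray, d: float) -> np.ndarray:
    """Row-stochastic transition matrix ``exp(Q d)`` for a Morgan distance d."""
    if d < 0:
        raise ValueError("genetic distance must be nonnegative")
    t = expm(q * d)
    np.clip(t, 0.0, None, out=t)
    t /= t.sum(axis=1, keepdims=True)
    return t


def initial_distribution(t: np.ndarray) -> np.ndarray:
    """Stationary distribution: normalized leading left eigenvector of T."""
    vals, vecs = np.linalg.eig(t.T)
    idx = np.argmin(np.abs(vals - 1.0))
    if abs(vals[idx] - 1.0) > 1e-8:
        raise ValueError("transition matrix has no unit eigenvalue; not stochastic?")
    pi = np.real(vecs[:, idx])
    pi = np.abs(pi)
    total = pi.sum()
    if total == 0:
        raise ValueError("degenerate stationary eigenvector")
    return pi / total


@dataclass
class TransitionModel:
    """Per-interval transition matrices and the stationary initial law."""

    q: np.ndarray
    distances: np.ndarray  # (M-1,) Morgans
    matrices: list[np.ndarray]  # M-1 row-stochastic (S, S)
    initial: np.ndarray  # (S,)


def build_transition_model(
    design: MatingDesign, pos: np.ndarray, ed: float
) -> TransitionModel:
    q = build_rate_matrix(design)
    d = genetic_distances(pos, ed) if len(pos) > 1 else np.zeros(0)
    # distances repeat heavily on evenly spaced maps; cache the exponentials
    mats: list[np.ndarray] = []
    cache: dict[float, np.ndarray] = {}
    for dm in d:
        key = round(float(dm), 12)
        if key not in cache:
            cache[key] = transition_matrix(q, float(dm))
        mats.append(cache[key])
    ref = mats[0] if mats else transition_matrix(q, 0.01)
    return TransitionModel(q=q, distances=d, matrices=mats, initial=initial_distribution(ref))
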