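"""Independent brute-force oracles used by unit and acceptance tests.

These enumerate or directly evaluate the model definitions and never call the
dynamic-programming code paths they check.
"""

import itertools

import numpy as np


def emission_brute_force(y, h, combo, e_seq, w, e_ref, e_alt, inbred=True):
    """Offspring emission by explicit double sum over true and observable genotypes.

    Evaluates the three binomial kernels, the 3x3 mismapping table and the
    genotype indicator from first principles.
    """
    y_ref, y_alt = y
    kernel = [
        (1 - e_seq) ** y_ref * e_seq**y_alt,
        (1 - w) ** y_ref * w**y_alt,
        e_seq**y_ref * (1 - e_seq) ** y_alt,
    ]
    if all(k > 0 for k in kernel):
        total = sum(kernel)
        kernel = [k / total for k in kernel]
    else:
        floored = [k + 0.005 for k in kernel]
        total = sum(floored)
        kernel = [k / total for k in floored]
    table = [
        [1 - e_ref, e_ref, 0.0],
        [0.0, 1.0, 0.0],
        [0.0, e_alt, 1 - e_alt],
    ]
    combo = np.asarray(combo)
    anc = combo[:, 0] if inbred else combo.reshape(-1)
    implied = int(anc[h[0]] + anc[h[1]])
    total = 0.0
    for x in range(3):
        indicator = 1.0 if x == implied else 0.0
        p_y_given_x = sum(kernel[xp] * table[x][xp] for xp in range(3))
        total += p_y_given_x * indicator
    return total


def joint_logprob(log_pyx, gmap, log_lf, log_trans, log_pi, combo_seq, h_seq):
    """log P(H^o, X^f, Y^o, Y^f) of one concrete assignment (up to shared norms)."""
    n_markers, n_off, _ = log_pyx.shape
    n_combos = gmap.shape[0]
    lp = -n_markers * np.log(n_combos)  # uniform founder prior
    lp += sum(log_lf[m, combo_seq[m]] for m in range(n_markers))
    for i in range(n_off):
        lp += log_pi[h_seq[0, i]] + log_pyx[0, i, gmap[combo_seq[0], h_seq[0, i]]]
        for m in range(1, n_markers):
            lp += log_trans[m - 1][h_seq[m - 1, i], h_seq[m, i]]
            lp += log_pyx[m, i, gmap[combo_seq[m], h_seq[m, i]]]
    return lp


def exhaustive_joint_max(log_pyx, gmap, log_lf, log_trans, log_pi):
    """Maximum joint log-probability over all founder and haplotype sequences."""
    n_markers, n_off, _ = log_pyx.shape
    n_combos, n_states = gmap.shape
    best = -np.inf
    for combo_seq in itertools.product(range(n_combos), repeat=n_markers):
        lp = -n_markers * np.log(n_combos)
        lp += sum(log_lf[m, combo_seq[m]] for m in range(n_markers))
        if not np.isfinite(lp):
            continue
        for i in range(n_off):
            best_i = -np.inf
            for path in itertools.product(range(n_states), repeat=n_markers):
                v = log_pi[path[0]] + log_pyx[0, i, gmap[combo_seq[0], path[0]]]
                for m in range(1, n_markers):
                    v += log_trans[m - 1][path[m - 1], path[m]]
                    v += log_pyx[m, i, gmap[combo_seq[m], path[m]]]
                best_i = max(best_i, v)
            lp += best_i
        best = max(best, lp)
    return best


def random_tiny_instance(rng, space, max_markers=3, max_offspring=2, read_mean=2.0):
    """A random small decoding problem plus its prepared log quantities."""
    from hapclean.emission import ModelParams, founder_emission_matrix, genotype_likelihoods
    from hapclean.scheme import build_transition_model

    n_markers = int(rng.integers(1, max_markers + 1))
    n_off = int(rng.integers(1, max_offspring + 1))
    pos = np.sort(rng.choice(np.arange(1, 2_000_000), size=n_markers, replace=False))
    params = ModelParams(
        n_markers,
        e_seq=float(rng.uniform(0.001, 0.01)),
        ed=float(rng.uniform(0.01, 0.1)),
        w=rng.uniform(0.1, 0.9, n_markers),
        e_ref=rng.uniform(0, 0.2, n_markers),
        e_alt=rng.uniform(0, 0.2, n_markers),
    )
    oreads = rng.poisson(read_mean, size=(n_markers, n_off, 2))
    freads = rng.poisson(3.0, size=(n_markers, space.design.n_founders, 2))
    model = build_transition_model(space.design, pos, params.ed)
    pyx = genotype_likelihoods(oreads, params)
    lf = founder_emission_matrix(freads, space.founder_classes, params)
    with np.errstate(divide="ignore"):
        log_pyx, log_lf = np.log(pyx), np.log(lf)
        log_trans = [np.log(t) for t in model.matrices]
        log_pi = np.log(model.initial)
    return log_pyx, log_lf, log_trans, log_pi
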