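"""Independent brute-force oracles shared by test modules."""

import itertools

import numpy as np


def enumerate_fixed_margin(row_sums, col_sums):
    """Brute-force enumeration of binary matrices with given margins."""
    n_cols = len(col_sums)
    states = []
    row_choices = [
        list(itertools.combinations(range(n_cols), r)) for r in row_sums
    ]
    for combo in itertools.product(*row_choices):
        m = np.zeros((len(row_sums), n_cols), dtype=bool)
        for i, cols in enumerate(combo):
            m[i, list(cols)] = True
        if (m.sum(axis=0) == np.asarray(col_sums)).all():
            states.append(m)
    return states


def brute_force_poisson_binomial(probs):
    """Literal 2^N sum over all outcome combinations."""
    n = len(probs)
    pmf = np.zeros(n + 1)
    for bits in itertools.product([0, 1], repeat=n):
        p = 1.0
        for b, pi in zip(bits, probs):
            p *= pi if b else 1 - pi
        pmf[sum(bits)] += p
    return pmf
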