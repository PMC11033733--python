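"""Hot loops for binary-matrix randomization, JIT-compiled when numba is
available and falling back to pure Python otherwise."""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def deco(fn):
            return fn

        return deco


@njit(cache=True)
def sequential_swap_chain(m, n_sim, burn_in, thin, seed):
    """Checkerboard-swap Markov chain on a 0/1 matrix.

    Mutates ``m`` in place; emits ``n_sim`` snapshots, the first after
    ``burn_in`` accepted swaps and then one every ``thin`` accepted swaps.
    Row and column sums are invariant under every move.
    """
    np.random.seed(seed)
    nr, nc = m.shape
    out = np.empty((n_sim, nr, nc), dtype=np.uint8)
    accepted = 0
    emitted = 0
    target = burn_in
    while emitted < n_sim:
        i = np.random.randint(0, nr)
        j = np.random.randint(0, nr)
        k = np.random.randint(0, nc)
        l = np.random.randint(0, nc)
        if i == j or k == l:
            continue
        a = m[i, k]
        b = m[i, l]
        c = m[j, k]
        d = m[j, l]
        if a == 1 and d == 1 and b == 0 and c == 0:
            m[i, k] = 0
            m[j, l] = 0
            m[i, l] = 1
            m[j, k] = 1
        elif a == 0 and d == 0 and b == 1 and c == 1:
            m[i, k] = 1
            m[j, l] = 1
            m[i, l] = 0
            m[j, k] = 0
        else:
            continue
        accepted += 1
        if accepted >= target:
            out[emitted] = m
            emitted += 1
            target += thin
    return out


@njit(cache=True)
def quasiswap_repair(m, seed):
    """Reduce a non-negative integer matrix with fixed marginals to 0/1.

    Repeated 2x2 moves (decrement one diagonal, increment the other) that
    never increase the excess  sum(max(entry - 1, 0)); terminates when the
    matrix is binary.  Marginals are preserved by every move.
    """
    np.random.seed(seed)
    nr, nc = m.shape
    excess = 0
    for i in range(nr):
        for k in range(nc):
            if m[i, k] > 1:
                excess += m[i, k] - 1
    while excess > 0:
        # random cell holding surplus
        while True:
            i = np.random.randint(0, nr)
            k = np.random.randint(0, nc)
            if m[i, k] > 1:
                break
        # random occupied partner cell off this row and column
        while True:
            j = np.random.randint(0, nr)
            l = np.random.randint(0, nc)
            if j != i and l != k and m[j, l] > 0:
                break
        delta = -1  # m[i,k] > 1 loses one surplus unit
        if m[j, l] > 1:
            delta -= 1
        if m[i, l] >= 1:
            delta += 1
        if m[j, k] >= 1:
            delta += 1
        if delta <= 0:
            m[i, k] -= 1
            m[j, l] -= 1
            m[i, l] += 1
            m[j, k] += 1
            excess += delta
    return m
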