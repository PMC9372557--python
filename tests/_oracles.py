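"""Independent numeric oracles used only by the tests.

These deliberately avoid the package's own code paths: the principal
eigenvector is obtained by plain power iteration, the principal
eigenvalue by the dense eigensolver, and random judgment matrices are
built directly from their defining structure.
"""

from __future__ import annotations

import numpy as np


def power_iteration_weights(a: np.ndarray, iters: int = 500) -> np.ndarray:
    """Principal right eigenvector of a positive matrix, sum-normalized."""
    w = np.full(a.shape[0], 1.0 / a.shape[0])
    for _ in range(iters):
        w = a @ w
        w = w / w.sum()
    return w


def principal_eigenvalue(a: np.ndarray) -> float:
    """Largest-modulus eigenvalue via the dense eigensolver."""
    vals = np.linalg.eigvals(a)
    return float(vals[np.argmax(vals.real)].real)


def random_saaty_weights(n: int, rng: np.random.Generator) -> np.ndarray:
    """Positive weights whose ratio spread fits the 1-9 scale."""
    w = rng.uniform(1.0, 9.0, size=n)
    return w / w.sum()


def random_reciprocal_pcm(n: int, rng: np.random.Generator) -> np.ndarray:
    """Arbitrary (possibly very inconsistent) valid reciprocal matrix."""
    a = np.ones((n, n))
    iu = np.triu_indices(n, k=1)
    upper = np.exp(rng.uniform(np.log(1 / 9), np.log(9), size=len(iu[0])))
    a[iu] = upper
    a[(iu[1], iu[0])] = 1.0 / upper
    return a
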