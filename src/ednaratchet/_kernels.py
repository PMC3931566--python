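"""Optional numba-accelerated inner loops with numpy fallbacks.

Only the eDNA production scatter (N genomes × l alleles per generation) is
hot enough to warrant a compiled kernel; everything else stays in plain
vectorized numpy.  Results are integer-exact, so the two paths agree
bit-for-bit.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly when numba is present
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False


def _add_genomes_numpy(mat: np.ndarray, loci: np.ndarray, chosen: np.ndarray, weights: np.ndarray) -> None:
    a = mat.shape[1]
    l = loci.shape[1]
    codes = loci[chosen].astype(np.int64) + np.arange(l, dtype=np.int64)[None, :] * a
    add = np.bincount(codes.ravel(), weights=np.repeat(weights, l), minlength=l * a)
    mat += add.astype(np.int64).reshape(l, a)


if HAVE_NUMBA:

    @njit(cache=False)
    def _add_genomes_numba(mat, loci, chosen, weights):  # pragma: no cover
        l = loci.shape[1]
        for c in range(chosen.size):
            i = chosen[c]
            w = weights[c]
            for k in range(l):
                mat[k, loci[i, k]] += w

    def add_genomes(mat, loci, chosen, weights):
        """mat[k, loci[i, k]] += weights[c] for each chosen genome i."""
        _add_genomes_numba(mat, loci, chosen.astype(np.int64), weights.astype(np.int64))

else:
    add_genomes = _add_genomes_numpy
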