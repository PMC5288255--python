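"""Independent reference implementations used as oracles by the tests.

These deliberately take different computational routes from the package:
KMO via pairwise Schur-complement partial correlations (the package uses
the anti-image matrix from the full inverse), Bartlett via a direct
determinant (the package uses the eigenvalue product).
"""

import numpy as np


def kmo_reference(R: np.ndarray) -> float:
    p = R.shape[0]
    r2 = q2 = 0.0
    for i in range(p):
        for j in range(p):
            if i == j:
                continue
            K = [k for k in range(p) if k not in (i, j)]
            RKK = R[np.ix_(K, K)]
            riK = R[i, K]
            rjK = R[j, K]
            sol_i = np.linalg.solve(RKK, riK)
            sol_j = np.linalg.solve(RKK, rjK)
            num = R[i, j] - riK @ sol_j
            den = np.sqrt((1 - riK @ sol_i) * (1 - rjK @ sol_j))
            r2 += R[i, j] ** 2
            q2 += (num / den) ** 2
    return r2 / (r2 + q2)


def bartlett_reference(R: np.ndarray, n: int) -> float:
    p = R.shape[0]
    return -(n - 1 - (2 * p + 5) / 6.0) * np.log(np.linalg.det(R))
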