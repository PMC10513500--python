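"""Independent brute-force oracles shared by the test suite."""

import itertools
import math

import numpy as np


def exact_shapley_oracle(f, background, instance):
    """Exact Shapley values by enumerating all 2^d coalitions.

    The coalition value v(S) is the mean over background rows of f applied
    to a hybrid point taking the instance's values on S and the background
    row's values elsewhere.
    """
    background = np.asarray(background, dtype=float)
    instance = np.asarray(instance, dtype=float)
    d = len(instance)
    out = np.zeros(d)

    def value(subset):
        mat = background.copy()
        for j in subset:
            mat[:, j] = instance[j]
        return float(np.mean(f(mat)))

    for j in range(d):
        others = [k for k in range(d) if k != j]
        for r in range(d):
            for subset in itertools.combinations(others, r):
                weight = (
                    math.factorial(len(subset))
                    * math.factorial(d - len(subset) - 1)
                    / math.factorial(d)
                )
                out[j] += weight * (value(subset + (j,)) - value(subset))
    return out
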