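"""Independent oracles for the test suite.

Everything here is written from first principles with scalar arithmetic and
exhaustive enumeration, deliberately sharing no code with the package.
"""

from __future__ import annotations

import itertools
import math


def logistic_correct_prob(d: float, s: float, r: float) -> float:
    """Scalar probability of a correct decision (limit values at d in {0,1})."""
    if d <= 0.0:
        return 1.0
    if d >= 1.0:
        return 0.0
    return 1.0 / (1.0 + (d / (1.0 - d)) * math.exp(-s * r))


def enumerate_sequence(difficulties: list[float], s: float) -> dict:
    """Exact expectations by exhaustive enumeration over all 2^N paths.

    Each path of correctness outcomes has probability equal to the product
    of its per-position conditional probabilities, where position i (0-based)
    sees the signal (sum of +/-1-coded prior outcomes) / i. Returns the
    exact expected fraction correct, its across-run variance, and the exact
    per-position probability of a correct decision.
    """
    n = len(difficulties)
    e_frac = 0.0
    e_frac2 = 0.0
    per_position = [0.0] * n
    for path in itertools.product((0, 1), repeat=n):
        prob = 1.0
        score = 0
        for i, c in enumerate(path):
            r = 0.0 if i == 0 else score / i
            p = logistic_correct_prob(difficulties[i], s, r)
            prob *= p if c else (1.0 - p)
            score += 2 * c - 1
        frac = sum(path) / n
        e_frac += prob * frac
        e_frac2 += prob * frac * frac
        for i, c in enumerate(path):
            if c:
                per_position[i] += prob
    return {
        "fraction_correct": e_frac,
        "variance": e_frac2 - e_frac**2,
        "by_position": per_position,
    }


def enumerate_scenario(
    d_bar: float, b: float, v: int, s: float, aligned_flags: list[bool]
) -> dict:
    """Enumeration oracle in terms of (d_bar, b, v) and an alignment order."""
    d_align = d_bar - b * v / 2.0
    d_mis = d_bar + b * v / 2.0
    difficulties = [d_align if a else d_mis for a in aligned_flags]
    return enumerate_sequence(difficulties, s)
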