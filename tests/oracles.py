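"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the package's own code paths: threshold selection is
an exhaustive scan over every real-threshold interval with exact Fraction
arithmetic, and the hypergeometric upper tail is an exact sum of binomial
coefficients.
"""

from fractions import Fraction
from math import comb


def youden_scan(tp_values, fp_values):
    """Exhaustive maximum of TPR - FPR over all real thresholds.

    J(t) is a step function changing only at the observed values, with calls
    made inclusively (value >= t), so scanning every unique observed value
    plus one point above the maximum covers every real-threshold interval.
    Returns (best_j as Fraction, largest threshold attaining it).
    """
    tp = sorted(tp_values)
    fp = sorted(fp_values)
    candidates = sorted(set(tp) | set(fp))
    candidates.append(max(candidates) + 1.0)
    best_j, best_t = None, None
    for t in candidates:
        tpr = Fraction(sum(1 for v in tp if v >= t), len(tp))
        fpr = Fraction(sum(1 for v in fp if v >= t), len(fp))
        j = tpr - fpr
        if best_j is None or j > best_j or (j == best_j and t > best_t):
            best_j, best_t = j, t
    return best_j, best_t


def hypergeom_upper_exact(k, n1, n2, N):
    """Exact P(X >= k), X ~ Hypergeometric(N, n1, n2), as a Fraction."""
    total = comb(N, n2)
    num = sum(comb(n1, i) * comb(N - n1, n2 - i) for i in range(k, min(n1, n2) + 1))
    return Fraction(num, total)
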