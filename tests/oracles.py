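"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own implementations: the
Hardy-Weinberg oracle enumerates every heterozygote configuration
directly from log-factorials, and the odds-ratio oracle is the 2x2
cross-product formula.
"""

import numpy as np
from scipy.special import gammaln


def hwe_exact_brute_force(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact HWE p by full enumeration of heterozygote counts."""
    n = n_hom_major + n_het + n_hom_minor
    rare = 2 * min(n_hom_major, n_hom_minor) + n_het
    if rare == 0:
        return 1.0

    def log_prob(h: int) -> float:
        a = (rare - h) // 2  # minor homozygotes
        b = n - h - a  # major homozygotes
        return (
            gammaln(n + 1)
            - gammaln(a + 1)
            - gammaln(h + 1)
            - gammaln(b + 1)
            + h * np.log(2.0)
            + gammaln(rare + 1)
            + gammaln(2 * n - rare + 1)
            - gammaln(2 * n + 1)
        )

    hs = [h for h in range(rare % 2, rare + 1, 2) if n - h - (rare - h) // 2 >= 0]
    probs = np.exp([log_prob(h) for h in hs])
    probs = probs / probs.sum()
    p_obs = probs[hs.index(n_het)]
    return float(probs[probs <= p_obs * (1.0 + 1e-12)].sum())


def cross_product_or(a: int, b: int, c: int, d: int) -> float:
    """OR = (a*d)/(b*c) for table [[a, b], [c, d]] (case/ctrl x exp/unexp)."""
    return (a * d) / (b * c)


def pearson_chi2(table: np.ndarray) -> float:
    """Pearson chi-square statistic, computed from first principles."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    return float(((table - expected) ** 2 / expected).sum())


def empirical_tail_p(z_obs: float, null_z) -> float:
    """Two-sided add-one empirical p by direct counting."""
    null_z = np.asarray(null_z, dtype=float)
    return (int(np.sum(np.abs(null_z) >= abs(z_obs))) + 1) / (null_z.size + 1)
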