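"""Independent brute-force oracle for the conditioned NB exact test.

Deliberately avoids scipy distributions and vectorisation: probabilities
come from explicit log-gamma formulas and the conditional sum is a plain
Python loop, so agreement with the package's implementation is a genuine
dual-route check.
"""

import math


def nb_log_pmf(k: int, mu: float, alpha: float) -> float:
    """log NB(mean mu, variance mu + alpha mu^2) pmf; Poisson at alpha=0."""
    if mu <= 0:
        return 0.0 if k == 0 else -math.inf
    if alpha == 0:
        return k * math.log(mu) - mu - math.lgamma(k + 1)
    r = 1.0 / alpha
    return (
        math.lgamma(k + r)
        - math.lgamma(r)
        - math.lgamma(k + 1)
        + r * math.log(r / (r + mu))
        + k * math.log(mu / (r + mu))
    )


def conditioned_test_enumeration(
    k_a: int, k_b: int, s_a: float, s_b: float, q_hat: float, alpha: float
) -> float:
    """Enumerate every split a + b = k_a + k_b of the conditional law."""
    ks = k_a + k_b
    if ks == 0:
        return 1.0
    mu_a, mu_b = q_hat * s_a, q_hat * s_b
    probs = [
        math.exp(nb_log_pmf(a, mu_a, alpha) + nb_log_pmf(ks - a, mu_b, alpha))
        for a in range(ks + 1)
    ]
    total = sum(probs)
    p_obs = probs[k_a]
    numer = sum(p for p in probs if p <= p_obs * (1.0 + 1e-12))
    return min(numer / total, 1.0)
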