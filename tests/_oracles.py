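"""Independent numerical oracles: direct quadrature of the model definition.

These integrate the onset-age density against the exponential sojourn law
segment by segment, without any of the closed-form algebra used by the
package, so agreement is a genuine dual-route check.
"""

import numpy as np
from scipy.integrate import quad


def interval_case_prob_quad(w, beta, lam, t0, T, delta, j):
    """P(interval case in (t_{j-1}, t_j)) by piecewise quadrature."""
    t = lambda i: t0 + i * delta
    tjm1, tj = t(j - 1), t(j)

    def onset_contrib(u, n_missed):
        # clinical onset must land in (t_{j-1}, t_j); n_missed exams failed
        return (
            w
            * (1.0 - beta) ** n_missed
            * (np.exp(-(tjm1 - u) / lam) - np.exp(-(tj - u) / lam))
        )

    total = quad(lambda u: onset_contrib(u, j), 0.0, t0, epsabs=1e-14)[0]
    for i in range(1, j):
        total += quad(lambda u: onset_contrib(u, j - i), t(i - 1), t(i), epsabs=1e-14)[0]
    # onset inside the same interval: no exam intervenes
    total += quad(
        lambda u: w * (1.0 - np.exp(-(tj - u) / lam)), tjm1, tj, epsabs=1e-14
    )[0]
    return total


def detection_weight_quad(w, beta, lam, t0, T, delta, i):
    """Joint mass of first detection at exam t_i, by piecewise quadrature."""
    t = lambda m: t0 + m * delta
    ti = t(i)

    def onset_contrib(u, n_missed):
        # still preclinical at t_i; n_missed earlier exams failed; exam i hits
        return w * (1.0 - beta) ** n_missed * np.exp(-(ti - u) / lam) * beta

    total = quad(lambda u: onset_contrib(u, i), 0.0, t0, epsabs=1e-14)[0]
    for m in range(1, i + 1):
        total += quad(lambda u: onset_contrib(u, i - m), t(m - 1), t(m), epsabs=1e-14)[0]
    return total
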