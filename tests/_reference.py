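"""Independent oracles used only by the test suite.

These deliberately use different algorithms from the package code so
that agreement is a genuine cross-check, not a tautology.
"""

import numpy as np


def _log_sum_fermi(x):
    lf = -np.logaddexp(0.0, x)
    m = lf.max()
    return m + np.log(np.exp(lf - m).sum())


def bar_fixed_point(forward_du, backward_du, kt, tol=1e-12, max_iter=20000):
    """Bennett acceptance ratio by self-consistent (fixed-point) iteration.

    The package solves the log-ratio equation by bisection; this oracle
    iterates ``c <- c + logsumR(c) - logsumF(c)`` (a contraction: the
    update is decreasing in c with derivative in (-2, 0)) from zero
    until the update falls below ``tol`` (in kT units).
    Sample convention matches :class:`porefep.fep.WindowSamples`:
    both arrays store dU = U(high) - U(low).
    """
    u_f = np.asarray(forward_du, dtype=float) / kt
    u_r = -np.asarray(backward_du, dtype=float) / kt
    m = np.log(u_f.size / u_r.size)
    c = 0.0
    for _ in range(max_iter):
        delta = _log_sum_fermi(-m + u_r + c) - _log_sum_fermi(m + u_f - c)
        c_new = c + delta
        if abs(delta) < tol:
            return c_new * kt
        c = c_new
    raise RuntimeError("fixed-point BAR did not converge")


def effective_sample_size(x, max_lag=5000):
    """ESS from the integrated autocorrelation time (initial positive
    sequence truncation)."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    n = x.size
    var = x.var()
    if var == 0:
        return float(n)
    acf = np.correlate(x, x, "full")[n - 1 :] / (n * var)
    tau = 1.0
    for k in range(1, min(n, max_lag)):
        if acf[k] <= 0:
            break
        tau += 2.0 * acf[k]
    return n / tau
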