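"""Independent high-precision oracles for the closed-form estimators.

Everything here re-evaluates the printed expressions term by term with
50-digit decimal arithmetic, never calling the package's own float
implementations.  Tests freeze values computed with these functions and
also re-run them at test time to guard the frozen constants.
"""

from decimal import Decimal, getcontext

getcontext().prec = 50

K_BOLTZMANN = Decimal("1.380649e-23")
N_AVOGADRO = Decimal("6.02214076e23")
_LN2 = Decimal(2).ln()


def _d(x) -> Decimal:
    return x if isinstance(x, Decimal) else Decimal(str(x))


def dec_log2(x) -> Decimal:
    return _d(x).ln() / _LN2


def dec_entropy_general(N, L, M, r, a, pk) -> Decimal:
    """Three-term sequential entropy in units of k, 50-digit decimals."""
    N, L, M = _d(N), _d(L), _d(M)
    W = N / (M + L / 2)
    mix = M * W * sum((_d(x) * (1 / _d(x)).ln() for x in r if x), Decimal(0))
    con = W * sum((_d(x) * (1 / _d(x)).ln() for x in a if x), Decimal(0))
    seq = (L / 2) * W * sum((_d(x) * (1 / _d(x)).ln() for x in pk if x), Decimal(0))
    return mix + con + seq


def dec_entropy_uniform(n, N, L, M, p) -> Decimal:
    """W * [M ln n + ln L + p (L/2) ln n] in units of k."""
    n, N, L, M, p = _d(n), _d(N), _d(L), _d(M), _d(p)
    W = N / (M + L / 2)
    return W * (M * n.ln() + L.ln() + p * (L / 2) * n.ln())


def dec_c1_mixed(n, L, p, N, M) -> Decimal:
    n, L, p, N, M = _d(n), _d(L), _d(p), _d(N), _d(M)
    count = p * N / (L + M)
    census = (n.ln() * L).exp() * dec_log2(count) if count > 1 else Decimal(0)
    return L * dec_log2(n) + census


def dec_c2_mixed(n, L, p, N, M) -> Decimal:
    n, L, p, N, M = _d(n), _d(L), _d(p), _d(N), _d(M)
    return L * dec_log2(n) + L * (p * N / (L + M)) * dec_log2(n)


def dec_c1_random(n, L, N) -> Decimal:
    n, L, N = _d(n), _d(L), _d(N)
    return (n.ln() * L).exp() * dec_log2(N / L) if N / L > 1 else Decimal(0)


def dec_c2_explicit(N, n) -> Decimal:
    return _d(N) * dec_log2(n)
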