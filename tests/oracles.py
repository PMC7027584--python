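"""Arbitrary-precision reference implementations of the estimators.

Direct formula evaluation in 60-digit decimal arithmetic, written
independently of the package's float code paths: inputs are converted from
binary floats exactly, so any disagreement beyond ~1e-15 relative is a
defect in one of the two routes.
"""

from decimal import Decimal, getcontext

getcontext().prec = 60

ONE = Decimal(1)


def _d(x) -> Decimal:
    return Decimal(x)  # exact conversion from float


def fixed_pool(pairs):
    """(estimate, se) of the inverse-variance fixed-effect pool."""
    w = [ONE / _d(v) for _, v in pairs]
    sw = sum(w)
    est = sum(wi * _d(th) for wi, (th, _) in zip(w, pairs)) / sw
    return est, (ONE / sw).sqrt()


def q_statistic(pairs):
    w = [ONE / _d(v) for _, v in pairs]
    sw = sum(w)
    theta = sum(wi * _d(th) for wi, (th, _) in zip(w, pairs)) / sw
    return sum(wi * (_d(th) - theta) ** 2 for wi, (th, _) in zip(w, pairs))


def i_squared(q, df):
    df = Decimal(df)
    if df == 0 or q <= df:
        return Decimal(0)
    return Decimal(100) * (q - df) / q


def tau2_dl(pairs):
    w = [ONE / _d(v) for _, v in pairs]
    sw = sum(w)
    c = sw - sum(wi * wi for wi in w) / sw
    q = q_statistic(pairs)
    df = Decimal(len(pairs) - 1)
    return max(Decimal(0), (q - df) / c)


def random_pool(pairs):
    """(estimate, se) of the DerSimonian-Laird random-effects pool."""
    t2 = tau2_dl(pairs)
    w = [ONE / (_d(v) + t2) for _, v in pairs]
    sw = sum(w)
    est = sum(wi * _d(th) for wi, (th, _) in zip(w, pairs)) / sw
    return est, (ONE / sw).sqrt()


def smd(n1, m1, s1, n2, m2, s2, hedges=False):
    """(d, variance) of the change-score SMD."""
    n1d, n2d = Decimal(n1), Decimal(n2)
    sp2 = ((n1d - 1) * _d(s1) ** 2 + (n2d - 1) * _d(s2) ** 2) / (n1d + n2d - 2)
    d = (_d(m1) - _d(m2)) / sp2.sqrt()
    var = (n1d + n2d) / (n1d * n2d) + d * d / (2 * (n1d + n2d))
    if hedges:
        j = ONE - Decimal(3) / (4 * (n1d + n2d - 2) - 1)
        d *= j
        var *= j * j
    return d, var


def log_odds_ratio(e1, n1, e2, n2, continuity="0.5"):
    """(log OR, Woolf variance), with the all-cells continuity rule."""
    a, b = Decimal(e1), Decimal(n1 - e1)
    c, dd = Decimal(e2), Decimal(n2 - e2)
    if min(a, b, c, dd) == 0:
        cc = Decimal(continuity)
        a, b, c, dd = a + cc, b + cc, c + cc, dd + cc
    est = (a * dd / (b * c)).ln()
    var = ONE / a + ONE / b + ONE / c + ONE / dd
    return est, var
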