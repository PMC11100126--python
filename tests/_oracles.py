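"""Independent brute-force evaluations of the printed metric sum formulas.

Everything here is plain-Python arithmetic over ``math.fsum`` (extended
precision accumulation), kept deliberately independent of the package's
vectorised implementations.
"""

from math import fsum
from statistics import median


def oracle_r(y, p):
    n = len(y)
    yb = fsum(y) / n
    pb = fsum(p) / n
    num = fsum((yi - yb) * (pi - pb) for yi, pi in zip(y, p))
    dy = fsum((yi - yb) ** 2 for yi in y)
    dp = fsum((pi - pb) ** 2 for pi in p)
    return num / (dy * dp) ** 0.5


def oracle_r2(y, p):
    n = len(y)
    yb = fsum(y) / n
    pb = fsum(p) / n
    num = fsum((yi - yb) * (pi - pb) for yi, pi in zip(y, p)) ** 2
    den = fsum((yi - yb) ** 2 for yi in y) * fsum((pi - pb) ** 2 for pi in p)
    return num / den


def oracle_r2_1a(y, p, train_mean):
    sse = fsum((yi - pi) ** 2 for yi, pi in zip(y, p))
    den = fsum((yi - train_mean) ** 2 for yi in y)
    return 1.0 - sse / den


def oracle_r2_1b(y, p):
    yb = fsum(y) / len(y)
    sse = fsum((yi - pi) ** 2 for yi, pi in zip(y, p))
    den = fsum((yi - yb) ** 2 for yi in y)
    return 1.0 - sse / den


def oracle_mspe(y, p):
    return fsum((yi - pi) ** 2 for yi, pi in zip(y, p)) / len(y)


def oracle_mae(y, p):
    return median(abs(yi - pi) for yi, pi in zip(y, p))
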