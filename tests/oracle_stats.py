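"""Independent brute-force disproportionality formulas for cross-checking.

Deliberately written from the definitions, without importing anything from
the package, so tests can compare the implementation against a second,
independent path.
"""

import math


def oracle_ror(a, b, c, d):
    if min(a, b, c, d) <= 0:
        return None
    ror = (a * d) / (b * c)
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    return ror, math.exp(math.log(ror) - 1.96 * se), math.exp(math.log(ror) + 1.96 * se)


def oracle_prr(a, b, c, d):
    if a <= 0 or c <= 0:
        return None
    prr = (a / (a + b)) / (c / (c + d))
    se = math.sqrt(1.0 / a - 1.0 / (a + b) + 1.0 / c - 1.0 / (c + d))
    lo = math.exp(math.log(prr) - 1.96 * se)
    hi = math.exp(math.log(prr) + 1.96 * se)
    n = a + b + c + d
    chi2 = (a * d - b * c) ** 2 * n / ((a + b) * (c + d) * (a + c) * (b + d))
    return prr, lo, hi, chi2


def oracle_ic(a, b, c, d):
    if a <= 0:
        return None
    n = a + b + c + d
    ratio = a * n / ((a + c) * (a + b))
    ic = math.log2(ratio)
    if min(a, b, c, d) <= 0:
        return ic, None
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    ic025 = math.log2(ratio * math.exp(-1.96 * se))
    return ic, ic025


def oracle_ebgm(a, b, c, d):
    if a <= 0:
        return None
    n = a + b + c + d
    ebgm = a * n / ((a + c) * (a + b))
    if min(a, b, c, d) <= 0:
        return ebgm, None, None
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    return (ebgm, math.exp(math.log(ebgm) - 1.96 * se),
            math.exp(math.log(ebgm) + 1.96 * se))
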