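"""Independent oracles used by the test suite.

High-precision (50-digit decimal) closed-form evaluation of the ROR and
BCPNN expressions, plus small brute-force scan/count helpers.  These stay
deliberately independent of the package's float implementations.
"""
from __future__ import annotations

import decimal
from decimal import Decimal

CTX = decimal.Context(prec=50)


def _d(x) -> Decimal:
    return CTX.create_decimal(str(x))


def _log2(x: Decimal) -> Decimal:
    return CTX.divide(CTX.ln(x), CTX.ln(_d(2)))


def dec_ror(a, b, c, d, z="1.96"):
    """50-digit ROR, ln ROR, SE and Wald CI (zero correction applied when
    b, c or d is zero, mirroring the documented contract)."""
    if min(b, c, d) == 0:
        a, b, c, d = (
            _d(a) + _d("0.5"),
            _d(b) + _d("0.5"),
            _d(c) + _d("0.5"),
            _d(d) + _d("0.5"),
        )
    else:
        a, b, c, d = _d(a), _d(b), _d(c), _d(d)
    z = _d(z)
    one = _d(1)
    ror = CTX.divide(CTX.multiply(a, d), CTX.multiply(b, c))
    ln_ror = CTX.ln(ror)
    se = CTX.sqrt(
        CTX.divide(one, a) + CTX.divide(one, b) + CTX.divide(one, c) + CTX.divide(one, d)
    )
    lower = CTX.exp(ln_ror - CTX.multiply(z, se))
    upper = CTX.exp(ln_ror + CTX.multiply(z, se))
    return {"ror": ror, "ln_ror": ln_ror, "se": se, "ci_lower": lower, "ci_upper": upper}


def dec_bcpnn(a, b, c, d, alpha1=1, beta1=1, alpha=2, beta=2, gamma11=1):
    """50-digit BCPNN information-component expressions."""
    a, b, c, d = _d(a), _d(b), _d(c), _d(d)
    n = a + b + c + d
    a1, b1, al, be, g11 = _d(alpha1), _d(beta1), _d(alpha), _d(beta), _d(gamma11)
    ab, ac = a + b, a + c
    one = _d(1)

    ic_raw = _log2(CTX.divide(CTX.multiply(a, n), CTX.multiply(ab, ac)))
    gamma = CTX.divide(
        CTX.multiply(g11, CTX.multiply(n + al, n + be)),
        CTX.multiply(ab + a1, ac + b1),
    )
    e_ic = _log2(
        CTX.divide(
            CTX.multiply(a + g11, CTX.multiply(n + al, n + be)),
            CTX.multiply(n + gamma, CTX.multiply(ab + a1, ac + b1)),
        )
    )
    inv_ln2_sq = CTX.power(CTX.divide(one, CTX.ln(_d(2))), _d(2))
    v_ic = CTX.multiply(
        inv_ln2_sq,
        CTX.divide(n - a + gamma - g11, CTX.multiply(a + g11, one + n + gamma))
        + CTX.divide(n - ab + al - a1, CTX.multiply(ab + a1, one + n + al))
        + CTX.divide(n - ac + be - b1, CTX.multiply(ac + b1, one + n + be)),
    )
    sd = CTX.sqrt(v_ic)
    ic025 = e_ic - CTX.multiply(_d(2), sd)
    return {"ic_raw": ic_raw, "e_ic": e_ic, "v_ic": v_ic, "ic025": ic025}


def rel_err(approx: float, exact: Decimal) -> float:
    exact_f = float(exact)
    denom = max(abs(exact_f), 1e-300)
    return abs(approx - exact_f) / denom


def brute_force_cells(reports, drug, pt):
    """Quadruple-branch scan: independent count of the fourfold table."""
    a = b = c = d = 0
    for rep in reports:
        has_drug = any(m.name == drug and m.role.value == "PS" for m in rep.drugs)
        has_pt = any(r.pt_name == pt for r in rep.reactions)
        if has_drug and has_pt:
            a += 1
        elif has_drug and not has_pt:
            b += 1
        elif has_pt:
            c += 1
        else:
            d += 1
    return a, b, c, d


def random_table(rng, n_min=20, n_max=100_000, a_min=1, a_max=200):
    """A random valid fourfold table with a >= a_min and N in range."""
    while True:
        n = int(rng.integers(n_min, n_max))
        a = int(rng.integers(a_min, a_max))
        b = int(rng.integers(0, max(1, n // 4)))
        c = int(rng.integers(0, max(1, n // 4)))
        if a + b + c <= n:
            return a, b, c, n - a - b - c
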