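"""National Provider Identifier (NPI) validation and synthesis.

An NPI is a 10-digit identifier whose final digit is a Luhn check digit
computed over the 9-digit base prefixed with the card-issuer constant
``80840`` (ISO 7812 health-industry prefix). The leading digit of an NPI
is 1 or 2.
"""

from __future__ import annotations

import numpy as np

NPI_PREFIX = "80840"


def luhn_check_digit(digits: str) -> int:
    """Luhn check digit for a numeric string (check digit to be appended)."""
    total = 0
    for i, ch in enumerate(reversed(digits)):
        d = int(ch)
        if i % 2 == 0:  # rightmost base digit is doubled
            d *= 2
            if d > 9:
                d -= 9
        total += d
    return (10 - total % 10) % 10


def validate_npi(candidate: object) -> bool:
    """True iff ``candidate`` is a structurally valid 10-digit NPI.

    Requires 10 ASCII digits, leading digit in {1, 2}, and a correct Luhn
    check digit over the 80840-prefixed 9-digit base. Any malformed input
    (wrong length, non-numeric, None/NaN) returns False.
    """
    if not isinstance(candidate, str):
        return False
    if len(candidate) != 10 or not candidate.isdigit():
        return False
    if candidate[0] not in ("1", "2"):
        return False
    return luhn_check_digit(NPI_PREFIX + candidate[:9]) == int(candidate[9])


def generate_npis(n: int, rng: np.random.Generator) -> list[str]:
    """Generate ``n`` distinct structurally valid NPIs."""
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        lead = str(rng.integers(1, 3))
        body = "".join(str(d) for d in rng.integers(0, 10, size=8))
        base = lead + body
        npi = base + str(luhn_check_digit(NPI_PREFIX + base))
        if npi not in seen:
            seen.add(npi)
            out.append(npi)
    return out
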