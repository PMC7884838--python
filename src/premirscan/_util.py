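"""Small shared helpers: complements, half-up rounding, seeded RNG streams."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import numpy as np

_COMPLEMENT = str.maketrans(
    "ACGTUNRYSWKMBDHVacgtunryswkmbdhv",
    "TGCAANYRSWMKVHDBtgcaanyrswmkvhdb",
)


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC-aware, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def round_half_up(value, ndigits: int) -> float:
    """Decimal half-up rounding, matching how printed report tables are rounded."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(value)).quantize(q, rounding=ROUND_HALF_UP))


def ratio_percent(numerator: int, denominator: int, ndigits: int) -> float:
    """100*numerator/denominator with exact decimal half-up rounding.

    Rounding is done on the exact rational value, not on an intermediate float,
    so boundary cases (….005) round the way a printed table would.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    q = Decimal(1).scaleb(-ndigits)
    return float(
        (Decimal(100 * numerator) / Decimal(denominator)).quantize(
            q, rounding=ROUND_HALF_UP
        )
    )


def child_rng(seed: int, offset: int) -> np.random.Generator:
    """Derive an independent deterministic stream for one pipeline stage.

    A single user-facing integer seed drives the whole run; each stage uses a
    fixed small offset so stages can be rerun in isolation reproducibly.
    """
    return np.random.default_rng(int(seed) + int(offset))
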