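"""Small shared helpers: surface-form normalization and half-up rounding."""

from __future__ import annotations

import unicodedata
from decimal import ROUND_HALF_UP, Decimal


def normalize_surface(text: str) -> str:
    """Normalize a surface form for terminology matching.

    Unicode NFC, case-fold, and collapse internal whitespace. No stemming:
    terminologies list exact consumer surface forms.
    """
    folded = unicodedata.normalize("NFC", text).casefold()
    return " ".join(folded.split())


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round with ties away from zero, at decimal (not binary) precision.

    Used for reported percentages and average document frequencies so that
    printed tables round the way people round by hand (82.45 -> 82.5), not
    the way float banker's rounding does.
    """
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP))


def round_half_up_int(value: float) -> int:
    return int(round_half_up(value, 0))
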