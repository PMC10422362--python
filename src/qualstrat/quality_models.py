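"""Phred symbol conversions and published basecaller quality-score formulas.

Two score families are implemented:

* the likelihood-ratio score used by CTC-style basecallers (Chiron,
  Causalcall): ``qs = 10 * log10(P1 / P2)``, where P1 and P2 are the
  probabilities of the most and second-most likely nucleotide at a position;
* the scaled Phred-style score used by RNN basecallers (Flappie, Nanonet):
  ``qs = -10 * (y * log10(1 - p) + log10(x))``, where ``p`` is the probability
  of the most likely nucleotide and ``(x, y)`` are tool-internal scaling
  coefficients.

The six built-in ``(x, y)`` coefficient sets are the published values for
Flappie and the five Nanonet read categories. With ``x = y = 1`` the scaled
formula reduces to the standard Phred transform ``-10 * log10(1 - p)``, which
is the Flappie row (and the "Nanonet another" fallback row).

Symbols follow the Sanger convention throughout: character ordinal = Q + 33,
error probability = 10^(-Q/10).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

PHRED_OFFSET = 33
SYMBOL_MIN = 33
SYMBOL_MAX = 126
PHRED_MAX = SYMBOL_MAX - SYMBOL_MIN  # 93


@dataclass(frozen=True)
class QualitySymbol:
    """One FASTQ quality character with its Phred value and error probability."""

    symbol: str
    phred: int
    error_prob: float


@dataclass(frozen=True)
class ScalingCoefficients:
    """An ``(x, y)`` pair selecting one basecaller quality model."""

    model_name: str
    x: float
    y: float

    def __post_init__(self) -> None:
        if self.x <= 0 or self.y <= 0:
            raise ValueError(f"{self.model_name}: coefficients must be positive")


#: Published coefficient sets, one row per model.
COEFFICIENTS: dict[str, ScalingCoefficients] = {
    name: ScalingCoefficients(name, x, y)
    for name, x, y in [
        ("flappie", 1.00000, 1.00000),
        ("nanonet_template_high_p", 0.05524, 0.70268),
        ("nanonet_template_low_p", 0.20938, 1.00776),
        ("nanonet_complement", 0.13120, 0.88952),
        ("nanonet_2d", 0.02657, 0.65590),
        ("nanonet_another", 1.00000, 1.00000),
    ]
}


def phred_from_symbol(symbol: str) -> QualitySymbol:
    """Decode one Phred+33 quality character."""
    if len(symbol) != 1:
        raise ValueError(f"expected a single character, got {symbol!r}")
    ordinal = ord(symbol)
    if not SYMBOL_MIN <= ordinal <= SYMBOL_MAX:
        raise ValueError(
            f"quality character {symbol!r} (ordinal {ordinal}) outside [33,126]"
        )
    q = ordinal - PHRED_OFFSET
    return QualitySymbol(symbol=symbol, phred=q, error_prob=10.0 ** (-q / 10.0))


def symbol_from_phred(phred: int) -> str:
    """Encode an integer Phred value as its Phred+33 character."""
    if not 0 <= phred <= PHRED_MAX:
        raise ValueError(f"Phred value {phred} outside [0,{PHRED_MAX}]")
    return chr(phred + PHRED_OFFSET)


def theoretical_error_prob(symbol: str) -> float:
    return phred_from_symbol(symbol).error_prob


def chiron_quality(p1: float, p2: float) -> float:
    """Likelihood-ratio quality score ``10 * log10(p1 / p2)``.

    ``p1`` is the probability of the most likely nucleotide and ``p2`` of the
    runner-up, so the score is non-negative and zero only when they tie. The
    score is scale-free: it depends only on the ratio p1/p2.
    """
    if p2 <= 0:
        raise ValueError("p2 must be positive")
    if p1 > 1 or p2 > p1:
        raise ValueError(f"need 0 < p2 <= p1 <= 1, got p1={p1}, p2={p2}")
    return 10.0 * math.log10(p1 / p2)


def scaled_quality(p: float, coeffs: ScalingCoefficients) -> float:
    """Scaled Phred-style score ``-10 * (y * log10(1 - p) + log10(x))``."""
    if p <= 0:
        raise ValueError(f"p must be in (0,1), got {p}")
    if p >= 1:
        raise ValueError("p = 1 gives an infinite score; p must be < 1")
    return -10.0 * (coeffs.y * math.log10(1.0 - p) + math.log10(coeffs.x))


def select_nanonet_coefficients(read_kind: str, p: float) -> ScalingCoefficients:
    """Pick the Nanonet coefficient row for a read category.

    Template reads use one of two rows split at p = 0.1 (the boundary value
    itself goes to the "p <= 0.1" row); complement, 2d and the fallback
    "another" category each have a single row.
    """
    if not 0 < p < 1:
        raise ValueError(f"p must be in (0,1), got {p}")
    if read_kind == "template":
        key = "nanonet_template_high_p" if p > 0.1 else "nanonet_template_low_p"
    elif read_kind == "complement":
        key = "nanonet_complement"
    elif read_kind == "2d":
        key = "nanonet_2d"
    elif read_kind == "another":
        key = "nanonet_another"
    else:
        raise ValueError(f"unknown Nanonet read kind {read_kind!r}")
    return COEFFICIENTS[key]


def round_clamp_phred(score: float) -> int:
    """Round a real-valued score to the nearest integer Phred, clamped to [0,93].

    Basecallers do not document their rounding, so emission of symbols keeps
    this step separate from the score formulas.
    """
    return min(PHRED_MAX, max(0, int(math.floor(score + 0.5))))


def coefficients_table() -> pd.DataFrame:
    """The built-in coefficient sets as a DataFrame (exportable as TSV)."""
    return pd.DataFrame(
        [(c.model_name, c.x, c.y) for c in COEFFICIENTS.values()],
        columns=["model", "x", "y"],
    )
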