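"""Codon-harmonization flags: codons far more frequent in the expression
host than in the source organism.

Rare codons in the native coding sequence can enforce ribosomal pausing
that lets upstream domains fold co-translationally.  A codon whose
relative synonymous frequency in the expression host exceeds its source
frequency by more than a configurable fold (default 5x) loses that pause
in the heterologous host and is a candidate for recoding.  Frequencies
are within-family fractions (relative synonymous codon frequencies), so
single-codon families are never flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .seqio import (
    CODON_TO_AA,
    STOP_CODONS,
    SYNONYMOUS_FAMILIES,
    CodingRecord,
    CodonUsageTable,
)

__all__ = ["CodonFlag", "codon_ratio_table", "flag_fast_codons", "harmonize"]


@dataclass(frozen=True)
class CodonFlag:
    """One over-frequent codon; ``codon_index`` is 1-based and equals the
    amino-acid position."""

    codon_index: int
    codon: str
    ratio: float  # host frequency / source frequency; may be inf


def codon_ratio_table(
    host: CodonUsageTable, source: CodonUsageTable
) -> dict[str, float]:
    """Per-codon host/source frequency ratio.

    Source frequency 0 with host frequency > 0 maps to ``inf`` (always
    flaggable); 0/0 maps to 1 by convention (no evidence either way).
    """
    ratios: dict[str, float] = {}
    for codon, host_freq in host.frequencies.items():
        source_freq = source.frequencies[codon]
        if source_freq == 0.0:
            ratios[codon] = math.inf if host_freq > 0 else 1.0
        else:
            ratios[codon] = host_freq / source_freq
    return ratios


def flag_fast_codons(
    cds: CodingRecord, ratios: dict[str, float], fold: float = 5.0
) -> list[CodonFlag]:
    """Flag every codon position with host/source ratio strictly above
    ``fold``.  A trailing stop codon is ignored; a premature stop is an
    error."""
    flags: list[CodonFlag] = []
    last = len(cds.codons)
    for index, codon in enumerate(cds.codons, start=1):
        if codon in STOP_CODONS:
            if index == last:
                continue
            raise ValueError(f"stop codon {codon} at codon position {index}")
        ratio = ratios[codon]
        if ratio > fold:
            flags.append(CodonFlag(codon_index=index, codon=codon, ratio=ratio))
    return flags


def harmonize(
    cds: CodingRecord,
    host: CodonUsageTable,
    source: CodonUsageTable,
    fold: float = 5.0,
) -> CodingRecord:
    """Suggest a harmonized coding sequence.

    Each flagged codon is replaced by the synonymous codon whose host
    frequency is nearest the original codon's *source* frequency
    (restoring the native pause propensity); ties resolve to the
    alphabetically first codon.  Unflagged codons are untouched.
    """
    ratios = codon_ratio_table(host, source)
    flagged = {flag.codon_index for flag in flag_fast_codons(cds, ratios, fold)}
    new_codons = list(cds.codons)
    for index in flagged:
        codon = cds.codons[index - 1]
        family = SYNONYMOUS_FAMILIES[CODON_TO_AA[codon]]
        target = source.frequencies[codon]
        new_codons[index - 1] = min(
            family, key=lambda c: (abs(host.frequencies[c] - target), c)
        )
    return CodingRecord(id=cds.id, codons=tuple(new_codons))
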