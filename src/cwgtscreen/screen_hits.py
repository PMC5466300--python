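"""Hit identification and screen-level summaries.

A screened sample becomes a hit when its nickel-eluate electrophoresis
trace contains a peak whose apparent molecular weight matches the
construct's expected (tagged) weight within a +/-15% window, boundaries
inclusive.  Peaks passing the follow-up purity/concentration cutoffs
(strictly above 27% purity OR strictly above 70 ug/mL) are carried to
gel + mass-spec confirmation; confirmation itself is an external boolean
input, never computed here.  Summaries reproduce the screen-level
bookkeeping: hit tallies by vector and by host condition, mean yield per
vector floored to integer ug/mL, full-length vs truncated counts, and
the confirmed-hit percentage of all screened samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .library_design import DesignPoint, SelectionConfig
from .seqio import PeakRecord, Table2Hit, Table3Hit

__all__ = [
    "HitRecord",
    "ScreenSummary",
    "match_peaks",
    "apply_cutoffs",
    "call_hits",
    "summarize",
    "hits_from_table2",
    "hits_from_table3",
]


@dataclass(frozen=True)
class HitRecord:
    """A sample whose eluate matched its expected molecular weight."""

    sample: DesignPoint
    matched_peak: Optional[PeakRecord]
    passed_cutoffs: bool
    confirmed: bool  # mass-spec confirmation, supplied externally
    yield_ug_ml: float

    def __post_init__(self) -> None:
        if self.yield_ug_ml < 0:
            raise ValueError("yield must be >= 0")


@dataclass(frozen=True)
class ScreenSummary:
    hits_total: int
    hits_by_vector: dict[str, int]
    hits_by_host: dict[str, int]
    floor_mean_yield_by_vector: dict[str, int]  # ug/mL, floored
    n_full_length: int
    n_truncated: int
    percent_confirmed: float  # of total samples, one decimal


def match_peaks(
    expected_mw: float, peaks: Sequence[PeakRecord], tolerance: float = 0.15
) -> Optional[PeakRecord]:
    """Best peak within ``expected_mw * (1 +/- tolerance)``, or None.

    Boundaries are inclusive.  Among candidates the smallest relative MW
    deviation wins; exact ties go to the higher concentration.
    """
    if expected_mw <= 0:
        raise ValueError("expected_mw must be > 0")
    # epsilon keeps the inclusive boundary robust to float rounding
    eps = 1e-9 * expected_mw
    lo = expected_mw * (1.0 - tolerance) - eps
    hi = expected_mw * (1.0 + tolerance) + eps
    candidates = [p for p in peaks if lo <= p.observed_mw <= hi]
    if not candidates:
        return None
    return min(
        candidates,
        key=lambda p: (abs(p.observed_mw - expected_mw) / expected_mw,
                       -p.concentration),
    )


def apply_cutoffs(
    peak: PeakRecord, purity_cutoff: float = 27.0, conc_cutoff: float = 70.0
) -> bool:
    """True iff purity is strictly above ``purity_cutoff`` OR concentration
    strictly above ``conc_cutoff``."""
    return peak.purity > purity_cutoff or peak.concentration > conc_cutoff


def call_hits(
    samples: Sequence[DesignPoint],
    expected_mws: Mapping[str, float],
    peaks: Iterable[PeakRecord],
    config: Optional[SelectionConfig] = None,
    confirmations: Optional[Mapping[str, bool]] = None,
) -> list[HitRecord]:
    """Identify hits for a screened plate.

    ``expected_mws`` maps sample id -> expected (tagged) MW in kDa;
    ``peaks`` may hold several peaks per sample.  A peak whose sample id
    is not in ``samples`` is an error.  Output order follows ``samples``;
    only matched samples yield a record.
    """
    config = config or SelectionConfig()
    by_sample: dict[str, list[PeakRecord]] = {}
    known = {s.sample_id for s in samples}
    for peak in peaks:
        if peak.sample_id not in known:
            raise ValueError(f"peak for unknown sample {peak.sample_id!r}")
        by_sample.setdefault(peak.sample_id, []).append(peak)

    hits: list[HitRecord] = []
    for sample in samples:
        sample_peaks = by_sample.get(sample.sample_id, [])
        if not sample_peaks:
            continue
        expected = expected_mws[sample.sample_id]
        peak = match_peaks(expected, sample_peaks, config.mw_tolerance)
        if peak is None:
            continue
        hits.append(
            HitRecord(
                sample=sample,
                matched_peak=peak,
                passed_cutoffs=apply_cutoffs(
                    peak, config.purity_cutoff, config.conc_cutoff
                ),
                confirmed=bool(confirmations.get(sample.sample_id, False))
                if confirmations
                else False,
                yield_ug_ml=peak.concentration,
            )
        )
    return hits


def summarize(hits: Sequence[HitRecord], total_samples: int) -> ScreenSummary:
    """Screen-level tallies over a hit list (callers decide whether to pass
    all matched samples or the confirmed subset)."""
    if total_samples < len(hits):
        raise ValueError("total_samples smaller than the number of hits")
    by_vector: dict[str, int] = {}
    by_host: dict[str, int] = {}
    yields_by_vector: dict[str, list[float]] = {}
    n_full = 0
    for hit in hits:
        vec, host = hit.sample.vector, hit.sample.host
        by_vector[vec] = by_vector.get(vec, 0) + 1
        by_host[host] = by_host.get(host, 0) + 1
        yields_by_vector.setdefault(vec, []).append(hit.yield_ug_ml)
        if hit.sample.construct.is_full_length:
            n_full += 1
    floor_means = {
        vec: math.floor(sum(values) / len(values))
        for vec, values in yields_by_vector.items()
    }
    percent = round(100.0 * len(hits) / total_samples, 1) if total_samples else 0.0
    return ScreenSummary(
        hits_total=len(hits),
        hits_by_vector=by_vector,
        hits_by_host=by_host,
        floor_mean_yield_by_vector=floor_means,
        n_full_length=n_full,
        n_truncated=len(hits) - n_full,
        percent_confirmed=percent,
    )


# ---------------------------------------------------------------------------
# Adapters for the packaged screening-table transcriptions
# ---------------------------------------------------------------------------

def hits_from_table2(rows: Sequence[Table2Hit]) -> list[HitRecord]:
    """Confirmed test-library hits as :class:`HitRecord` objects (the
    transcription carries no peak data, so ``matched_peak`` is None)."""
    from .library_design import Construct, parse_label

    hits = []
    for index, row in enumerate(rows, start=1):
        sample = DesignPoint(
            sample_id=f"T2-{index:02d}",
            construct=Construct(
                parent_id=row.protein, deletions=parse_label(row.construct)
            ),
            vector=row.vector,
            host=row.chaperones,
        )
        hits.append(
            HitRecord(
                sample=sample,
                matched_peak=None,
                passed_cutoffs=True,
                confirmed=True,
                yield_ug_ml=row.yield_ug_ml,
            )
        )
    return hits


def hits_from_table3(rows: Sequence[Table3Hit]) -> list[HitRecord]:
    """Confirmed crop-library hits as :class:`HitRecord` objects.  The
    transcription does not record vectors (all cytoplasmic hits came from
    the same vector), so a single placeholder vector groups the yields."""
    from .library_design import Construct, parse_label

    hits = []
    for row in rows:
        sample = DesignPoint(
            sample_id=row.id,
            construct=Construct(
                parent_id=row.protein, deletions=parse_label(row.construct)
            ),
            vector="pET55dest",
            host="none",
        )
        hits.append(
            HitRecord(
                sample=sample,
                matched_peak=None,
                passed_cutoffs=True,
                confirmed=True,
                yield_ug_ml=row.yield_ug_ml,
            )
        )
    return hits
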