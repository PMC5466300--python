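"""Deterministic synthetic data: proteins with planted features, and
screening plates with planted hits.

Every stage of the pipeline is testable offline against ground truth
generated here.  All randomness flows from explicit integer seeds
(``numpy.random.default_rng``); the same spec always yields the same
sequence or plate.

The protein generator plants exactly the requested features and nothing
else: background residues are drawn from a hydrophilic, order-promoting
alphabet (Trp/Tyr enriched; no A/C/I/L/V/F/M/P) whose windowed
Kyte-Doolittle mean stays far below the TM threshold and whose TOP-IDP
mean stays below zero, so un-planted regions trigger neither segment
predictor.  Accidental sequons arising from random draws are destroyed by
editing their Ser/Thr position to Ala, which cannot create a new sequon
or break a planted one.  These biases make the generator's sequences
compositionally unlike real proteins; they are scaffolds for exercising
the predictors' contracts, not evolutionary simulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .library_design import DesignPoint
from .seqfeatures import Segment
from .seqio import PeakRecord, ProteinRecord

__all__ = ["PlantSpec", "PlateSpec", "make_protein", "make_plate"]

# Hydrophilic AND order-promoting background; W/Y enriched to keep the
# windowed TOP-IDP mean negative (see module docstring).
_BACKGROUND = "DENQGSTKRH" + "WWWWWW" + "YYYYYY"

_SEQUON_THIRD = "ST"


@dataclass(frozen=True)
class PlantSpec:
    """Recipe for one synthetic protein with planted features."""

    seed: int
    length: int
    tm_interval: Optional[tuple[int, int]] = None  # 1-based inclusive
    sequon_positions: tuple[int, ...] = ()
    cysteine_count: int = 0
    disordered_tail_len: Optional[int] = None


@dataclass(frozen=True)
class PlateSpec:
    """Recipe for one synthetic screening plate.

    Planted hit samples receive a peak at their expected MW times
    ``1 + eta`` with ``eta ~ Normal(0, mw_noise_sd)`` truncated to the
    match tolerance, plus hit-grade purity and concentration; decoys
    receive a peak offset beyond the tolerance with sub-cutoff purity
    and concentration, so planted truth is exactly recoverable.
    """

    seed: int
    planted: tuple[str, ...] = ()  # sample ids
    mw_noise_sd: float = 0.03
    tolerance: float = 0.15
    decoy_mw_offset: float = 0.30  # fraction; must exceed tolerance
    hit_purity: tuple[float, float] = (35.0, 95.0)
    hit_concentration: tuple[float, float] = (80.0, 300.0)
    decoy_purity: tuple[float, float] = (1.0, 20.0)
    decoy_concentration: tuple[float, float] = (1.0, 50.0)

    def __post_init__(self) -> None:
        if self.decoy_mw_offset <= self.tolerance:
            raise ValueError("decoy_mw_offset must exceed the match tolerance")
        if self.hit_purity[0] <= 27.0 and self.hit_concentration[0] <= 70.0:
            raise ValueError(
                "hit purity or concentration range must clear the cutoffs"
            )


def _check_feasible(spec: PlantSpec) -> None:
    occupied: set[int] = set()

    def claim(positions, what: str) -> None:
        for pos in positions:
            if not 1 <= pos <= spec.length:
                raise ValueError(f"{what} position {pos} outside 1..{spec.length}")
            if pos in occupied:
                raise ValueError(f"{what} overlaps another planted feature at {pos}")
            occupied.add(pos)

    if spec.tm_interval is not None:
        start, end = spec.tm_interval
        if start > end:
            raise ValueError("empty tm_interval")
        claim(range(start, end + 1), "tm_interval")
    tail_start = None
    if spec.disordered_tail_len is not None:
        if spec.disordered_tail_len < 1:
            raise ValueError("disordered_tail_len must be >= 1")
        tail_start = spec.length - spec.disordered_tail_len + 1
        claim(range(tail_start, spec.length + 1), "disordered tail")
    for pos in spec.sequon_positions:
        claim(range(pos, pos + 3), f"sequon at {pos}")
    if spec.cysteine_count < 0:
        raise ValueError("cysteine_count must be >= 0")
    if spec.cysteine_count and spec.length - len(occupied) < spec.cysteine_count * 8:
        raise ValueError("not enough free positions for the requested cysteines")


def make_protein(spec: PlantSpec) -> ProteinRecord:
    """Generate the synthetic protein described by ``spec``.

    Guarantees: ``scan_sequons`` returns exactly ``spec.sequon_positions``;
    ``count_cysteines`` returns exactly ``spec.cysteine_count``; a planted
    hydrophobic block occupies ``tm_interval``; a P/E/S/Q-rich tail of
    ``disordered_tail_len`` residues ends the sequence.  Same seed, same
    sequence.
    """
    _check_feasible(spec)
    rng = np.random.default_rng(spec.seed)
    residues = [str(rng.choice(list(_BACKGROUND))) for _ in range(spec.length)]
    reserved: set[int] = set()  # 0-based indices that later passes must not edit

    if spec.tm_interval is not None:
        start, end = spec.tm_interval
        for i in range(start - 1, end):
            residues[i] = str(rng.choice(list("ILVF")))
            reserved.add(i)

    tail_start_idx = None
    if spec.disordered_tail_len is not None:
        tail_start_idx = spec.length - spec.disordered_tail_len
        pattern = "PESQ"
        for offset, i in enumerate(range(tail_start_idx, spec.length)):
            residues[i] = pattern[offset % 4]
            reserved.add(i)

    for pos in spec.sequon_positions:
        i = pos - 1
        residues[i] = "N"
        # X position: anything but P (or N/C, which could seed side effects)
        residues[i + 1] = str(rng.choice(list("GQESTDKRH")))
        residues[i + 2] = str(rng.choice(list(_SEQUON_THIRD)))
        reserved.update((i, i + 1, i + 2))

    if spec.cysteine_count:
        free = [i for i in range(spec.length) if i not in reserved]
        # spacing >= 8 keeps Cys hydropathy contributions dispersed; try a
        # random greedy placement, fall back to a left-to-right scan
        chosen: list[int] = []
        for i in rng.permutation(free):
            if all(abs(i - c) >= 8 for c in chosen):
                chosen.append(int(i))
            if len(chosen) == spec.cysteine_count:
                break
        if len(chosen) < spec.cysteine_count:
            chosen = []
            for i in free:
                if all(abs(i - c) >= 8 for c in chosen):
                    chosen.append(i)
                if len(chosen) == spec.cysteine_count:
                    break
        if len(chosen) < spec.cysteine_count:
            raise ValueError("could not place cysteines with required spacing")
        for i in chosen:
            residues[i] = "C"
            reserved.add(i)

    planted = set(spec.sequon_positions)
    # destroy accidental sequons (edit S/T of the motif to A)
    for _ in range(spec.length):
        dirty = False
        for i in range(spec.length - 2):
            if (
                residues[i] == "N"
                and residues[i + 1] != "P"
                and residues[i + 2] in _SEQUON_THIRD
                and (i + 1) not in planted
            ):
                residues[i + 2] = "A"
                dirty = True
        if not dirty:
            break

    return ProteinRecord(id=f"syn{spec.seed}", residues="".join(residues))


def make_plate(
    spec: PlateSpec,
    samples: Sequence[DesignPoint],
    expected_mws: Mapping[str, float],
) -> tuple[list[PeakRecord], dict[str, bool]]:
    """Generate one plate's peak table plus per-sample truth labels."""
    sample_ids = {s.sample_id for s in samples}
    stray = set(spec.planted) - sample_ids
    if stray:
        raise ValueError(f"planted samples not on the plate: {sorted(stray)}")
    rng = np.random.default_rng(spec.seed)
    planted = set(spec.planted)
    peaks: list[PeakRecord] = []
    truth: dict[str, bool] = {}
    for sample in samples:
        expected = expected_mws[sample.sample_id]
        is_hit = sample.sample_id in planted
        truth[sample.sample_id] = is_hit
        if is_hit:
            eta = rng.normal(0.0, spec.mw_noise_sd)
            while abs(eta) > spec.tolerance:
                eta = rng.normal(0.0, spec.mw_noise_sd)
            purity = rng.uniform(*spec.hit_purity)
            conc = rng.uniform(*spec.hit_concentration)
            peaks.append(
                PeakRecord(
                    sample_id=sample.sample_id,
                    observed_mw=expected * (1.0 + eta),
                    concentration=conc,
                    purity=purity,
                )
            )
        else:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            offset = sign * (spec.decoy_mw_offset + rng.uniform(0.0, 0.2))
            observed = expected * (1.0 + offset)
            peaks.append(
                PeakRecord(
                    sample_id=sample.sample_id,
                    observed_mw=max(observed, 0.5),
                    concentration=rng.uniform(*spec.decoy_concentration),
                    purity=rng.uniform(*spec.decoy_purity),
                )
            )
    return peaks, truth
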