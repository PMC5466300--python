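"""Per-sequence annotations consumed by target selection and construct design.

For every candidate protein the pipeline needs: the putative
N-glycosylation sites (sequons, N-X-S/T with X != P), the cysteine count,
a transmembrane-segment call (type II membrane anchors motivate N-terminal
truncation constructs), a disordered C-terminus call (motivating C-terminal
trimming), and the expected molecular weight of the expressed product
(matched against electrophoresis peaks at hit-calling time).

TM and disorder calls are deterministic sliding-window predictors built on
published per-residue propensity scales: Kyte & Doolittle (1982) hydropathy
for membrane segments, and the TOP-IDP disorder propensity scale of
Campen et al. (2008).  They are self-contained desk-scale predictors, with
windows and thresholds exposed in the selection configuration.

Coordinates are 1-based and inclusive throughout, matching the
"Δ1–50"-style construct notation used in screening tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from Bio.Data.IUPACData import protein_weights as _AA_WEIGHTS

from .seqio import ProteinRecord

__all__ = [
    "KYTE_DOOLITTLE",
    "TOP_IDP",
    "WATER_MASS_DA",
    "Segment",
    "FeatureSummary",
    "scan_sequons",
    "count_cysteines",
    "hydropathy_profile",
    "predict_tm_segments",
    "disorder_profile",
    "predict_disordered_cterm",
    "molecular_weight",
    "annotate",
    "write_annotation_table",
    "read_annotation_table",
]

#: Kyte & Doolittle (1982) hydropathy scale; X scored neutral.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0,
}

#: TOP-IDP disorder propensity (Campen et al. 2008); positive values are
#: disorder-promoting, negative order-promoting.  X scored neutral.
TOP_IDP: dict[str, float] = {
    "W": -0.884, "F": -0.697, "Y": -0.510, "I": -0.486, "M": -0.397,
    "L": -0.326, "V": -0.121, "N": 0.007, "C": 0.020, "T": 0.059,
    "A": 0.060, "G": 0.166, "R": 0.180, "D": 0.192, "H": 0.303,
    "Q": 0.318, "S": 0.341, "K": 0.586, "E": 0.736, "P": 0.987,
    "X": 0.0,
}

#: Average mass of one water molecule, Da (added once per peptide chain).
WATER_MASS_DA = 18.0153

# Average residue contribution = free amino acid mass - one water.
_RESIDUE_MASS = {aa: m - WATER_MASS_DA for aa, m in _AA_WEIGHTS.items()}
# X gets the unweighted mean of the 20 standard residue masses.
_RESIDUE_MASS["X"] = sum(_RESIDUE_MASS.values()) / len(_RESIDUE_MASS)


@dataclass(frozen=True, order=True)
class Segment:
    """A 1-based inclusive residue interval carrying a feature kind."""

    start: int
    end: int
    kind: str = "TM"  # "TM" or "DISORDER"
    score: float = 0.0  # mean window score over the segment's run

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid segment {self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "Segment") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass(frozen=True)
class FeatureSummary:
    """Everything selection and construct design need to know about one
    protein: sequon positions, cysteine count, TM segments, a possible
    disordered C-terminus, and the expected (tagged) molecular weight."""

    sequon_positions: tuple[int, ...]
    cysteine_count: int
    tm_segments: tuple[Segment, ...]
    disordered_cterm: Optional[Segment]
    expected_mw: float  # kDa

    @property
    def n_sequons(self) -> int:
        return len(self.sequon_positions)


# ---------------------------------------------------------------------------
# Simple scans
# ---------------------------------------------------------------------------

def scan_sequons(seq: ProteinRecord) -> list[int]:
    """1-based positions of every sequon Asn (N-X-S/T, X != P).

    Overlapping sequons are each reported.
    """
    residues = seq.residues
    hits = []
    for i in range(len(residues) - 2):
        if residues[i] == "N" and residues[i + 1] != "P" and residues[i + 2] in "ST":
            hits.append(i + 1)
    return hits


def count_cysteines(seq: ProteinRecord) -> int:
    return seq.residues.count("C")


# ---------------------------------------------------------------------------
# Windowed profiles and segment calls
# ---------------------------------------------------------------------------

def _windowed_profile(
    residues: str, scale: dict[str, float], window: int
) -> dict[int, float]:
    """Mean scale value over the window centred at each position whose full
    window fits; keys are 1-based centre positions."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd")
    if window > len(residues):
        raise ValueError(
            f"window {window} longer than sequence ({len(residues)} residues)"
        )
    half = window // 2
    values = [scale[aa] for aa in residues]
    profile: dict[int, float] = {}
    acc = sum(values[:window])
    profile[half + 1] = acc / window
    for centre in range(half + 2, len(residues) - half + 1):
        acc += values[centre + half - 1] - values[centre - half - 2]
        profile[centre] = acc / window
    return profile


def hydropathy_profile(seq: ProteinRecord, window: int = 19) -> dict[int, float]:
    """Kyte-Doolittle windowed-mean hydropathy, 1-based centre positions."""
    return _windowed_profile(seq.residues, KYTE_DOOLITTLE, window)


def disorder_profile(seq: ProteinRecord, window: int = 21) -> dict[int, float]:
    """TOP-IDP windowed-mean disorder propensity, 1-based centre positions."""
    return _windowed_profile(seq.residues, TOP_IDP, window)


def _runs_at_or_above(
    profile: dict[int, float], threshold: float
) -> list[tuple[int, int, float]]:
    """Maximal runs of consecutive centre positions with score >= threshold,
    as (first_centre, last_centre, mean_score) triples."""
    runs = []
    positions = sorted(profile)
    start = None
    acc = 0.0
    for pos in positions:
        if profile[pos] >= threshold:
            if start is None:
                start, acc = pos, 0.0
            acc += profile[pos]
        elif start is not None:
            runs.append((start, pos - 1, acc / (pos - start)))
            start = None
    if start is not None:
        last = positions[-1]
        runs.append((start, last, acc / (last - start + 1)))
    return runs


def predict_tm_segments(
    seq: ProteinRecord,
    window: int = 19,
    threshold: float = 1.6,
    min_len: int = 15,
) -> list[Segment]:
    """Hydropathy-based transmembrane segment call.

    Maximal runs of window centres scoring at least ``threshold`` and at
    least ``min_len`` centres long are reported, each extended by half a
    window on both sides (clipped to the sequence) so the segment covers
    the residues that produced the signal.
    """
    profile = hydropathy_profile(seq, window)
    half = window // 2
    segments = []
    for first, last, mean_score in _runs_at_or_above(profile, threshold):
        if last - first + 1 < min_len:
            continue
        segments.append(
            Segment(
                start=max(1, first - half),
                end=min(len(seq.residues), last + half),
                kind="TM",
                score=mean_score,
            )
        )
    return segments


def predict_disordered_cterm(
    seq: ProteinRecord,
    window: int = 21,
    threshold: float = 0.0,
    min_len: int = 30,
) -> Optional[Segment]:
    """Disordered C-terminal segment, or None.

    Reported iff the terminal maximal run of disorder-positive window
    centres reaches the last scored position and spans at least
    ``min_len`` centres; the segment is extended to the true C-terminus.
    """
    if window > len(seq.residues):
        return None
    profile = disorder_profile(seq, window)
    runs = _runs_at_or_above(profile, threshold)
    if not runs:
        return None
    first, last, mean_score = runs[-1]
    if last != max(profile):  # run must reach the C-terminal scored position
        return None
    if last - first + 1 < min_len:
        return None
    half = window // 2
    return Segment(
        start=max(1, first - half),
        end=len(seq.residues),
        kind="DISORDER",
        score=mean_score,
    )


# ---------------------------------------------------------------------------
# Molecular weight
# ---------------------------------------------------------------------------

def molecular_weight(seq: ProteinRecord, tag_mass: float = 0.0) -> float:
    """Expected average molecular weight in kDa.

    Sum of average residue masses plus one water, plus ``tag_mass`` (Da)
    for any purification/fusion tag.  Average (not monoisotopic) masses,
    since the quantity is matched against electrophoretic estimates.
    """
    total = sum(_RESIDUE_MASS[aa] for aa in seq.residues) + WATER_MASS_DA + tag_mass
    return total / 1000.0


# ---------------------------------------------------------------------------
# Summary and report I/O
# ---------------------------------------------------------------------------

def annotate(
    seq: ProteinRecord,
    tag_mass: float = 0.0,
    tm_window: int = 19,
    tm_threshold: float = 1.6,
    tm_min_len: int = 15,
    disorder_window: int = 21,
    disorder_threshold: float = 0.0,
    disorder_min_len: int = 30,
) -> FeatureSummary:
    """Compute the full :class:`FeatureSummary` for one protein."""
    return FeatureSummary(
        sequon_positions=tuple(scan_sequons(seq)),
        cysteine_count=count_cysteines(seq),
        tm_segments=tuple(
            predict_tm_segments(seq, tm_window, tm_threshold, tm_min_len)
        )
        if tm_window <= len(seq.residues)
        else (),
        disordered_cterm=predict_disordered_cterm(
            seq, disorder_window, disorder_threshold, disorder_min_len
        ),
        expected_mw=molecular_weight(seq, tag_mass),
    )


def write_annotation_table(
    annotations: dict[str, FeatureSummary], path
) -> None:
    """Per-protein TSV report: id, sequon count, cysteine count, TM
    segments ("start-end;..."), disordered C-terminus, expected MW."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "id\tn_sequons\tn_cys\ttm_segments\tdisordered_cterm\texpected_mw_kda\n"
        )
        for pid, summ in annotations.items():
            tm = ";".join(f"{s.start}-{s.end}" for s in summ.tm_segments)
            dis = (
                f"{summ.disordered_cterm.start}-{summ.disordered_cterm.end}"
                if summ.disordered_cterm
                else ""
            )
            fh.write(
                f"{pid}\t{summ.n_sequons}\t{summ.cysteine_count}\t{tm}\t{dis}\t"
                f"{summ.expected_mw:.4f}\n"
            )


def read_annotation_table(path) -> dict[str, FeatureSummary]:
    """Inverse of :func:`write_annotation_table` (sequon positions are not
    round-tripped; only the count is preserved, as position placeholders)."""
    annotations: dict[str, FeatureSummary] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = [
            "id", "n_sequons", "n_cys", "tm_segments", "disordered_cterm",
            "expected_mw_kda",
        ]
        if header != expected:
            raise ValueError(f"unexpected annotation header {header}")
        for line in fh:
            pid, n_seq, n_cys, tm, dis, mw = line.rstrip("\n").split("\t")
            tm_segments = tuple(
                Segment(int(a), int(b), "TM")
                for a, b in (part.split("-") for part in tm.split(";") if part)
            )
            dis_seg = None
            if dis:
                a, b = dis.split("-")
                dis_seg = Segment(int(a), int(b), "DISORDER")
            annotations[pid] = FeatureSummary(
                sequon_positions=tuple(range(1, int(n_seq) + 1)),
                cysteine_count=int(n_cys),
                tm_segments=tm_segments,
                disordered_cterm=dis_seg,
                expected_mw=float(mw),
            )
    return annotations
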