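"""Library selection, truncation-construct design and design-matrix
enumeration.

Within each phylogenetic bin, candidates with expression evidence are
ranked by ascending sequon count then ascending cysteine count (fewer
unsatisfiable glycosylation sites and fewer potential aberrant disulfides
make soluble bacterial expression more likely), and the library is filled
greedily across bins while favouring organisms not yet represented.  For
every selected protein, a full-length construct is always emitted; an
N-terminal truncation is added when a transmembrane segment sits near the
N-terminus (a type II membrane anchor), and C-terminally trimmed variants
when a disordered C-terminus was predicted.  The experimental design is
the full cross product construct x expression vector x host condition.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import yaml

from .seqfeatures import FeatureSummary, Segment, molecular_weight
from .seqio import ProteinRecord

__all__ = [
    "Candidate",
    "Construct",
    "DesignPoint",
    "SelectionConfig",
    "FULL_LENGTH_LABEL",
    "format_label",
    "parse_label",
    "rank_bin",
    "assemble_library",
    "LibrarySelection",
    "design_constructs",
    "enumerate_design",
]

FULL_LENGTH_LABEL = "full-length"

# Label grammar matches the screening-table typography: Greek delta,
# en-dash interval, " and " conjunction.
_DELETION_RE = re.compile(r"^Δ(\d+)[–-](\d+)$")


def format_label(deletions: Sequence[tuple[int, int]]) -> str:
    """Deterministic construct label: ``full-length``, ``Δ1–50``,
    ``Δ1–91 and Δ393–457`` ..."""
    if not deletions:
        return FULL_LENGTH_LABEL
    return " and ".join(f"Δ{start}–{end}" for start, end in deletions)


def parse_label(label: str) -> tuple[tuple[int, int], ...]:
    """Inverse of :func:`format_label` (ASCII hyphen accepted)."""
    label = label.strip()
    if label == FULL_LENGTH_LABEL:
        return ()
    deletions = []
    for part in label.split(" and "):
        match = _DELETION_RE.match(part.strip())
        if not match:
            raise ValueError(f"unparseable construct label {label!r}")
        deletions.append((int(match.group(1)), int(match.group(2))))
    return tuple(deletions)


@dataclass(frozen=True)
class Construct:
    """A parent protein with zero or more deleted intervals.

    ``deletions`` are 1-based inclusive, sorted, non-overlapping.
    ``expected_mw`` (kDa, tag included) is None for constructs built from
    table transcriptions where the parent sequence is not available.
    """

    parent_id: str
    deletions: tuple[tuple[int, int], ...] = ()
    expected_mw: Optional[float] = None

    def __post_init__(self) -> None:
        prev_end = 0
        for start, end in self.deletions:
            if start <= prev_end:
                raise ValueError(
                    f"{self.parent_id}: deletions must be sorted and non-overlapping"
                )
            if start > end:
                raise ValueError(f"{self.parent_id}: empty deletion {start}-{end}")
            prev_end = end

    @property
    def label(self) -> str:
        return format_label(self.deletions)

    @property
    def is_full_length(self) -> bool:
        return not self.deletions

    def retained_residues(self, parent: ProteinRecord) -> str:
        """The expressed amino-acid sequence after applying the deletions."""
        keep = []
        deleted = set()
        for start, end in self.deletions:
            if end > len(parent.residues):
                raise ValueError(
                    f"{self.parent_id}: deletion {start}-{end} exceeds parent "
                    f"length {len(parent.residues)}"
                )
            deleted.update(range(start, end + 1))
        for pos, aa in enumerate(parent.residues, start=1):
            if pos not in deleted:
                keep.append(aa)
        if not keep:
            raise ValueError(f"{self.parent_id}: deletions span the entire protein")
        return "".join(keep)


@dataclass(frozen=True)
class DesignPoint:
    """One expression sample: construct x vector x host condition."""

    sample_id: str
    construct: Construct
    vector: str
    host: str


@dataclass(frozen=True)
class Candidate:
    """A culled subject annotated with features, expression evidence
    (EST/mRNA/cDNA support) and its phylogenetic bin."""

    protein: ProteinRecord
    features: FeatureSummary
    evidence: bool
    bin: int


@dataclass
class SelectionConfig:
    """Every numeric knob of the pipeline in one place.

    Defaults are the published operating points of the screen: the 40%
    identity floor and 85-115% length window for culling, ten
    phylogenetic bins, a +/-15% molecular-weight match window, purity/
    concentration cutoffs of 27% and 70 ug/mL, and a 5-fold threshold
    for over-frequent host codons.  TM/disorder predictor settings are
    conventional sliding-window values.
    """

    min_identity: float = 0.40
    min_len_ratio: float = 0.85
    max_len_ratio: float = 1.15
    k_bins: int = 10
    per_bin: int = 1
    mw_tolerance: float = 0.15
    purity_cutoff: float = 27.0  # percent
    conc_cutoff: float = 70.0  # ug/mL
    codon_fold: float = 5.0
    tm_window: int = 19
    tm_threshold: float = 1.6
    tm_min_len: int = 15
    tm_start_max: int = 40  # TM must start by this residue to trigger truncation
    disorder_window: int = 21
    disorder_threshold: float = 0.0
    disorder_min_len: int = 30
    stalk_offset: int = 0
    tag_mass: float = 0.0  # Da

    def __post_init__(self) -> None:
        if not 0 < self.min_len_ratio <= self.max_len_ratio:
            raise ValueError("length window fractions must be ordered and positive")
        for name in (
            "min_identity", "k_bins", "per_bin", "mw_tolerance",
            "purity_cutoff", "conc_cutoff", "codon_fold", "tm_window",
            "disorder_window",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "SelectionConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Ranking and library assembly
# ---------------------------------------------------------------------------

def rank_bin(candidates: Sequence[Candidate]) -> list[Candidate]:
    """Order one bin's candidates for selection.

    Candidates without expression evidence are dropped; the rest sort by
    (sequon count, cysteine count, id) ascending — the id tie-break makes
    the order total and the ranking stable.
    """
    eligible = [c for c in candidates if c.evidence]
    return sorted(
        eligible,
        key=lambda c: (c.features.n_sequons, c.features.cysteine_count, c.protein.id),
    )


@dataclass(frozen=True)
class LibrarySelection:
    selected: tuple[Candidate, ...]
    empty_bins: tuple[int, ...]  # bins with no eligible candidate


def assemble_library(
    bins: dict[str, int],
    candidates: Sequence[Candidate],
    per_bin: int = 1,
) -> LibrarySelection:
    """Greedy library selection across bins.

    Bins are visited in index order; each contributes up to ``per_bin``
    candidates in rank order, except that a candidate whose organism is
    already represented in the library is passed over while the bin still
    holds an eligible candidate from an unrepresented organism (maximising
    organism coverage).  Bins with no eligible candidate are reported.
    """
    if per_bin < 1:
        raise ValueError("per_bin must be >= 1")
    by_bin: dict[int, list[Candidate]] = {}
    for cand in candidates:
        by_bin.setdefault(cand.bin, []).append(cand)
    selected: list[Candidate] = []
    represented: set[str] = set()
    empty: list[int] = []
    for bin_index in sorted(set(bins.values())):
        ranked = rank_bin(by_bin.get(bin_index, []))
        if not ranked:
            empty.append(bin_index)
            continue
        chosen: list[Candidate] = []
        pool = list(ranked)
        while pool and len(chosen) < per_bin:
            fresh = next(
                (c for c in pool if c.protein.organism not in represented), None
            )
            pick = fresh if fresh is not None else pool[0]
            pool.remove(pick)
            chosen.append(pick)
            represented.add(pick.protein.organism)
        selected.extend(chosen)
    return LibrarySelection(selected=tuple(selected), empty_bins=tuple(empty))


# ---------------------------------------------------------------------------
# Construct design
# ---------------------------------------------------------------------------

def design_constructs(
    protein: ProteinRecord,
    features: FeatureSummary,
    stalk_offset: int = 0,
    tag_mass: float = 0.0,
    tm_start_max: int = 40,
) -> list[Construct]:
    """Truncation constructs for one protein.

    Always emits the full-length construct.  If a predicted TM segment
    starts at or before residue ``tm_start_max`` (an N-terminal type II
    anchor), adds the N-terminal truncation Δ1–(tm_end + stalk_offset).
    If a disordered C-terminus was predicted, each N-terminally truncated
    variant is additionally emitted with that segment deleted as well.
    Expected masses are recomputed per construct from the retained
    residues plus the tag.
    """

    def build(deletions: tuple[tuple[int, int], ...]) -> Construct:
        construct = Construct(parent_id=protein.id, deletions=deletions)
        retained = construct.retained_residues(protein)  # validates bounds
        mw = molecular_weight(
            ProteinRecord(id=protein.id, residues=retained), tag_mass=tag_mass
        )
        return replace(construct, expected_mw=mw)

    constructs = [build(())]
    anchor = next(
        (seg for seg in features.tm_segments if seg.start <= tm_start_max), None
    )
    n_variants: list[tuple[tuple[int, int], ...]] = []
    if anchor is not None:
        cut_end = min(anchor.end + stalk_offset, len(protein.residues))
        n_variants.append(((1, cut_end),))
    for deletions in n_variants:
        constructs.append(build(deletions))
    tail = features.disordered_cterm
    if tail is not None:
        for deletions in n_variants:
            if any(start <= tail.end and tail.start <= end for start, end in deletions):
                continue  # overlapping deletions would be ill-formed
            constructs.append(build(deletions + ((tail.start, tail.end),)))
    return constructs


# ---------------------------------------------------------------------------
# Design-matrix enumeration
# ---------------------------------------------------------------------------

def enumerate_design(
    constructs: Sequence[Construct],
    vectors: Sequence[str],
    hosts: Sequence[str],
) -> list[DesignPoint]:
    """Full cross product construct x vector x host, in deterministic
    (construct, vector, host) order; sample ids are S0001, S0002, ..."""
    if not constructs or not vectors or not hosts:
        raise ValueError("constructs, vectors and hosts must all be non-empty")
    points = []
    for index, (construct, vector, host) in enumerate(
        itertools.product(constructs, vectors, hosts), start=1
    ):
        points.append(
            DesignPoint(
                sample_id=f"S{index:04d}",
                construct=construct,
                vector=vector,
                host=host,
            )
        )
    return points
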