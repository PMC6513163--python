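"""Split proteins into candidate functional regions by annotation consensus.

Region boundaries are assigned exclusively by annotation type in a fixed
order of precedence — Domain; Family and Homologous superfamily;
Unintegrated signatures; Transmembrane; Non-transmembrane; Disorder — with
signal peptides always kept as regions whenever present, and all Repeat and
Site annotations excluded from boundary building.  Overlapping intervals of
the same tier are union-merged; lower tiers may only claim residues not
already claimed.  Residues claimed by no tier become Unassigned regions,
subject to two length rules tuned to signal-peptide and linker length
distributions:

* terminal Unassigned regions shorter than 18 residues are merged into the
  neighbouring region (longer ones stay separate);
* interior Unassigned regions shorter than 20 residues are discarded
  outright, leaving a residue gap that belongs to no region.

A protein with no usable annotations is a single Unassigned region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from .io_formats import EntryType, FeatureAnnotation, ProteinSequence

logger = logging.getLogger(__name__)

#: Minimum length for a terminal Unassigned region to stand on its own.
MIN_TERMINAL_LENGTH = 18
#: Minimum length for an interior Unassigned region to survive at all.
MIN_INTERDOMAIN_LENGTH = 20

#: Boundary-building precedence, highest first (signal peptide handled
#: separately: always claimed, before every tier).
PRECEDENCE_TIERS: tuple[tuple[EntryType, ...], ...] = (
    (EntryType.DOMAIN,),
    (EntryType.FAMILY, EntryType.HOMOLOGOUS_SUPERFAMILY),
    (EntryType.UNINTEGRATED_SIGNATURE,),
    (EntryType.TRANSMEMBRANE,),
    (EntryType.NON_TRANSMEMBRANE,),
    (EntryType.DISORDER,),
)

#: Annotation types that never shape boundaries.
EXCLUDED_FROM_BOUNDARIES = frozenset({EntryType.REPEAT, EntryType.SITE})


class OriginType(str, Enum):
    """Which precedence tier created a region."""

    SIGNAL_PEPTIDE = "SignalPeptide"
    DOMAIN = "Domain"
    FAMILY_SUPERFAMILY = "FamilySuperfamily"
    UNINTEGRATED_SIGNATURE = "UnintegratedSignature"
    TRANSMEMBRANE = "Transmembrane"
    NON_TRANSMEMBRANE = "NonTransmembrane"
    DISORDER = "Disorder"
    UNASSIGNED = "Unassigned"


_TIER_ORIGIN = {
    (EntryType.DOMAIN,): OriginType.DOMAIN,
    (EntryType.FAMILY, EntryType.HOMOLOGOUS_SUPERFAMILY): OriginType.FAMILY_SUPERFAMILY,
    (EntryType.UNINTEGRATED_SIGNATURE,): OriginType.UNINTEGRATED_SIGNATURE,
    (EntryType.TRANSMEMBRANE,): OriginType.TRANSMEMBRANE,
    (EntryType.NON_TRANSMEMBRANE,): OriginType.NON_TRANSMEMBRANE,
    (EntryType.DISORDER,): OriginType.DISORDER,
}


@dataclass
class Region:
    """A continuous sub-sequence of a protein; the unit of prediction."""

    protein_accession: str
    index: int
    start: int
    end: int
    origin_type: OriginType
    features: tuple[FeatureAnnotation, ...] = ()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region {self.start}..{self.end} inverted")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def region_id(self) -> str:
        return f"{self.protein_accession}:{self.index}"


@dataclass
class RegionSet:
    """The ordered, non-overlapping regions of one protein."""

    protein: ProteinSequence
    regions: list[Region] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev_end = 0
        for r in self.regions:
            if r.start <= prev_end:
                raise ValueError(
                    f"{self.protein.accession}: regions overlap or are unsorted"
                )
            if r.end > self.protein.length:
                raise ValueError(
                    f"{self.protein.accession}: region exceeds protein length"
                )
            prev_end = r.end

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    @property
    def covered_residues(self) -> int:
        return sum(r.length for r in self.regions)


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union-merge overlapping closed intervals (touching ones stay apart)."""
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [intervals[0]]
    for s, e in intervals[1:]:
        ls, le = merged[-1]
        if s <= le:
            merged[-1] = (ls, max(le, e))
        else:
            merged.append((s, e))
    return merged


def _clip_to_unclaimed(
    intervals: list[tuple[int, int]], claimed: list[bool]
) -> list[tuple[int, int]]:
    """Intersect intervals with unclaimed residues; fragments may split."""
    out = []
    for s, e in intervals:
        run_start = None
        for pos in range(s, e + 1):
            free = not claimed[pos - 1]
            if free and run_start is None:
                run_start = pos
            elif not free and run_start is not None:
                out.append((run_start, pos - 1))
                run_start = None
        if run_start is not None:
            out.append((run_start, e))
    return out


def build_regions(
    protein: ProteinSequence, annotations: Iterable[FeatureAnnotation]
) -> RegionSet:
    """Build consensus region boundaries for one protein.

    Raises ``ValueError`` for a zero-length protein; annotations out of
    bounds are rejected with a warning.
    """
    length = protein.length
    usable: list[FeatureAnnotation] = []
    for a in annotations:
        if a.protein_accession != protein.accession:
            raise ValueError(
                f"annotation for {a.protein_accession} passed with "
                f"protein {protein.accession}"
            )
        if a.end > length:
            logger.warning(
                "%s: annotation %s %d..%d out of bounds (length %d), skipped",
                protein.accession, a.entry_id, a.start, a.end, length,
            )
            continue
        if a.entry_type in EXCLUDED_FROM_BOUNDARIES:
            continue
        usable.append(a)

    claimed = [False] * length
    proto: list[tuple[int, int, OriginType]] = []

    def claim(intervals: list[tuple[int, int]], origin: OriginType) -> None:
        for s, e in _clip_to_unclaimed(_merge_intervals(intervals), claimed):
            proto.append((s, e, origin))
            for pos in range(s - 1, e):
                claimed[pos] = True

    # Signal peptide first: included whenever available.
    claim(
        [(a.start, a.end) for a in usable if a.entry_type == EntryType.SIGNAL_PEPTIDE],
        OriginType.SIGNAL_PEPTIDE,
    )
    for tier in PRECEDENCE_TIERS:
        claim(
            [(a.start, a.end) for a in usable if a.entry_type in tier],
            _TIER_ORIGIN[tier],
        )

    # Unclaimed runs become Unassigned regions.
    pos = 1
    while pos <= length:
        if not claimed[pos - 1]:
            run_start = pos
            while pos <= length and not claimed[pos - 1]:
                pos += 1
            proto.append((run_start, pos - 1, OriginType.UNASSIGNED))
        else:
            pos += 1

    proto.sort()
    proto = _apply_length_rules(proto, length)
    regions = [
        Region(protein.accession, i + 1, s, e, origin)
        for i, (s, e, origin) in enumerate(proto)
    ]
    return RegionSet(protein=protein, regions=regions)


def _apply_length_rules(
    proto: list[tuple[int, int, OriginType]], length: int
) -> list[tuple[int, int, OriginType]]:
    """Merge short terminal Unassigned regions; discard short interior ones."""
    proto = list(proto)

    def span(s, e):
        return e - s + 1

    # N-terminal rule.
    if len(proto) >= 2:
        s, e, origin = proto[0]
        if (
            origin == OriginType.UNASSIGNED
            and span(s, e) < MIN_TERMINAL_LENGTH
            and proto[1][0] == e + 1  # adjacency: no discarded gap between
        ):
            ns, ne, norigin = proto[1]
            if norigin == OriginType.SIGNAL_PEPTIDE and len(proto) > 2:
                pass  # keep signal peptide intact; short terminal stays
            else:
                proto[1] = (s, ne, norigin)
                del proto[0]
    # C-terminal rule.
    if len(proto) >= 2:
        s, e, origin = proto[-1]
        if (
            origin == OriginType.UNASSIGNED
            and span(s, e) < MIN_TERMINAL_LENGTH
            and proto[-2][1] == s - 1
        ):
            ps, pe, porigin = proto[-2]
            if porigin == OriginType.SIGNAL_PEPTIDE and len(proto) > 2:
                pass
            else:
                proto[-2] = (ps, e, porigin)
                del proto[-1]
    # Interior rule: short Unassigned linkers are discarded, leaving gaps.
    kept = []
    for s, e, origin in proto:
        if (
            origin == OriginType.UNASSIGNED
            and span(s, e) < MIN_INTERDOMAIN_LENGTH
            and s > 1
            and e < length
        ):
            continue
        kept.append((s, e, origin))
    return kept


def assign_features_to_regions(
    region_set: RegionSet,
    annotations: Iterable[FeatureAnnotation],
    min_overlap: float = 0.75,
) -> tuple[RegionSet, list[FeatureAnnotation]]:
    """Attach annotations to regions by the fractional-overlap rule.

    An annotation attaches to the single region maximising the overlap
    (ties broken to the leftmost region), provided the overlap covers at
    least ``min_overlap`` of the annotation's length.  Repeats and Sites
    participate here even though they never shape boundaries.  Returns the
    region set with features attached plus the annotations that attached to
    no region (multi-region spanners, used for whole-protein vectors).
    """
    regions = [replace(r, features=()) for r in region_set.regions]
    attached: list[list[FeatureAnnotation]] = [[] for _ in regions]
    spanners: list[FeatureAnnotation] = []
    for a in annotations:
        best_i, best_ov = None, 0
        for i, r in enumerate(regions):
            ov = min(a.end, r.end) - max(a.start, r.start) + 1
            if ov > best_ov:
                best_i, best_ov = i, ov
        if best_i is not None and best_ov / a.length >= min_overlap:
            attached[best_i].append(a)
        else:
            spanners.append(a)
    regions = [
        replace(r, features=tuple(feats)) for r, feats in zip(regions, attached)
    ]
    return RegionSet(protein=region_set.protein, regions=regions), spanners


def write_region_tsv(region_sets: Iterable[RegionSet], path: str | Path) -> None:
    """Serialize regions as BED-like TSV (0-based half-open at the boundary)."""
    with open(path, "w") as out:
        out.write("#accession\tstart\tend\tindex\torigin_type\n")
        for rs in region_sets:
            for r in rs:
                out.write(
                    f"{r.protein_accession}\t{r.start - 1}\t{r.end}"
                    f"\t{r.index}\t{r.origin_type.value}\n"
                )


def read_region_tsv(
    path: str | Path, proteins: Sequence[ProteinSequence]
) -> list[RegionSet]:
    """Load region sets written by :func:`write_region_tsv`."""
    by_acc = {p.accession: p for p in proteins}
    rows: dict[str, list[Region]] = {}
    with open(path) as handle:
        for line in handle:
            if line.startswith("#") or not line.strip():
                continue
            acc, start, end, index, origin = line.rstrip("\n").split("\t")
            rows.setdefault(acc, []).append(
                Region(acc, int(index), int(start) + 1, int(end), OriginType(origin))
            )
    out = []
    for acc, regions in rows.items():
        if acc not in by_acc:
            raise ValueError(f"region TSV references unknown protein {acc}")
        out.append(RegionSet(by_acc[acc], sorted(regions, key=lambda r: r.start)))
    return out
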