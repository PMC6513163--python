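"""Readers for the standard annotation formats and temporal-holdout label assembly.

The pipeline consumes four text formats: FASTA protein sequences,
InterProScan 5 tab-separated feature annotations, GAF 2.x GO-annotation
files at two release dates, and interpro2go/external2go signature-to-GO
mappings.  All readers accept plain or gzip-compressed files.

Coordinates are 1-based inclusive throughout (UniProt/InterPro convention).
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.UniProt import GOA

logger = logging.getLogger(__name__)

#: GO evidence codes accepted as experimental / curated (non-IEA) support.
EXPERIMENTAL_EVIDENCE_CODES = frozenset(
    {"EXP", "IDA", "IMP", "IGI", "IEP", "TAS", "IC", "IPI"}
)

_GO_ID_RE = re.compile(r"^GO:\d{7}$")

#: All GO evidence codes recognised by the GAF reader (GO Consortium list).
KNOWN_EVIDENCE_CODES = frozenset(
    {
        "EXP", "IDA", "IPI", "IMP", "IGI", "IEP", "HTP", "HDA", "HMP", "HGI",
        "HEP", "IBA", "IBD", "IKR", "IRD", "ISS", "ISO", "ISA", "ISM", "IGC",
        "RCA", "TAS", "NAS", "IC", "ND", "IEA",
    }
)


class EntryType(str, Enum):
    """Typed category of a feature annotation, driving region precedence."""

    DOMAIN = "Domain"
    FAMILY = "Family"
    HOMOLOGOUS_SUPERFAMILY = "HomologousSuperfamily"
    UNINTEGRATED_SIGNATURE = "UnintegratedSignature"
    SIGNAL_PEPTIDE = "SignalPeptide"
    TRANSMEMBRANE = "Transmembrane"
    NON_TRANSMEMBRANE = "NonTransmembrane"
    DISORDER = "Disorder"
    REPEAT = "Repeat"
    SITE = "Site"
    OTHER = "Other"


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence with its accession."""

    accession: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"{self.accession}: empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FeatureAnnotation:
    """One annotated interval on a protein (1-based inclusive coordinates)."""

    protein_accession: str
    source_db: str
    entry_type: EntryType
    entry_id: str
    description: str
    start: int
    end: int
    interpro_id: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"{self.protein_accession}/{self.entry_id}: bad interval "
                f"{self.start}..{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GoAnnotation:
    """A protein-to-GO-term association from one GAF release."""

    protein_accession: str
    go_id: str
    evidence_code: str
    release_tag: str
    negated: bool = False

    def __post_init__(self) -> None:
        if not _GO_ID_RE.match(self.go_id):
            raise ValueError(f"malformed GO identifier: {self.go_id!r}")
        if self.evidence_code not in KNOWN_EVIDENCE_CODES:
            raise ValueError(f"unknown evidence code: {self.evidence_code!r}")


@dataclass(frozen=True)
class SignatureGoMapping:
    """A signature (or InterPro entry) to GO-term mapping, external2go style."""

    signature_id: str
    go_id: str

    def __post_init__(self) -> None:
        if not self.signature_id or not self.go_id:
            raise ValueError("signature_id and go_id must be non-empty")


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _accession_from_header(header_token: str) -> str:
    # UniProt FASTA dialect "sp|ACC|NAME" / "tr|ACC|NAME": keep ACC.
    parts = header_token.split("|")
    if len(parts) >= 3 and parts[0] in ("sp", "tr"):
        return parts[1]
    return header_token


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read protein sequences from a FASTA file.

    The accession is the header token before the first whitespace; UniProt
    ``sp|ACC|NAME`` headers are reduced to ``ACC``.
    """
    proteins = []
    with _open_text(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            proteins.append(
                ProteinSequence(
                    accession=_accession_from_header(record.id),
                    sequence=str(record.seq),
                )
            )
    return proteins


def write_fasta(proteins: Iterable[ProteinSequence], path: str | Path) -> None:
    with open(path, "w") as out:
        for p in proteins:
            out.write(f">{p.accession}\n")
            for i in range(0, p.length, 60):
                out.write(p.sequence[i : i + 60] + "\n")


# Analysis-name rules used when no explicit entry-type map covers a row.
_ANALYSIS_RULES: dict[str, EntryType] = {
    "MOBIDB_LITE": EntryType.DISORDER,
    "MOBIDBLITE": EntryType.DISORDER,
    "GENE3D": EntryType.HOMOLOGOUS_SUPERFAMILY,
    "SUPERFAMILY": EntryType.HOMOLOGOUS_SUPERFAMILY,
    "SIGNALP": EntryType.SIGNAL_PEPTIDE,
    "SIGNALP_EUK": EntryType.SIGNAL_PEPTIDE,
    "TMHMM": EntryType.TRANSMEMBRANE,
    "COILS": EntryType.OTHER,
}


def _phobius_type(signature_id: str) -> EntryType | None:
    sig = signature_id.upper()
    if "SIGNAL" in sig:
        return EntryType.SIGNAL_PEPTIDE
    if "NON" in sig and ("CYTOPLASMIC" in sig or "MEMBRANE" in sig):
        # NON_CYTOPLASMIC_DOMAIN / CYTOPLASMIC_DOMAIN: loop topology
        return EntryType.NON_TRANSMEMBRANE
    if "TRANSMEMBRANE" in sig:
        return EntryType.TRANSMEMBRANE
    if "CYTOPLASMIC" in sig:
        return EntryType.NON_TRANSMEMBRANE
    return None


def _resolve_entry_type(
    analysis: str,
    signature_id: str,
    interpro_id: str,
    entry_type_map: Mapping[str, str | EntryType] | None,
) -> EntryType:
    """Assign a typed category to an InterProScan row.

    Resolution order: explicit map (keyed by signature or InterPro entry ID,
    mirroring InterPro's entry.list), then analysis-specific rules (Phobius
    topology, MobiDB-lite disorder, Gene3D/SUPERFAMILY), then
    UnintegratedSignature for rows with no InterPro entry, else Other.
    """
    if entry_type_map is not None:
        for key in (signature_id, interpro_id):
            if key and key in entry_type_map:
                return EntryType(entry_type_map[key])
    upper = analysis.upper()
    if upper == "PHOBIUS":
        t = _phobius_type(signature_id)
        if t is not None:
            return t
    if upper in _ANALYSIS_RULES:
        return _ANALYSIS_RULES[upper]
    if not interpro_id:
        return EntryType.UNINTEGRATED_SIGNATURE
    return EntryType.OTHER


def read_interproscan_tsv(
    path: str | Path,
    entry_type_map: Mapping[str, str | EntryType] | None = None,
) -> list[FeatureAnnotation]:
    """Read feature annotations from an InterProScan 5 TSV file.

    Columns used (0-based): 0 accession, 3 analysis, 4 signature ID,
    5 signature description, 6 start, 7 stop, 11 InterPro entry ID,
    12 InterPro description.  ``entry_type_map`` maps signature or
    InterPro IDs to :class:`EntryType` names (e.g. from InterPro's
    entry.list); rows it does not cover fall back to per-analysis rules.

    Rows with ``start > end`` are rejected with a warning; non-integer
    coordinates raise ``ValueError``.
    """
    annotations = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 8:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 8 tab-separated columns, "
                    f"got {len(cols)}"
                )
            try:
                start, end = int(cols[6]), int(cols[7])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinates "
                    f"{cols[6]!r}..{cols[7]!r}"
                ) from exc
            if start > end:
                logger.warning(
                    "%s:%d: start > end (%d > %d), record rejected",
                    path, lineno, start, end,
                )
                continue
            interpro_id = cols[11] if len(cols) > 11 and cols[11] != "-" else ""
            interpro_desc = cols[12] if len(cols) > 12 and cols[12] != "-" else ""
            description = cols[5] if cols[5] != "-" else ""
            if interpro_desc:
                description = (description + " " + interpro_desc).strip()
            annotations.append(
                FeatureAnnotation(
                    protein_accession=cols[0],
                    source_db=cols[3],
                    entry_type=_resolve_entry_type(
                        cols[3], cols[4], interpro_id, entry_type_map
                    ),
                    entry_id=cols[4],
                    description=description,
                    start=start,
                    end=end,
                    interpro_id=interpro_id,
                )
            )
    return annotations


def read_gaf(path: str | Path, release_tag: str) -> list[GoAnnotation]:
    """Read all rows of a GAF 2.x file, tagging them with a release label.

    No evidence filtering happens here; rows with a NOT qualifier are
    retained but flagged ``negated``.
    """
    annotations = []
    with _open_text(path) as handle:
        for rec in GOA.gafiterator(handle):
            qualifiers = rec.get("Qualifier", [])
            negated = any(q.split("|")[0] == "NOT" or q == "NOT" for q in qualifiers)
            annotations.append(
                GoAnnotation(
                    protein_accession=rec["DB_Object_ID"],
                    go_id=rec["GO_ID"],
                    evidence_code=rec["Evidence"],
                    release_tag=release_tag,
                    negated=negated,
                )
            )
    return annotations


def filter_non_iea(annotations: Iterable[GoAnnotation]) -> list[GoAnnotation]:
    """Keep only annotations with experimental / curated evidence codes.

    The accepted set is EXP, IDA, IMP, IGI, IEP, TAS, IC and IPI; everything
    else — IEA in particular, but also e.g. ISS — is dropped.  Idempotent.
    """
    return [a for a in annotations if a.evidence_code in EXPERIMENTAL_EVIDENCE_CODES]


class EmptySplitError(ValueError):
    """Raised when a GO term appears in neither annotation release."""


def temporal_split(
    old_annotations: Sequence[GoAnnotation],
    new_annotations: Sequence[GoAnnotation],
    go_id: str,
) -> tuple[set[str], set[str]]:
    """Split proteins for one GO term into training and evaluation sets.

    Training proteins carry the term in the older release; evaluation
    proteins gained the term by the newer release only.  NOT-qualified
    rows never contribute positives.
    """
    old_pos = {
        a.protein_accession
        for a in old_annotations
        if a.go_id == go_id and not a.negated
    }
    new_pos = {
        a.protein_accession
        for a in new_annotations
        if a.go_id == go_id and not a.negated
    }
    if not old_pos and not new_pos:
        raise EmptySplitError(f"{go_id} absent from both releases")
    return old_pos, new_pos - old_pos


def negative_pool(
    annotations: Sequence[GoAnnotation],
    go_id: str,
    ancestor_edges: Mapping[str, set[str]] | None = None,
    exclude_descendants: bool = False,
) -> set[str]:
    """Proteins usable as negatives for ``go_id``.

    A negative has at least one (non-negated) annotation to some other term
    in the release but none to the target term — nor, when
    ``exclude_descendants`` is set and a child->parents ``ancestor_edges``
    table is supplied, to any descendant of the target.  Proteins whose only
    relation to the target is a NOT-qualified row are excluded as ambiguous.
    """
    blocked_terms = {go_id}
    if exclude_descendants:
        if ancestor_edges is None:
            raise ValueError("exclude_descendants requires ancestor_edges")
        # descendants of go_id = terms whose ancestor closure contains go_id
        for term, parents in ancestor_edges.items():
            if go_id in _ancestor_closure(term, ancestor_edges):
                blocked_terms.add(term)
    annotated: set[str] = set()
    blocked: set[str] = set()
    for a in annotations:
        if a.go_id in blocked_terms:
            blocked.add(a.protein_accession)
        elif not a.negated:
            annotated.add(a.protein_accession)
    return annotated - blocked


def _ancestor_closure(term: str, edges: Mapping[str, set[str]]) -> set[str]:
    seen: set[str] = set()
    stack = [term]
    while stack:
        t = stack.pop()
        for parent in edges.get(t, ()):
            if parent not in seen:
                seen.add(parent)
                stack.append(parent)
    return seen


def read_external2go(path: str | Path) -> list[SignatureGoMapping]:
    """Parse an interpro2go/external2go mapping file.

    Lines look like ``InterPro:IPR000008 C2 domain > GO:... ; GO:0005515``.
    Comment lines (``!``) are skipped; lines without a ``; GO:`` part are
    skipped with a warning.
    """
    mappings = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith("!"):
                continue
            if "; GO:" not in line:
                logger.warning("%s:%d: no '; GO:' part, line skipped", path, lineno)
                continue
            left, go_id = line.rsplit(";", 1)
            sig_token = left.split()[0]
            signature_id = sig_token.split(":", 1)[1] if ":" in sig_token else sig_token
            mappings.append(
                SignatureGoMapping(signature_id=signature_id, go_id=go_id.strip())
            )
    return mappings


def propagate_domain_labels_to_proteins(
    mappings: Sequence[SignatureGoMapping],
    region_signatures: Mapping[str, Iterable[str]],
    region_proteins: Mapping[str, str],
    go_id: str,
) -> tuple[set[str], set[str]]:
    """Attach domain-level GO labels to regions and lift them to proteins.

    Regions whose assigned signature IDs match an external2go mapping for
    ``go_id`` become known region-level positives (the r+ anchors); their
    parent proteins are marked positive for consistency.  Returns
    ``(positive_region_ids, positive_protein_accessions)``.
    """
    sigs_for_term = {m.signature_id for m in mappings if m.go_id == go_id}
    pos_regions = {
        rid
        for rid, sigs in region_signatures.items()
        if sigs_for_term.intersection(sigs)
    }
    pos_proteins = {region_proteins[rid] for rid in pos_regions}
    return pos_regions, pos_proteins
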