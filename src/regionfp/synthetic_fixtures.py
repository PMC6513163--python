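"""Seeded synthetic corpora with the statistical structure the method assumes.

The generator emulates the shape of a curated proteome slice: proteins
made of 1-6 continuous regions (region count 1 + Poisson(2), truncated at
6, matching the observed mean of about three regions per protein; region
lengths uniform in [25, 400] so nothing trips the terminal/linker length
rules), sparse token features per region with Zipf-like background
frequencies, and a single planted region-specific function:

* proteins belong to families; a family token appears in every region of
  its members, and positives are enriched in half of the families, so
  family vocabulary is partially label-correlated without being
  region-specific — the confounder that misleads a whole-protein model at
  region level (a family can contain both functional and non-functional
  members);
* every positive protein carries the causal feature in exactly one of its
  regions;
* the true region label is 1 iff the region carries the causal feature;
* training labels are the true labels flipped independently with
  probability ``label_noise``, and the protein label is the OR of the
  (noisy) region labels — the max-aggregation assumption;
* residue-contact records place more than three sub-cutoff residues in
  each causal region (full structural coverage everywhere), so
  structure-derived evaluation labels recover the planted ground truth
  while the training labels carry the noise.

Everything is fully determined by the seed, and the generator can emit the
exact text formats the readers consume (FASTA, InterProScan-style TSV, GAF,
contact TSV).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .evaluation import LigandClass, ResidueContactRecord, write_contact_tsv
from .io_formats import (
    EntryType,
    FeatureAnnotation,
    GoAnnotation,
    ProteinSequence,
    write_fasta,
)
from .region_builder import OriginType, Region, RegionSet

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: GO term used for all synthetic labels (DNA binding, as a binding term
#: with unambiguous residue-level ground truth).
SYNTHETIC_GO_ID = "GO:0003677"


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic corpus."""

    n_proteins: int = 200
    mean_extra_regions: float = 2.0  # region count = 1 + Poisson(this), <= 6
    max_regions: int = 6
    min_region_length: int = 25
    max_region_length: int = 400
    vocab_size: int = 500
    causal_feature: str = "bindmotif"
    positive_fraction: float = 0.3
    label_noise: float = 0.05
    feature_noise_per_region: int = 5
    zipf_exponent: float = 1.1
    n_families: int = 20
    family_enrichment: float = 4.0  # positive-sampling weight, first half
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 4:
            raise ValueError("n_proteins must be >= 4")
        if not (0 < self.positive_fraction < 1):
            raise ValueError("positive_fraction must be in (0, 1)")
        if not (0 <= self.label_noise < 0.5):
            raise ValueError("label_noise must be in [0, 0.5)")
        n_pos = round(self.n_proteins * self.positive_fraction)
        if n_pos < 1 or n_pos >= self.n_proteins:
            raise ValueError("positive_fraction infeasible for this n_proteins")


@dataclass
class SyntheticCorpus:
    """A generated corpus plus its planted ground truth."""

    spec: SyntheticSpec
    proteins: list[ProteinSequence]
    region_sets: list[RegionSet]
    annotations: list[FeatureAnnotation]
    region_ids: list[str]              # flattened, row order of feature matrices
    region_proteins: list[str]         # parallel: owning protein accession
    region_feature_counts: list[dict[str, int]]
    protein_feature_counts: list[dict[str, int]]
    causal_region_labels: np.ndarray   # planted truth, pre-noise
    hidden_region_labels: np.ndarray   # noisy training labels
    protein_labels: dict[str, int]     # OR of noisy region labels
    contacts: list[ResidueContactRecord]

    @property
    def protein_region_index(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {p.accession: [] for p in self.proteins}
        for i, acc in enumerate(self.region_proteins):
            out[acc].append(i)
        return out


def _zipf_probabilities(vocab_size: int, exponent: float) -> np.ndarray:
    ranks = np.arange(1, vocab_size + 1, dtype=float)
    p = ranks ** -exponent
    return p / p.sum()


def generate_corpus(spec: SyntheticSpec) -> SyntheticCorpus:
    """Generate a corpus; identical specs (incl. seed) give identical output."""
    rng = np.random.default_rng(spec.seed)
    n_pos = round(spec.n_proteins * spec.positive_fraction)
    families = rng.integers(spec.n_families, size=spec.n_proteins)
    # positives concentrate in the first half of the families, so family
    # vocabulary is predictive at protein level but mixed within a family
    weight = np.where(families < spec.n_families // 2,
                      spec.family_enrichment, 1.0)
    is_positive = np.zeros(spec.n_proteins, dtype=bool)
    is_positive[rng.choice(spec.n_proteins, size=n_pos, replace=False,
                           p=weight / weight.sum())] = True

    vocab = [f"tok{j:04d}" for j in range(spec.vocab_size)]
    bg_probs = _zipf_probabilities(spec.vocab_size, spec.zipf_exponent)

    proteins: list[ProteinSequence] = []
    region_sets: list[RegionSet] = []
    annotations: list[FeatureAnnotation] = []
    region_ids: list[str] = []
    region_proteins: list[str] = []
    region_counts: list[dict[str, int]] = []
    causal_labels: list[int] = []
    contacts: list[ResidueContactRecord] = []

    for p in range(spec.n_proteins):
        acc = f"SYN{p:05d}"
        n_regions = 1 + min(int(rng.poisson(spec.mean_extra_regions)),
                            spec.max_regions - 1)
        lengths = rng.integers(spec.min_region_length,
                               spec.max_region_length + 1, size=n_regions)
        seq = "".join(
            rng.choice(list(AMINO_ACIDS), size=int(lengths.sum()))
        )
        protein = ProteinSequence(acc, seq)
        proteins.append(protein)

        causal_region = int(rng.integers(n_regions)) if is_positive[p] else -1
        start = 1
        regions: list[Region] = []
        for r in range(n_regions):
            end = start + int(lengths[r]) - 1
            counts: dict[str, int] = {}
            noise_idx = rng.choice(spec.vocab_size,
                                   size=spec.feature_noise_per_region,
                                   replace=False, p=bg_probs)
            for j in noise_idx:
                counts[vocab[j]] = counts.get(vocab[j], 0) + 1
            counts[f"fam{families[p]:03d}"] = 1  # family-wide, every region
            causal = r == causal_region
            if causal:
                counts[spec.causal_feature] = 1
            region = Region(acc, r + 1, start, end, OriginType.DOMAIN)
            desc = " ".join(
                tok for tok, c in sorted(counts.items()) for _ in range(c)
            )
            ann = FeatureAnnotation(
                protein_accession=acc, source_db="SYNTH",
                entry_type=EntryType.DOMAIN,
                entry_id=f"SYNSIG{p:05d}_{r + 1}",
                description=desc, start=start, end=end,
            )
            annotations.append(ann)
            regions.append(
                Region(acc, r + 1, start, end, OriginType.DOMAIN, (ann,))
            )
            region_ids.append(region.region_id)
            region_proteins.append(acc)
            region_counts.append(counts)
            causal_labels.append(int(causal))
            if causal:
                # > 3 residues within the 6-angstrom cutoff
                contact_res = rng.choice(
                    np.arange(start, end + 1), size=4, replace=False
                )
                for res in contact_res:
                    contacts.append(
                        ResidueContactRecord(acc, int(res), 3.0,
                                             LigandClass.DNA, True)
                    )
            start = end + 1
        # full structural coverage: far-from-ligand records elsewhere
        contact_set = {c.residue for c in contacts
                       if c.protein_accession == acc}
        for res in range(1, protein.length + 1):
            if res not in contact_set:
                contacts.append(
                    ResidueContactRecord(acc, res, 999.0,
                                         LigandClass.DNA, True)
                )
        region_sets.append(RegionSet(protein, regions))

    causal_arr = np.array(causal_labels, dtype=int)
    flips = rng.random(causal_arr.size) < spec.label_noise
    hidden = np.where(flips, 1 - causal_arr, causal_arr)

    protein_labels: dict[str, int] = {}
    offset = 0
    protein_counts: list[dict[str, int]] = []
    for p, rs in enumerate(region_sets):
        k = len(rs.regions)
        protein_labels[proteins[p].accession] = int(hidden[offset:offset + k].max())
        merged: dict[str, int] = {}
        for c in region_counts[offset:offset + k]:
            for tok, v in c.items():
                merged[tok] = merged.get(tok, 0) + v
        protein_counts.append(merged)
        offset += k

    return SyntheticCorpus(
        spec=spec, proteins=proteins, region_sets=region_sets,
        annotations=annotations, region_ids=region_ids,
        region_proteins=region_proteins,
        region_feature_counts=region_counts,
        protein_feature_counts=protein_counts,
        causal_region_labels=causal_arr,
        hidden_region_labels=hidden,
        protein_labels=protein_labels,
        contacts=contacts,
    )


def write_corpus(corpus: SyntheticCorpus, outdir: str | Path) -> dict[str, Path]:
    """Emit the corpus in the exact formats the io readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "proteins.fasta",
        "interproscan": outdir / "features.tsv",
        "gaf": outdir / "annotations.gaf",
        "contacts": outdir / "contacts.tsv",
        "truth": outdir / "region_truth.tsv",
    }
    write_fasta(corpus.proteins, paths["fasta"])
    with open(paths["interproscan"], "w") as out:
        for a in corpus.annotations:
            # InterProScan 5 TSV dialect (md5/length/score/status/date stubbed)
            out.write(
                "\t".join([
                    a.protein_accession, "-", "0", a.source_db, a.entry_id,
                    a.description, str(a.start), str(a.end), "0.0", "T",
                    "2018-01-01", "-", "-",
                ]) + "\n"
            )
    with open(paths["gaf"], "w") as out:
        out.write("!gaf-version: 2.1\n")
        for acc, label in corpus.protein_labels.items():
            if label == 1:
                out.write(
                    "\t".join([
                        "UniProtKB", acc, acc, "", SYNTHETIC_GO_ID,
                        "PMID:0000000", "IDA", "", "F", acc, "", "protein",
                        "taxon:9606", "20180101", "SYNTH", "", "",
                    ]) + "\n"
                )
    write_contact_tsv(corpus.contacts, paths["contacts"])
    with open(paths["truth"], "w") as out:
        out.write("#region_id\tcausal\thidden\n")
        for rid, c, h in zip(corpus.region_ids, corpus.causal_region_labels,
                             corpus.hidden_region_labels):
            out.write(f"{rid}\t{int(c)}\t{int(h)}\n")
    return paths


def generate_annotation_fixture(outdir: str | Path | None = None):
    """A 511-residue protein with Domain annotations at 1-249 and 339-402.

    Mirrors the canonical two-domain membrane-remodelling protein used as
    the worked example for boundary building: an IMD/I-BAR domain followed
    by an SH3 domain, with two unannotated stretches between and after
    them.  The sequence itself is synthetic (seeded random amino acids) —
    only the length and the domain coordinates matter for boundary
    building.  Returns ``(protein, annotations)`` and, when ``outdir`` is
    given, also writes FASTA + InterProScan-style TSV files there.
    """
    rng = np.random.default_rng(511)
    seq = "".join(rng.choice(list(AMINO_ACIDS), size=511))
    protein = ProteinSequence("Q9UHR4", seq)
    annotations = [
        FeatureAnnotation("Q9UHR4", "Pfam", EntryType.DOMAIN, "PF08397",
                          "IMD I-BAR domain", 1, 249),
        FeatureAnnotation("Q9UHR4", "Pfam", EntryType.DOMAIN, "PF00018",
                          "SH3 domain", 339, 402),
    ]
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta([protein], outdir / "fixture.fasta")
        with open(outdir / "fixture.tsv", "w") as out:
            for a in annotations:
                out.write(
                    "\t".join([
                        a.protein_accession, "-", "511", a.source_db,
                        a.entry_id, a.description, str(a.start), str(a.end),
                        "0.0", "T", "2018-01-01", "-", "-",
                    ]) + "\n"
                )
    return protein, annotations
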