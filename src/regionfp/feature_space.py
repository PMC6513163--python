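"""Encode regions and whole proteins in four feature spaces.

Each region (or protein, for the whole-protein baseline) becomes a
fixed-length vector in one of four spaces:

* ``KMER`` — overlapping k-residue subsequences of the region sequence
  (k = 3 by default);
* ``KEY``  — keywords tokenized from the descriptions of the features
  assigned to the region;
* ``IPR``  — InterPro entry IDs assigned with the 75%-overlap rule;
* ``SIG``  — member-database signature IDs, including unintegrated entries
  such as signal-peptide and transmembrane predictions.

Count vectors are TF-IDF weighted (smoothed idf with a +1 floor, L2 row
normalization, so cosine similarity lives in [0, 1]) and pairwise region
similarity is a cosine kernel thresholded at the 95th percentile of
off-diagonal similarities estimated from a random sample of regions.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.io import mmread, mmwrite
from sklearn.feature_extraction import DictVectorizer
from sklearn.feature_extraction.text import TfidfTransformer

from .io_formats import FeatureAnnotation, ProteinSequence
from .region_builder import Region, RegionSet


class FeatureSpace(str, Enum):
    KMER = "KMER"
    KEY = "KEY"
    IPR = "IPR"
    SIG = "SIG"


class IdLevel(str, Enum):
    INTERPRO = "interpro"
    SIGNATURE = "signature"


@dataclass
class FeatureMatrix:
    """TF-IDF-weighted items x features matrix for one feature space."""

    space: FeatureSpace
    item_ids: list[str]
    vocabulary: list[str]
    weights: sp.csr_matrix  # items x vocabulary, non-negative
    row_norm: bool = True

    @property
    def n_items(self) -> int:
        return self.weights.shape[0]

    def row(self, i: int) -> np.ndarray:
        return np.asarray(self.weights[i].todense()).ravel()


@dataclass
class SimilarityKernel:
    """Thresholded cosine-similarity kernel over items (symbol kappa)."""

    space: FeatureSpace
    threshold: float
    values: sp.csr_matrix  # items x items, symmetric, in [0, 1]


def extract_kmers(sequence: str, k: int = 3) -> dict[str, int]:
    """Count overlapping length-k subsequences; empty if sequence < k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return dict(Counter(sequence[i : i + k] for i in range(len(sequence) - k + 1)))


_TOKEN_RE = re.compile(r"[^0-9A-Za-z]+")


def extract_keywords(
    descriptions: Iterable[str], lowercase: bool = True
) -> dict[str, int]:
    """Tokenize feature descriptions into keyword counts.

    Splits on any non-alphanumeric character, drops empty tokens and (by
    default) case-folds, so 'WD repeat-containing' yields wd, repeat and
    containing.  No stop-word removal.
    """
    counts: Counter[str] = Counter()
    for desc in descriptions:
        for token in _TOKEN_RE.split(desc):
            if token:
                counts[token.lower() if lowercase else token] += 1
    return dict(counts)


def extract_ids(region: Region, level: IdLevel | str) -> dict[str, int]:
    """Unique InterPro entry IDs or member-database signature IDs (0/1)."""
    level = IdLevel(level)
    ids: set[str] = set()
    for a in region.features:
        if level is IdLevel.INTERPRO:
            if a.interpro_id:
                ids.add(a.interpro_id)
        else:
            ids.add(a.entry_id)
    return {i: 1 for i in sorted(ids)}


def region_counts(
    region: Region,
    space: FeatureSpace | str,
    sequence: str | None = None,
    k: int = 3,
    lowercase: bool = True,
) -> dict[str, int]:
    """Raw feature counts for one region in the requested space.

    ``sequence`` is the full protein sequence (needed for KMER only).
    """
    space = FeatureSpace(space)
    if space is FeatureSpace.KMER:
        if sequence is None:
            raise ValueError("KMER space needs the protein sequence")
        return extract_kmers(sequence[region.start - 1 : region.end], k=k)
    if space is FeatureSpace.KEY:
        return extract_keywords(
            (a.description for a in region.features if a.description),
            lowercase=lowercase,
        )
    if space is FeatureSpace.IPR:
        return extract_ids(region, IdLevel.INTERPRO)
    return extract_ids(region, IdLevel.SIGNATURE)


class TfidfEncoder:
    """Fit a vocabulary + idf on training items; transform new items.

    Weight(i, f) = count(i, f) * idf(f) with
    idf(f) = ln((1 + N)/(1 + df(f))) + 1, rows L2-normalized.  The
    vocabulary is fixed at fit time; unseen features are dropped on
    transform.
    """

    def __init__(self, space: FeatureSpace | str):
        self.space = FeatureSpace(space)
        self._vec = DictVectorizer(sparse=True)
        self._tfidf = TfidfTransformer(
            norm="l2", use_idf=True, smooth_idf=True, sublinear_tf=False
        )

    def fit_transform(
        self, counts: Sequence[Mapping[str, int]], item_ids: Sequence[str]
    ) -> FeatureMatrix:
        if not counts or all(not c for c in counts):
            raise ValueError("all-zero input: no features to fit")
        raw = self._vec.fit_transform(counts)
        weights = self._tfidf.fit_transform(raw)
        return FeatureMatrix(
            space=self.space,
            item_ids=list(item_ids),
            vocabulary=list(self._vec.get_feature_names_out()),
            weights=sp.csr_matrix(weights),
        )

    def transform(
        self, counts: Sequence[Mapping[str, int]], item_ids: Sequence[str]
    ) -> FeatureMatrix:
        raw = self._vec.transform(counts)
        weights = self._tfidf.transform(raw)
        return FeatureMatrix(
            space=self.space,
            item_ids=list(item_ids),
            vocabulary=list(self._vec.get_feature_names_out()),
            weights=sp.csr_matrix(weights),
        )


def tfidf_fit_transform(
    counts: Sequence[Mapping[str, int]],
    item_ids: Sequence[str],
    space: FeatureSpace | str = FeatureSpace.KEY,
) -> tuple[FeatureMatrix, TfidfEncoder]:
    """One-shot TF-IDF fit; returns the matrix and the fitted encoder."""
    enc = TfidfEncoder(space)
    return enc.fit_transform(counts, item_ids), enc


def _percentile_with_implicit_zeros(
    sorted_nonzero: np.ndarray, total: int, q: float
) -> float:
    """Linear-interpolated percentile of a vector holding ``total`` values,
    of which only the (ascending-sorted) nonzero ones are materialized."""
    n_zero = total - sorted_nonzero.size
    if n_zero < 0:
        raise ValueError("more nonzero values than total")

    def value_at(j: int) -> float:
        return 0.0 if j < n_zero else float(sorted_nonzero[j - n_zero])

    h = (total - 1) * (q / 100.0)
    lo = int(np.floor(h))
    hi = min(lo + 1, total - 1)
    v_lo, v_hi = value_at(lo), value_at(hi)
    return v_lo + (h - lo) * (v_hi - v_lo)


def build_kernel(
    matrix: FeatureMatrix,
    percentile: float = 95.0,
    sample_size: int = 10_000,
    seed: int = 0,
) -> SimilarityKernel:
    """Thresholded cosine-similarity kernel over the matrix rows.

    The threshold is the ``percentile``-th percentile of off-diagonal
    cosine similarities among ``min(sample_size, N)`` rows sampled without
    replacement (zero similarities included).  Entries below the threshold
    are set to 0; the diagonal is kept at 1 for nonzero rows.
    """
    n = matrix.n_items
    if n < 2:
        raise ValueError("kernel needs at least 2 items")
    rng = np.random.default_rng(seed)
    m = min(sample_size, n)
    idx = rng.choice(n, size=m, replace=False)
    sample = matrix.weights[idx]
    sims = (sample @ sample.T).tocoo()
    off = sims.row != sims.col
    nonzero_vals = np.sort(sims.data[off])
    threshold = _percentile_with_implicit_zeros(
        nonzero_vals, total=m * (m - 1), q=percentile
    )

    full = matrix.weights @ matrix.weights.T
    full = full.tocoo()
    keep = full.data >= threshold
    kernel = sp.coo_matrix(
        (full.data[keep], (full.row[keep], full.col[keep])), shape=(n, n)
    ).tocsr()
    # exact diagonal: 1 for nonzero rows, robust to float drift
    nonzero_rows = np.asarray((matrix.weights != 0).sum(axis=1)).ravel() > 0
    kernel = kernel.tolil()
    for i in np.flatnonzero(nonzero_rows):
        kernel[i, i] = 1.0
    return SimilarityKernel(
        space=matrix.space, threshold=threshold, values=kernel.tocsr()
    )


def protein_counts(
    protein: ProteinSequence,
    region_set: RegionSet,
    spanners: Sequence[FeatureAnnotation],
    space: FeatureSpace | str,
    k: int = 3,
    lowercase: bool = True,
) -> dict[str, int]:
    """Whole-protein feature counts for the baseline model.

    Sum of the region counts plus the features of annotations that failed
    the 75% single-region overlap rule (multi-region spanners).  K-mers are
    computed on the full sequence, so junction k-mers are included.
    """
    space = FeatureSpace(space)
    if space is FeatureSpace.KMER:
        return extract_kmers(protein.sequence, k=k)
    total: Counter[str] = Counter()
    for region in region_set:
        total.update(region_counts(region, space, lowercase=lowercase))
    if space is FeatureSpace.KEY:
        total.update(
            extract_keywords(
                (a.description for a in spanners if a.description),
                lowercase=lowercase,
            )
        )
    elif space is FeatureSpace.IPR:
        for a in spanners:
            if a.interpro_id:
                total[a.interpro_id] = 1
    else:
        for a in spanners:
            total[a.entry_id] = 1
    return dict(total)


def save_matrix(matrix: FeatureMatrix, prefix: str | Path) -> None:
    """Persist a feature matrix as MTX plus item-id and vocabulary sidecars."""
    prefix = Path(prefix)
    mmwrite(str(prefix) + ".mtx", matrix.weights)
    Path(str(prefix) + ".items.txt").write_text("\n".join(matrix.item_ids) + "\n")
    Path(str(prefix) + ".vocab.txt").write_text("\n".join(matrix.vocabulary) + "\n")


def load_matrix(prefix: str | Path, space: FeatureSpace | str) -> FeatureMatrix:
    prefix = Path(prefix)
    weights = sp.csr_matrix(mmread(str(prefix) + ".mtx"))
    item_ids = Path(str(prefix) + ".items.txt").read_text().splitlines()
    vocab = Path(str(prefix) + ".vocab.txt").read_text().splitlines()
    return FeatureMatrix(FeatureSpace(space), item_ids, vocab, weights)
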