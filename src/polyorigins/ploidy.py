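"""Ploidy classification from four-allele phasing products.

When a diploid is phased for four alleles, two of the four haplotypes are
(noisy) duplicates, so the sorted pairwise distances among the four phased
alleles carry a strong ploidy signal: a genuine tetraploid has four partly
distinct haplotypes, a diploid collapses to at most two.  A transparent
nearest-centroid discriminant is trained on samples of known ploidy and
applied to the rest.  This is a reconstruction of the distance-signal
approach, not a port of any particular implementation; per-sample features
are pooled across loci rather than voted per locus.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from .alignments import p_distance

logger = logging.getLogger(__name__)

FEATURE_NAMES = tuple(f"sorted_d{i}" for i in range(6)) + (
    "mean_distinct_haplotypes",
    "frac_loci_gt2_distinct",
)

#: Standardized-margin threshold below which a call is flagged ambiguous.
DEFAULT_AMBIGUITY_THRESHOLD = 0.1


@dataclass(frozen=True)
class PloidyFeatures:
    sample_id: str
    values: np.ndarray  # the 8 features, ordered as FEATURE_NAMES
    n_loci_used: int
    n_loci_skipped: int


@dataclass
class PloidyModel:
    centroids: dict[int, np.ndarray]  # ploidy (2 or 4) -> feature centroid
    scales: np.ndarray
    threshold: float
    n_per_class: dict[int, int]
    training_accuracy: float


@dataclass(frozen=True)
class PloidyCall:
    sample_id: str
    ploidy: int
    margin: float
    ambiguous: bool


def _distinct_haplotype_count(seqs) -> int:
    """Number of zero-distance groups among haplotypes (missing-aware)."""
    n = len(seqs)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(n), 2):
        d = p_distance(seqs[i], seqs[j])
        if d == 0:
            parent[find(i)] = find(j)
    return len({find(i) for i in range(n)})


def ploidy_features(loci, sample_id: str) -> PloidyFeatures:
    """Pooled distance features for one sample phased as four haplotypes.

    Per locus: the 6 pairwise p-distances among the 4 haplotypes, sorted
    ascending, plus the distinct-haplotype count.  Loci where any pairwise
    distance is undefined (no comparable sites) are skipped and counted.
    """
    sorted_d = []
    distinct = []
    skipped = 0
    for locus in loci:
        if sample_id not in locus.samples():
            continue
        haps = locus.haplotypes(sample_id)
        if len(haps) != 4:
            raise ValueError(f"sample {sample_id!r} has {len(haps)} haplotypes at {locus.locus_id}")
        seqs = [seq for _, seq in haps]
        d = [p_distance(a, b) for a, b in itertools.combinations(seqs, 2)]
        if any(np.isnan(x) for x in d):
            skipped += 1
            continue
        sorted_d.append(np.sort(d))
        distinct.append(_distinct_haplotype_count(seqs))
    if not sorted_d:
        raise ValueError(f"sample {sample_id!r}: no usable loci")
    sorted_d = np.vstack(sorted_d)
    distinct = np.array(distinct)
    values = np.concatenate(
        [sorted_d.mean(axis=0), [distinct.mean(), float((distinct > 2).mean())]]
    )
    return PloidyFeatures(sample_id, values, len(distinct), skipped)


def train_ploidy_classifier(
    labeled, threshold: float = DEFAULT_AMBIGUITY_THRESHOLD
) -> PloidyModel:
    """Nearest-centroid discriminant on scale-standardized features.

    ``labeled`` is a list of ``(PloidyFeatures, ploidy)`` with both classes
    (2 and 4) represented by at least two samples.  Feature scales are the
    pooled within-class SDs, floored to stay positive.
    """
    by_class: dict[int, list[np.ndarray]] = {}
    for feats, ploidy in labeled:
        if ploidy not in (2, 4):
            raise ValueError(f"ploidy must be 2 or 4, got {ploidy}")
        by_class.setdefault(ploidy, []).append(feats.values)
    if set(by_class) != {2, 4}:
        raise ValueError("training data must contain both diploids and tetraploids")
    for ploidy, rows in by_class.items():
        if len(rows) < 2:
            raise ValueError(f"need >= 2 training samples of ploidy {ploidy}")
    centroids = {p: np.vstack(rows).mean(axis=0) for p, rows in by_class.items()}
    pooled = np.vstack([np.vstack(rows) - centroids[p] for p, rows in by_class.items()])
    scales = pooled.std(axis=0)
    floor = max(1e-8, 1e-6 * float(np.abs(pooled).max() or 1.0))
    if (scales < floor).any():
        logger.warning("zero-variance ploidy features; scales floored at %g", floor)
        scales = np.maximum(scales, floor)
    model = PloidyModel(centroids, scales, threshold, {p: len(r) for p, r in by_class.items()}, 0.0)
    correct = sum(predict_ploidy(model, f).ploidy == p for f, p in labeled)
    model.training_accuracy = correct / len(labeled)
    return model


def predict_ploidy(model: PloidyModel, features: PloidyFeatures) -> PloidyCall:
    """Call the nearer centroid; flag calls with a small standardized margin."""
    x = features.values
    if x.shape != model.scales.shape:
        raise ValueError("feature dimension mismatch")
    dist = {
        p: float(np.linalg.norm((x - c) / model.scales)) for p, c in model.centroids.items()
    }
    call = min(dist, key=lambda p: (dist[p], p))
    other = 4 if call == 2 else 2
    margin = dist[other] - dist[call]
    return PloidyCall(features.sample_id, call, margin, margin < model.threshold)


def classify_study(loci, sample_ids, training_labels: dict[str, int],
                   threshold: float = DEFAULT_AMBIGUITY_THRESHOLD):
    """Train on the labeled subset and call every sample.

    ``loci`` must hold four haplotypes per sample (see
    :func:`polyorigins.synth.expand_to_four_alleles` for diploid-as-
    tetraploid phasing products).  Returns ``(calls, model)``.
    """
    feats = {sid: ploidy_features(loci, sid) for sid in sample_ids}
    labeled = [(feats[sid], p) for sid, p in training_labels.items() if sid in feats]
    model = train_ploidy_classifier(labeled, threshold)
    calls = [predict_ploidy(model, feats[sid]) for sid in sample_ids]
    return calls, model
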