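"""A/B compartment scoring and cross-sample comparison.

The compartment score of a chromosome is the leading eigenvector of the
Pearson correlation matrix of its balanced cis observed/expected map,
scaled by the square root of its eigenvalue — positive score = open A
compartment, negative = compact B, under an orientation fixed by a
user-supplied reference track (planted A-density on simulations; gene
density or GC on real data).  Because the leading eigenvector can track
karyotype rather than compartments on aneuploid genomes, the top few
eigenvectors are computed and the one best correlated with the
orientation track is selected, with a flag when it is not the first.

Samples are compared by pairwise Pearson correlation of their scores
over jointly unmasked bins, followed by average-linkage hierarchical
clustering on (1 − r) distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.cluster.hierarchy as sch

from .contact import BinTable, ContactMatrix, cis_oe_dense
from .genome import GenomicInterval

__all__ = [
    "CompartmentTrack",
    "SampleSimilarity",
    "compartment_score",
    "compare_tracks",
    "compartment_at",
]


@dataclass
class CompartmentTrack:
    """Signed per-bin compartment score along one chromosome."""

    bins: BinTable  # bin table of the source matrix (genome-wide)
    chrom: str
    score: np.ndarray  # per chromosome bin; NaN where masked
    sample: str = ""
    eig_index: int = 0  # which eigenvector was selected (0 = leading)
    eigenvalues: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def labels(self) -> np.ndarray:
        """'A' (score > 0), 'B' (score < 0), '' where missing or zero."""
        out = np.full(self.score.shape, "", dtype="<U1")
        out[self.score > 0] = "A"
        out[self.score < 0] = "B"
        return out

    @property
    def leading_selected(self) -> bool:
        return self.eig_index == 0


def compartment_score(
    matrix: ContactMatrix,
    chrom: str,
    orientation_track: np.ndarray,
    n_eigs: int = 3,
    min_bins: int = 20,
    use_weights: bool = True,
    sample: str | None = None,
) -> CompartmentTrack:
    """Eigenvector compartment score for one chromosome.

    ``orientation_track`` is a per-bin reference signal on the
    chromosome (length = number of chromosome bins); the returned score
    correlates non-negatively with it.  Requires >= ``min_bins``
    unmasked bins; constant O/E rows raise an error naming the
    chromosome.
    """
    oe, valid = cis_oe_dense(matrix, chrom, use_weights=use_weights)
    n = oe.shape[0]
    orientation_track = np.asarray(orientation_track, dtype=float)
    if orientation_track.shape != (n,):
        raise ValueError(
            f"orientation track has length {len(orientation_track)}, "
            f"expected {n} bins on {chrom}"
        )
    # constant O/E rows (typically all-zero, ultra-sparse bins) carry no
    # correlation signal: mask them rather than poisoning the whole matrix
    idx = np.flatnonzero(valid)
    sub = oe[np.ix_(idx, idx)]
    informative = sub.var(axis=1) > 0
    valid = np.zeros_like(valid)
    valid[idx[informative]] = True
    if valid.sum() < min_bins:
        raise ValueError(
            f"{chrom}: only {int(valid.sum())} informative unmasked bins "
            f"(< {min_bins})"
        )
    sub = sub[np.ix_(informative, informative)]
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(sub)
    if np.isnan(corr).any():
        raise ValueError(
            f"{chrom}: degenerate O/E correlation matrix (constant rows)"
        )
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1][:n_eigs]
    evals, evecs = evals[order], evecs[:, order]
    ref = orientation_track[valid]
    ref = ref - np.nanmean(ref)
    best_k, best_abs = 0, -1.0
    corrs = np.zeros(len(order))
    for k in range(len(order)):
        v = evecs[:, k]
        denom = np.linalg.norm(v - v.mean()) * np.linalg.norm(ref)
        r = float((v - v.mean()) @ ref / denom) if denom > 0 else 0.0
        corrs[k] = r
        if abs(r) > best_abs:
            best_abs, best_k = abs(r), k
    if best_k != 0:
        warnings.warn(
            f"{chrom}: eigenvector {best_k + 1} (not the leading one) best "
            "matches the orientation track; it may track karyotype",
            RuntimeWarning,
            stacklevel=2,
        )
    vec = evecs[:, best_k] * np.sqrt(max(evals[best_k], 0.0))
    if corrs[best_k] < 0:
        vec = -vec
    score = np.full(n, np.nan)
    score[valid] = vec
    return CompartmentTrack(
        bins=matrix.bins,
        chrom=chrom,
        score=score,
        sample=sample or str(matrix.metadata.get("sample", "")),
        eig_index=int(best_k),
        eigenvalues=evals,
    )


@dataclass
class SampleSimilarity:
    """Pairwise compartment-score correlations + sample dendrogram."""

    samples: list[str]
    correlation: np.ndarray  # symmetric, diagonal 1; NaN = undefined pair
    linkage: np.ndarray  # scipy linkage matrix (average, 1 - r distance)

    def clusters(self, k: int) -> np.ndarray:
        return sch.fcluster(self.linkage, t=k, criterion="maxclust")

    def to_newick(self) -> str:
        tree = sch.to_tree(self.linkage)

        def render(node) -> str:
            if node.is_leaf():
                return self.samples[node.id]
            left, right = render(node.left), render(node.right)
            return (
                f"({left}:{node.dist - node.left.dist:.6g},"
                f"{right}:{node.dist - node.right.dist:.6g})"
            )

        return render(tree) + ";"


def compare_tracks(
    tracks: list[CompartmentTrack],
    region: GenomicInterval | None = None,
) -> SampleSimilarity:
    """Correlate compartment tracks pairwise and cluster the samples.

    Pairwise-complete observations: each pair uses bins unmasked in
    both tracks (optionally restricted to ``region``).  Pairs with < 2
    shared bins get a NaN correlation and enter the linkage at the
    maximum distance of 2 with a warning.
    """
    if len(tracks) < 2:
        raise ValueError("need at least two tracks to compare")
    t0 = tracks[0]
    for t in tracks[1:]:
        if t.bins != t0.bins or t.chrom != t0.chrom:
            raise ValueError("all tracks must share a bin table and chromosome")
    scores = np.vstack([t.score for t in tracks])
    if region is not None:
        if region.chrom != t0.chrom:
            raise ValueError("region is not on the tracks' chromosome")
        sl = t0.bins.chrom_slice(t0.chrom)
        idx = t0.bins.overlapping(region) - sl.start
        scores = scores[:, idx]
    m = len(tracks)
    corr = np.eye(m)
    undefined = []
    for a in range(m):
        for b in range(a + 1, m):
            ok = ~np.isnan(scores[a]) & ~np.isnan(scores[b])
            if ok.sum() < 2:
                corr[a, b] = corr[b, a] = np.nan
                undefined.append((a, b))
                continue
            r = np.corrcoef(scores[a, ok], scores[b, ok])[0, 1]
            corr[a, b] = corr[b, a] = r
    if undefined:
        warnings.warn(
            f"{len(undefined)} sample pair(s) share < 2 unmasked bins; "
            "their correlation is undefined and enters the linkage at "
            "maximum distance",
            RuntimeWarning,
            stacklevel=2,
        )
    dist = 1.0 - corr
    dist[np.isnan(dist)] = 2.0
    np.fill_diagonal(dist, 0.0)
    condensed = dist[np.triu_indices(m, k=1)]
    linkage = sch.linkage(condensed, method="average")
    samples = [t.sample or f"sample{k}" for k, t in enumerate(tracks)]
    return SampleSimilarity(samples=samples, correlation=corr, linkage=linkage)


def compartment_at(
    track: CompartmentTrack, interval: GenomicInterval
) -> tuple[float, str]:
    """Mean score and majority A/B label over an interval.

    Returns ``(nan, "unassigned")`` when the interval covers no
    unmasked bin.
    """
    if interval.chrom != track.chrom:
        raise ValueError(
            f"interval {interval} not on track chromosome {track.chrom}"
        )
    sl = track.bins.chrom_slice(track.chrom)
    idx = track.bins.overlapping(interval) - sl.start
    vals = track.score[idx]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        return (float("nan"), "unassigned")
    n_a, n_b = int((vals > 0).sum()), int((vals < 0).sum())
    if n_a == n_b:
        label = "A" if vals.mean() > 0 else ("B" if vals.mean() < 0 else "unassigned")
    else:
        label = "A" if n_a > n_b else "B"
    return (float(vals.mean()), label)
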