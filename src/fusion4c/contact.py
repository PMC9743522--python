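"""Binned contact matrices: data model, COO-text I/O, balancing, coarsening, O/E.

The on-disk format is a deliberately plain COO text dialect::

    #bin_size<TAB>10000
    #chrom<TAB>chr7<TAB>1000000
    #anchor<TAB>chr7<TAB>140790000        (optional; records coarsening phase)
    #meta<TAB>sample<TAB>JPA_2            (optional metadata)
    i<TAB>j<TAB>count                     (global bin ids, i <= j)

Upper triangle only; duplicate and lower-triangle entries are folded on
read.  The writer emits a canonical sorted form so that a read/write
round trip is byte-identical.

Balancing is iterative correction (ICE): per-bin multiplicative weights
that equalize row sums of the weighted symmetric matrix, with the
lowest-coverage bins masked out.  The weights contract matches what a
karyotype-aware normalizer would produce, so externally computed weights
can be attached to a matrix in their place.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .genome import GenomicInterval

__all__ = [
    "BinTable",
    "ContactMatrix",
    "BalanceResult",
    "read_matrix",
    "write_matrix",
    "write_bedgraph",
    "read_bedgraph",
    "balance",
    "coarsen_anchored",
    "observed_expected",
    "cis_oe_dense",
]


class BinTable:
    """Genome-wide tiling of uniform-width bins, optionally phase-anchored.

    The nominal ``bin_size`` applies everywhere except (a) the last bin
    of each chromosome, which may be short, and (b) on an anchored
    chromosome, a short first bin so that one bin boundary falls exactly
    on the anchor position.
    """

    def __init__(
        self,
        chromsizes: list[tuple[str, int]],
        bin_size: int,
        anchor: tuple[str, int] | None = None,
    ):
        if bin_size <= 0:
            raise ValueError("bin_size must be positive")
        self.chromsizes = [(str(c), int(s)) for c, s in chromsizes]
        self.bin_size = int(bin_size)
        self.anchor = (str(anchor[0]), int(anchor[1])) if anchor else None
        self._phase: dict[str, int] = {}
        if self.anchor is not None:
            chrom, pos = self.anchor
            if chrom not in dict(self.chromsizes):
                raise ValueError(f"anchor chromosome {chrom!r} not in table")
            self._phase[chrom] = pos % bin_size

        self._offset: dict[str, int] = {}
        chroms, starts, ends = [], [], []
        cum = 0
        for chrom, length in self.chromsizes:
            self._offset[chrom] = cum
            phase = self._phase.get(chrom, 0)
            edges = [0]
            nxt = phase if phase else bin_size
            while nxt < length:
                edges.append(nxt)
                nxt += bin_size
            edges.append(length)
            for s, e in zip(edges, edges[1:]):
                chroms.append(chrom)
                starts.append(s)
                ends.append(e)
            cum += len(edges) - 1
        self.chrom = np.array(chroms)
        self.start = np.array(starts, dtype=np.int64)
        self.end = np.array(ends, dtype=np.int64)

    @classmethod
    def from_chromsizes(
        cls, chromsizes: list[tuple[str, int]], bin_size: int
    ) -> "BinTable":
        return cls(chromsizes, bin_size)

    def __len__(self) -> int:
        return len(self.start)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, BinTable)
            and self.chromsizes == other.chromsizes
            and self.bin_size == other.bin_size
            and self._phase == other._phase
        )

    def __hash__(self):
        return hash((tuple(self.chromsizes), self.bin_size, tuple(sorted(self._phase.items()))))

    def chrom_offset(self, chrom: str) -> int:
        return self._offset[chrom]

    def n_bins(self, chrom: str) -> int:
        phase = self._phase.get(chrom, 0)
        length = dict(self.chromsizes)[chrom]
        n = -(-(length - phase) // self.bin_size)
        return n + (1 if phase else 0)

    def chrom_slice(self, chrom: str) -> slice:
        off = self._offset[chrom]
        return slice(off, off + self.n_bins(chrom))

    def bin_index(self, chrom: str, pos: int) -> int:
        """Global index of the bin containing ``pos``."""
        length = dict(self.chromsizes)[chrom]
        if not 0 <= pos < length:
            raise ValueError(f"position {chrom}:{pos} outside chromosome")
        phase = self._phase.get(chrom, 0)
        if phase and pos < phase:
            local = 0
        else:
            local = (pos - phase) // self.bin_size + (1 if phase else 0)
        return self._offset[chrom] + local

    def interval(self, i: int) -> GenomicInterval:
        return GenomicInterval(str(self.chrom[i]), int(self.start[i]), int(self.end[i]))

    def overlapping(self, region: GenomicInterval) -> np.ndarray:
        """Global indices of bins overlapping ``region``."""
        sel = (
            (self.chrom == region.chrom)
            & (self.start < region.end)
            & (self.end > region.start)
        )
        return np.flatnonzero(sel)

    def mids(self) -> np.ndarray:
        return (self.start + self.end) / 2.0


@dataclass
class ContactMatrix:
    """Symmetric binned contact map, stored as its upper triangle."""

    bins: BinTable
    mat: sp.csr_matrix  # upper triangle, i <= j
    weights: np.ndarray | None = None  # NaN marks masked bins
    metadata: dict = field(default_factory=dict)

    @classmethod
    def from_coo(
        cls,
        bins: BinTable,
        i: np.ndarray,
        j: np.ndarray,
        count: np.ndarray,
        **metadata,
    ) -> "ContactMatrix":
        i = np.asarray(i, dtype=np.int64)
        j = np.asarray(j, dtype=np.int64)
        count = np.asarray(count)
        if count.size and count.min() < 0:
            raise ValueError("negative contact counts")
        n = len(bins)
        if i.size and (i.min() < 0 or max(i.max(), j.max()) >= n):
            raise ValueError("bin index out of range")
        ii, jj = np.minimum(i, j), np.maximum(i, j)  # fold to upper triangle
        m = sp.coo_matrix((count, (ii, jj)), shape=(n, n)).tocsr()
        m.sum_duplicates()
        m.eliminate_zeros()
        return cls(bins=bins, mat=m, metadata=dict(metadata))

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def total(self) -> float:
        return float(self.mat.sum())

    def symmetric(self) -> sp.csr_matrix:
        """Full symmetric matrix; the diagonal is counted once."""
        upper = self.mat.astype(np.float64)
        return upper + upper.T - sp.diags(upper.diagonal())

    def coverage(self) -> np.ndarray:
        """Per-bin marginal (row sum of the symmetric matrix)."""
        return np.asarray(self.symmetric().sum(axis=1)).ravel()

    def balanced_symmetric(self) -> sp.csr_matrix:
        if self.weights is None:
            raise ValueError("matrix has no balancing weights; run balance() first")
        w = np.nan_to_num(self.weights, nan=0.0)
        d = sp.diags(w)
        return d @ self.symmetric() @ d


# ---------------------------------------------------------------------------
# COO text reader / writer


def _format_count(x) -> str:
    xf = float(x)
    if xf.is_integer() and abs(xf) < 1e15:
        return str(int(xf))
    return repr(xf)


def write_matrix(matrix: ContactMatrix, path) -> None:
    """Write canonical sorted COO text (byte-stable for fixed content)."""
    coo = matrix.mat.tocoo()
    order = np.lexsort((coo.col, coo.row))
    with open(path, "w") as fh:
        fh.write(f"#bin_size\t{matrix.bins.bin_size}\n")
        for chrom, length in matrix.bins.chromsizes:
            fh.write(f"#chrom\t{chrom}\t{length}\n")
        if matrix.bins.anchor is not None:
            fh.write(f"#anchor\t{matrix.bins.anchor[0]}\t{matrix.bins.anchor[1]}\n")
        for key in sorted(matrix.metadata):
            fh.write(f"#meta\t{key}\t{matrix.metadata[key]}\n")
        for k in order:
            fh.write(
                f"{coo.row[k]}\t{coo.col[k]}\t{_format_count(coo.data[k])}\n"
            )


def read_matrix(path) -> ContactMatrix:
    """Read COO text; folds lower-triangle entries, sums duplicates."""
    bin_size = None
    chromsizes: list[tuple[str, int]] = []
    anchor = None
    metadata: dict = {}
    ii, jj, cc = [], [], []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if line.startswith("#"):
                tag = fields[0][1:]
                if tag == "bin_size":
                    bin_size = int(fields[1])
                elif tag == "chrom":
                    chromsizes.append((fields[1], int(fields[2])))
                elif tag == "anchor":
                    anchor = (fields[1], int(fields[2]))
                elif tag == "meta":
                    metadata[fields[1]] = fields[2]
                else:
                    raise ValueError(f"{path}:{line_no}: unknown header {tag!r}")
                continue
            if len(fields) != 3:
                raise ValueError(f"{path}:{line_no}: expected 3 columns")
            ii.append(int(fields[0]))
            jj.append(int(fields[1]))
            cc.append(float(fields[2]))
    if bin_size is None or not chromsizes:
        raise ValueError(f"{path}: missing #bin_size or #chrom headers")
    bins = BinTable(chromsizes, bin_size, anchor=anchor)
    return ContactMatrix.from_coo(
        bins,
        np.array(ii, dtype=np.int64),
        np.array(jj, dtype=np.int64),
        np.array(cc),
        **metadata,
    )


def write_bedgraph(bins: BinTable, values: np.ndarray, path, *, skip_nan=True) -> None:
    """Per-bin signal track (weights, compartment scores, labels) as bedGraph."""
    values = np.asarray(values, dtype=float)
    if values.shape != (len(bins),):
        raise ValueError("values length must match bin table")
    with open(path, "w") as fh:
        for k in range(len(bins)):
            if skip_nan and np.isnan(values[k]):
                continue
            fh.write(
                f"{bins.chrom[k]}\t{bins.start[k]}\t{bins.end[k]}\t"
                f"{_format_count(values[k])}\n"
            )


def read_bedgraph(path, bins: BinTable) -> np.ndarray:
    """Read a bedGraph onto ``bins``; uncovered bins become NaN."""
    out = np.full(len(bins), np.nan)
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, _end, value = line.split("\t")[:4]
            out[bins.bin_index(chrom, int(start))] = float(value)
    return out


# ---------------------------------------------------------------------------
# Balancing (iterative correction)


@dataclass
class BalanceResult:
    weights: np.ndarray  # unit mean over unmasked bins; NaN where masked
    converged: bool
    n_iter: int
    rel_var: float  # final relative variance of weighted row sums


def balance(
    matrix: ContactMatrix,
    max_iter: int = 200,
    tol: float = 1e-6,
    min_coverage_quantile: float = 0.02,
) -> BalanceResult:
    """Iterative-correction weights equalizing weighted row sums.

    Bins in the lowest ``min_coverage_quantile`` of coverage (and all
    zero-coverage bins) are masked to NaN.  Weights are normalized to
    unit mean over unmasked bins; the balanced count for pair (i, j) is
    ``count * w_i * w_j``.  Non-convergence is reported, never silent.
    """
    if matrix.mat.nnz == 0:
        raise ValueError("cannot balance an empty matrix")
    sym = matrix.symmetric().astype(float)
    coverage = np.asarray(sym.sum(axis=1)).ravel()
    threshold = np.quantile(coverage, min_coverage_quantile)
    masked = (coverage <= 0) | (coverage < threshold)
    if masked.all():
        raise ValueError("all bins masked by the coverage filter")

    keep = ~masked
    w = np.ones(len(coverage))
    w[masked] = 0.0
    converged = False
    n_iter = 0
    rel_var = np.inf
    for n_iter in range(1, max_iter + 1):
        s = w * (sym @ w)
        sk = s[keep]
        mean = sk.mean()
        rel_var = float(sk.var() / mean**2) if mean > 0 else np.inf
        if rel_var <= tol:
            converged = True
            break
        w[keep] /= np.sqrt(sk / mean)
    if not converged:
        warnings.warn(
            f"balancing did not converge in {max_iter} iterations "
            f"(relative variance {rel_var:.3g} > tol {tol:.3g})",
            RuntimeWarning,
            stacklevel=2,
        )
    w[keep] /= w[keep].mean()
    w[masked] = np.nan
    matrix.weights = w
    return BalanceResult(weights=w, converged=converged, n_iter=n_iter, rel_var=rel_var)


# ---------------------------------------------------------------------------
# Anchored coarsening


def coarsen_anchored(
    matrix: ContactMatrix,
    factor: int,
    anchor: tuple[str, int] | None = None,
) -> ContactMatrix:
    """Sum fine bins into coarse bins, phasing edges at a breakpoint anchor.

    On the anchor chromosome the coarse edges are shifted so that one
    boundary coincides exactly with ``anchor`` — the rule used to keep a
    fusion's retained and lost gene terminals in different coarse bins.
    The first coarse bin on that chromosome may therefore be short.
    Counts are summed; the genome-wide total is conserved exactly.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    fine = matrix.bins
    if fine._phase:
        raise ValueError("input matrix must have an unphased uniform bin table")
    if anchor is not None:
        chrom, pos = anchor
        if pos % fine.bin_size:
            raise ValueError(
                f"anchor position {pos} is not aligned to the fine bin size "
                f"{fine.bin_size}; snap it to a fine-bin boundary first"
            )
    coarse_bins = BinTable(
        fine.chromsizes, fine.bin_size * factor, anchor=anchor
    )
    # map each fine bin to the coarse bin containing its start
    fine_to_coarse = np.empty(len(fine), dtype=np.int64)
    for k in range(len(fine)):
        fine_to_coarse[k] = coarse_bins.bin_index(str(fine.chrom[k]), int(fine.start[k]))
    coo = matrix.mat.tocoo()
    out = ContactMatrix.from_coo(
        coarse_bins,
        fine_to_coarse[coo.row],
        fine_to_coarse[coo.col],
        coo.data,
        **matrix.metadata,
    )
    return out


# ---------------------------------------------------------------------------
# Observed / expected


def _chrom_dense(matrix: ContactMatrix, chrom: str, use_weights: bool) -> np.ndarray:
    sl = matrix.bins.chrom_slice(chrom)
    block = matrix.symmetric()[sl, sl].toarray().astype(float)
    if use_weights:
        if matrix.weights is None:
            raise ValueError("use_weights=True but matrix is not balanced")
        w = matrix.weights[sl]
        block = block * np.outer(w, w)  # NaN weights poison masked rows/cols
    return block


def _expected_by_separation(block: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Mean (balanced) count at each diagonal separation over valid pairs."""
    n = block.shape[0]
    expected = np.full(n, np.nan)
    for d in range(n):
        rows = np.arange(0, n - d)
        cols = rows + d
        ok = valid[rows] & valid[cols]
        if ok.any():
            expected[d] = np.nanmean(block[rows[ok], cols[ok]])
    return expected


def cis_oe_dense(
    matrix: ContactMatrix, chrom: str, use_weights: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Dense cis observed/expected block and its per-bin validity mask.

    Masked bins (NaN weight, or zero coverage when unweighted) become
    NaN rows/columns.  Entries on a zero-expected diagonal are NaN.
    """
    sl = matrix.bins.chrom_slice(chrom)
    block = _chrom_dense(matrix, chrom, use_weights)
    if use_weights:
        valid = ~np.isnan(matrix.weights[sl])
    else:
        # raw O/E: expectation averages over every pair at a separation
        valid = np.ones(block.shape[0], dtype=bool)
    expected = _expected_by_separation(block, valid)
    n = block.shape[0]
    sep = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    with np.errstate(invalid="ignore", divide="ignore"):
        oe = block / expected[sep]
        oe[expected[sep] == 0] = np.nan
    oe[~valid, :] = np.nan
    oe[:, ~valid] = np.nan
    return oe, valid


def observed_expected(matrix: ContactMatrix, use_weights: bool = True) -> ContactMatrix:
    """Cis O/E transform of a whole matrix (trans entries are dropped).

    Every stored cis entry is divided by the mean (balanced) count at
    its diagonal separation within its chromosome; zero-expected
    diagonals yield NaN entries rather than division errors.
    """
    coo = matrix.mat.tocoo()
    data = np.full(coo.nnz, np.nan)
    keep = np.zeros(coo.nnz, dtype=bool)
    row_chrom = matrix.bins.chrom[coo.row]
    for chrom, _ in matrix.bins.chromsizes:
        sl = matrix.bins.chrom_slice(chrom)
        block = _chrom_dense(matrix, chrom, use_weights)
        if use_weights:
            valid = ~np.isnan(matrix.weights[sl])
        else:
            valid = np.ones(block.shape[0], dtype=bool)
        expected = _expected_by_separation(block, valid)
        sel = (row_chrom == chrom) & (matrix.bins.chrom[coo.col] == chrom)
        idx = np.flatnonzero(sel)
        if idx.size == 0:
            continue
        li, lj = coo.row[idx] - sl.start, coo.col[idx] - sl.start
        exp_here = expected[np.abs(lj - li)]
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = block[li, lj] / exp_here
        vals[exp_here == 0] = np.nan
        data[idx] = vals
        keep[idx] = True
    out = sp.coo_matrix(
        (data[keep], (coo.row[keep], coo.col[keep])), shape=matrix.mat.shape
    ).tocsr()
    return ContactMatrix(
        bins=matrix.bins, mat=out, weights=matrix.weights, metadata=dict(matrix.metadata)
    )
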