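"""Multi-caller SV consensus, matched-normal filtering and fusion aggregation.

The consensus rule mirrors common practice for heterogeneous caller
panels: two calls describe the same rearrangement when their chromosome
pairs match and *both* paired breakpoints fall within a tolerance
(default ±1000 bp, boundary inclusive) of each other.  SV type is *not*
required to agree — different callers label the same junction DUP, TRA
or BND.  Groups are the connected components of this relation
(single-linkage), each summarized by the medoid member.  Downstream
filters keep groups supported by at least ``min_callers`` callers and
larger than ``min_size`` (trans calls have no size and pass by
default), and a matched-normal subtraction flags groups also present in
the normal sample as germline.

RNA fusion calls from several callers are unioned by unordered gene
pair (union-then-targeted-review, not intersection): a fusion seen by a
single caller among hundreds of raw calls survives a priority-gene
review list, which is how low-support but clinically central fusions
(e.g. BRAF partners) are retained.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SVCall",
    "ConsensusSV",
    "FusionCall",
    "match_calls",
    "filter_consensus",
    "subtract_normal",
    "aggregate_fusions",
    "annotate_breakpoints",
    "read_bedpe",
    "write_bedpe",
    "read_gene_bed",
]

SV_TYPES = ("DEL", "DUP", "INV", "TRA", "BND")


def _chrom_key(chrom: str):
    """Natural ordering: chr2 < chr10 < chrX."""
    m = re.match(r"(?:chr)?(\d+)$", chrom)
    if m:
        return (0, int(m.group(1)), "")
    return (1, 0, chrom)


@dataclass(frozen=True)
class SVCall:
    """One caller's breakpoint pair."""

    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    sv_type: str
    caller: str
    sample: str = ""
    quality: float | None = None
    name: str = ""
    truth_id: int | None = None  # simulator provenance; None for real/FP calls

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown sv_type {self.sv_type!r}")
        if self.pos1 < 0 or self.pos2 < 0:
            raise ValueError("negative breakpoint position")

    @property
    def breakpoint1(self) -> tuple[str, int]:
        return (self.chrom1, self.pos1)

    @property
    def breakpoint2(self) -> tuple[str, int]:
        return (self.chrom2, self.pos2)

    @property
    def is_trans(self) -> bool:
        return self.chrom1 != self.chrom2

    @property
    def size(self) -> int | None:
        """bp span for cis calls; undefined (None) for trans calls."""
        return None if self.is_trans else self.pos2 - self.pos1

    def canonical(self) -> "SVCall":
        """Order breakpoints: chrom1 <= chrom2 (natural), pos1 <= pos2 cis."""
        k1, k2 = _chrom_key(self.chrom1), _chrom_key(self.chrom2)
        if k1 > k2 or (k1 == k2 and self.pos1 > self.pos2):
            return replace(
                self,
                chrom1=self.chrom2, pos1=self.pos2,
                chrom2=self.chrom1, pos2=self.pos1,
            )
        return self

    def sort_key(self):
        return (_chrom_key(self.chrom1), _chrom_key(self.chrom2),
                self.pos1, self.pos2, self.caller, self.name)


@dataclass
class ConsensusSV:
    """A group of mutually matching calls from one or more callers."""

    member_calls: list[SVCall]
    representative: SVCall  # medoid member
    somatic: bool | None = None  # None until matched-normal subtraction

    @property
    def callers(self) -> tuple[str, ...]:
        return tuple(sorted({c.caller for c in self.member_calls}))

    @property
    def n_callers(self) -> int:
        return len(self.callers)

    @property
    def is_trans(self) -> bool:
        return self.representative.is_trans

    @property
    def size(self) -> int | None:
        return self.representative.size

    @property
    def truth_ids(self) -> set[int]:
        return {c.truth_id for c in self.member_calls if c.truth_id is not None}


def _pair_matches(a: SVCall, b: SVCall, tolerance: int) -> bool:
    return (
        a.chrom1 == b.chrom1
        and a.chrom2 == b.chrom2
        and abs(a.pos1 - b.pos1) <= tolerance
        and abs(a.pos2 - b.pos2) <= tolerance
    )


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _medoid(calls: list[SVCall]) -> SVCall:
    """Member minimizing summed breakpoint distance; ties by canonical order."""
    best = None
    for c in sorted(calls, key=SVCall.sort_key):
        dist = sum(
            abs(c.pos1 - o.pos1) + abs(c.pos2 - o.pos2) for o in calls
        )
        if best is None or dist < best[0]:
            best = (dist, c)
    return best[1]


def match_calls(
    callsets: dict[str, list[SVCall]] | list[list[SVCall]],
    tolerance: int = 1000,
) -> list[ConsensusSV]:
    """Single-linkage grouping under the double-breakpoint tolerance rule.

    Two calls are linked when chromosome pairs match and both
    |pos1a − pos1b| and |pos2a − pos2b| are <= ``tolerance``
    (inclusive).  Connected components become ``ConsensusSV`` groups.
    Caller order is irrelevant to the result.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    if isinstance(callsets, dict):
        lists = [callsets[k] for k in callsets]
    else:
        lists = list(callsets)
    calls = sorted(
        (c.canonical() for lst in lists for c in lst), key=SVCall.sort_key
    )
    n = len(calls)
    uf = _UnionFind(n)
    # group by chromosome pair, sweep sorted by pos1
    by_pair: dict[tuple[str, str], list[int]] = {}
    for idx, c in enumerate(calls):
        by_pair.setdefault((c.chrom1, c.chrom2), []).append(idx)
    for indices in by_pair.values():
        indices.sort(key=lambda k: calls[k].pos1)
        for a_rank, ia in enumerate(indices):
            for ib in indices[a_rank + 1:]:
                if calls[ib].pos1 - calls[ia].pos1 > tolerance:
                    break
                if abs(calls[ia].pos2 - calls[ib].pos2) <= tolerance:
                    uf.union(ia, ib)
    groups: dict[int, list[SVCall]] = {}
    for idx, c in enumerate(calls):
        groups.setdefault(uf.find(idx), []).append(c)
    out = [
        ConsensusSV(member_calls=members, representative=_medoid(members))
        for members in groups.values()
    ]
    out.sort(key=lambda g: g.representative.sort_key())
    return out


def filter_consensus(
    consensus: list[ConsensusSV],
    min_size: int = 10_000,
    min_callers: int = 2,
    keep_trans: bool = True,
) -> list[ConsensusSV]:
    """Keep groups with enough caller support and (strictly) enough size.

    The size filter is strict (> ``min_size``); trans groups have no
    size and pass the size criterion when ``keep_trans``.  Ordering is
    preserved.
    """
    out = []
    for g in consensus:
        if g.n_callers < min_callers:
            continue
        if g.is_trans:
            if not keep_trans:
                continue
        elif g.size <= min_size:
            continue
        out.append(g)
    return out


def subtract_normal(
    tumor: list[ConsensusSV],
    normal: dict[str, list[SVCall]] | list[list[SVCall]],
    tolerance: int = 1000,
) -> list[ConsensusSV]:
    """Flag tumor groups also present in the matched normal as germline.

    A group is germline when any normal call matches its representative
    under the same double-breakpoint rule; everything else is somatic.
    Returns the same groups with ``somatic`` set.
    """
    if isinstance(normal, dict):
        normal_calls = [c.canonical() for lst in normal.values() for c in lst]
    else:
        normal_calls = [c.canonical() for lst in normal for c in lst]
    for g in tumor:
        rep = g.representative
        g.somatic = not any(
            _pair_matches(rep, nc, tolerance) for nc in normal_calls
        )
    return tumor


# ---------------------------------------------------------------------------
# RNA fusion aggregation

FUSION_COLUMNS = [
    "gene5", "gene3", "chrom5", "pos5", "chrom3", "pos3",
    "split_reads", "spanning_pairs", "caller",
]


@dataclass
class FusionCall:
    """Gene-pair-level fusion record aggregated across RNA callers."""

    gene5: str
    gene3: str
    callers: list[str] = field(default_factory=list)
    breakpoints: dict[str, tuple[str, int, str, int]] = field(default_factory=dict)
    read_support: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def n_callers(self) -> int:
        return len(set(self.callers))

    @property
    def gene_pair(self) -> frozenset:
        return frozenset((self.gene5, self.gene3))


def aggregate_fusions(
    rna_callsets: dict[str, "pd.DataFrame | str"],
    breakpoint_tolerance: int = 100_000,
    priority_genes: set[str] | None = None,
) -> tuple[list[FusionCall], int]:
    """Union RNA fusion calls across callers by unordered gene pair.

    ``rna_callsets`` maps caller name to a TSV path or DataFrame with
    columns gene5, gene3, chrom5, pos5, chrom3, pos3, split_reads,
    spanning_pairs.  Malformed rows (missing genes, unparsable
    positions, gene5 == gene3 read-throughs) are skipped and counted.
    ``priority_genes`` subsets the union to pairs touching the list —
    union-then-review, so a single-caller call survives.  Returns
    (fusions, n_skipped).
    """
    merged: dict[frozenset, FusionCall] = {}
    n_skipped = 0
    for caller, table in rna_callsets.items():
        if isinstance(table, (str, bytes)) or hasattr(table, "__fspath__"):
            table = pd.read_csv(table, sep="\t", dtype=str)
        for _, row in table.iterrows():
            try:
                g5, g3 = str(row["gene5"]).strip(), str(row["gene3"]).strip()
                if not g5 or not g3 or g5 == "nan" or g3 == "nan" or g5 == g3:
                    raise ValueError
                bp = (
                    str(row["chrom5"]), int(float(row["pos5"])),
                    str(row["chrom3"]), int(float(row["pos3"])),
                )
                support = (
                    int(float(row.get("split_reads", 0) or 0)),
                    int(float(row.get("spanning_pairs", 0) or 0)),
                )
            except (ValueError, TypeError, KeyError):
                n_skipped += 1
                continue
            key = frozenset((g5, g3))
            rec = merged.get(key)
            if rec is None:
                rec = FusionCall(gene5=g5, gene3=g3)
                merged[key] = rec
            rec.callers.append(caller)
            rec.breakpoints[caller] = bp
            rec.read_support[caller] = support
    fusions = sorted(merged.values(), key=lambda f: (f.gene5, f.gene3))
    if priority_genes is not None:
        fusions = [
            f for f in fusions if priority_genes & {f.gene5, f.gene3}
        ]
    # collapse per-pair breakpoints that agree within tolerance (report only)
    for f in fusions:
        pts = list(f.breakpoints.values())
        distinct = []
        for p in pts:
            if not any(
                p[0] == q[0] and p[2] == q[2]
                and abs(p[1] - q[1]) <= breakpoint_tolerance
                and abs(p[3] - q[3]) <= breakpoint_tolerance
                for q in distinct
            ):
                distinct.append(p)
        f.n_distinct_junctions = len(distinct)
    return fusions, n_skipped


# ---------------------------------------------------------------------------
# Gene annotation of breakpoints


@dataclass
class GeneModel:
    name: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] | None = None  # coordinate-sorted


def read_gene_bed(path) -> list[GeneModel]:
    """Gene models from BED6 or BED12 (block fields give exon structure)."""
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5] if len(f) > 5 else "+"
            exons = None
            if len(f) >= 12:
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offs = [int(x) for x in f[11].rstrip(",").split(",")]
                exons = [(start + o, start + o + s) for o, s in zip(offs, sizes)]
            genes.append(GeneModel(name, chrom, start, end, strand, exons))
    return genes


def _locate_in_gene(gene: GeneModel, pos: int) -> str:
    """'exon K' / 'intron K' in transcript numbering, or 'gene body'."""
    if gene.exons is None:
        return "gene body"
    m = len(gene.exons)
    for k, (s, e) in enumerate(gene.exons, start=1):
        if s <= pos < e:
            idx = k if gene.strand == "+" else m + 1 - k
            return f"exon {idx}"
    for k in range(m - 1):
        if gene.exons[k][1] <= pos < gene.exons[k + 1][0]:
            idx = k + 1 if gene.strand == "+" else m - 1 - k
            return f"intron {idx}"
    return "gene body"


# retained flank at each breakpoint implied by the junction geometry:
# a deletion joins the left flank of bp1 to the right flank of bp2; a
# tandem duplication's internal junction joins the left flank of bp2
# (end of the copy) to the right flank of bp1 (start of the next copy).
_RETAINED_SIDES = {
    "DEL": ("left", "right"),
    "DUP": ("right", "left"),
    "INV": ("left", "left"),
    "TRA": ("left", "right"),
    "BND": ("left", "right"),
}


def _retains_5prime(strand: str, side: str) -> bool:
    return (strand == "+" and side == "left") or (strand == "-" and side == "right")


@dataclass
class BreakpointAnnotation:
    breakpoint: tuple[str, int]
    genes: list[tuple[str, str, str]]  # (name, strand, 'exon K'/'intron K'/...)
    intergenic: bool


@dataclass
class FusionAnnotation:
    bp1: BreakpointAnnotation
    bp2: BreakpointAnnotation
    gene5: str | None  # predicted 5' fusion partner
    gene3: str | None
    note: str = ""


def annotate_breakpoints(
    call: "SVCall | ConsensusSV",
    genes: list[GeneModel],
) -> FusionAnnotation:
    """Label both breakpoints with genes/introns and predict 5'→3' order.

    The 5' partner is the gene whose 5' portion is retained by the
    junction (given its strand and the retained flank for the SV type);
    the 3' partner retains its 3' portion.  Intergenic breakpoints are
    labelled, never an error.
    """
    if isinstance(call, ConsensusSV):
        call = call.representative
    call = call.canonical()
    sides = _RETAINED_SIDES[call.sv_type]
    anns = []
    g5 = g3 = None
    for (chrom, pos), side in zip((call.breakpoint1, call.breakpoint2), sides):
        hits = [
            (g.name, g.strand, _locate_in_gene(g, pos))
            for g in genes
            if g.chrom == chrom and g.start <= pos < g.end
        ]
        anns.append(BreakpointAnnotation((chrom, pos), hits, intergenic=not hits))
        for name, strand, _ in hits:
            if _retains_5prime(strand, side):
                g5 = g5 or name
            else:
                g3 = g3 or name
    note = ""
    if g5 is None or g3 is None:
        note = "incomplete fusion orientation (intergenic or one-sided hit)"
    return FusionAnnotation(bp1=anns[0], bp2=anns[1], gene5=g5, gene3=g3, note=note)


# ---------------------------------------------------------------------------
# BEDPE I/O


def write_bedpe(calls_or_groups, path) -> None:
    """SV calls or consensus groups as 10+3-column BEDPE."""
    with open(path, "w") as fh:
        for item in calls_or_groups:
            if isinstance(item, ConsensusSV):
                c = item.representative
                name = ",".join(item.callers)
                extra = f"\t{c.sv_type}\t{c.sample}\t{_somatic_str(item.somatic)}"
            else:
                c = item.canonical()
                name = c.name or "."
                extra = f"\t{c.sv_type}\t{c.sample}\t{c.caller}"
            score = "." if c.quality is None else f"{c.quality:g}"
            fh.write(
                f"{c.chrom1}\t{c.pos1}\t{c.pos1 + 1}\t"
                f"{c.chrom2}\t{c.pos2}\t{c.pos2 + 1}\t"
                f"{name}\t{score}\t.\t.{extra}\n"
            )


def _somatic_str(flag: bool | None) -> str:
    return "." if flag is None else ("somatic" if flag else "germline")


def read_bedpe(path, caller: str = "", sample: str = "") -> list[SVCall]:
    calls = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            sv_type = f[10] if len(f) > 10 else "BND"
            calls.append(
                SVCall(
                    chrom1=f[0], pos1=int(f[1]),
                    chrom2=f[3], pos2=int(f[4]),
                    sv_type=sv_type,
                    caller=f[12] if len(f) > 12 else caller,
                    sample=f[11] if len(f) > 11 else sample,
                    name=f[6] if len(f) > 6 and f[6] != "." else "",
                ).canonical()
            )
    return calls
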