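"""Reference and rearranged (derived) genome models.

A derived genome is an ordered walk of reference segments, one walk per
derived chromosome.  Rearrangement events are expressed as *edits*: a
reference interval is replaced by zero or more (interval, orientation)
segments, possibly taken from another chromosome.  This covers the event
grammar used throughout the package:

* ``tandem_duplication`` — head-to-tail duplication of a segment (the
  canonical KIAA1549-BRAF mechanism at 7q34);
* ``deletion`` — loss of a segment (FAM131B-BRAF-style);
* ``insertion_translocation`` — a segment is lost and a segment from
  another chromosome is inserted in its place (the TOP2B-BRAF mechanism:
  a 151-kb loss on chromosome 7 replaced by a 263-kb insertion from
  chromosome 3);
* ``balanced_translocation`` — reciprocal exchange of two chromosome
  tails.

All coordinates are 0-based half-open.  Breakpoints must be aligned to
the simulator bin grid: downstream analysis is binned, so sub-bin
breakpoints carry no extra information here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EVENT_TYPES = (
    "tandem_duplication",
    "deletion",
    "insertion_translocation",
    "balanced_translocation",
)

FORWARD = "forward"
INVERTED = "inverted"


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self}")
        if self.end <= self.start:
            raise ValueError(f"empty or inverted interval: {self}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class SVEvent:
    """One structural-variant event on the reference genome.

    ``intervals`` holds one interval for ``tandem_duplication`` and
    ``deletion``; for ``insertion_translocation`` it holds (deleted
    target interval, inserted source interval on another chromosome);
    for ``balanced_translocation`` it holds the two exchanged chromosome
    tails.  ``orientation`` applies to the inserted/duplicated copy.
    """

    event_type: str
    intervals: tuple[GenomicInterval, ...]
    orientation: str = FORWARD
    name: str = ""

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        if self.orientation not in (FORWARD, INVERTED):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        n_expected = 1 if self.event_type in ("tandem_duplication", "deletion") else 2
        if len(self.intervals) != n_expected:
            raise ValueError(
                f"{self.event_type} takes {n_expected} interval(s), "
                f"got {len(self.intervals)}"
            )
        if self.event_type in ("insertion_translocation", "balanced_translocation"):
            a, b = self.intervals
            if a.chrom == b.chrom:
                raise ValueError(
                    f"{self.event_type} intervals must be on different "
                    f"chromosomes, both on {a.chrom}"
                )

    def breakpoint_pair(self) -> tuple[tuple[str, int], tuple[str, int]]:
        """Junction summary as a canonical breakpoint pair.

        For cis events this is (start, end) of the rearranged segment;
        for trans events, the two fusion-junction positions.
        """
        if self.event_type in ("tandem_duplication", "deletion"):
            iv = self.intervals[0]
            return (iv.chrom, iv.start), (iv.chrom, iv.end)
        if self.event_type == "insertion_translocation":
            target, source = self.intervals
            return (target.chrom, target.start), (source.chrom, source.start)
        a, b = self.intervals
        return (a.chrom, a.start), (b.chrom, b.start)

    @property
    def sv_type(self) -> str:
        return {
            "tandem_duplication": "DUP",
            "deletion": "DEL",
            "insertion_translocation": "TRA",
            "balanced_translocation": "TRA",
        }[self.event_type]


@dataclass
class DerivedGenome:
    """A rearranged genome as per-chromosome walks of reference segments.

    ``segments[chrom]`` is the ordered list of ``(GenomicInterval,
    orientation)`` whose concatenation spells the derived chromosome.
    The identity genome (no events) has one forward segment per
    chromosome spanning it entirely.
    """

    reference: list[tuple[str, int]]
    bin_size: int
    segments: dict[str, list[tuple[GenomicInterval, str]]]
    events: list[SVEvent] = field(default_factory=list)

    # ---- reference binning (must agree with contact.BinTable.from_chromsizes)

    def _ref_nbins(self) -> dict[str, int]:
        return {c: -(-length // self.bin_size) for c, length in self.reference}

    def _ref_offsets(self) -> dict[str, int]:
        off, cum = {}, 0
        for c, n in self._ref_nbins().items():
            off[c] = cum
            cum += n
        return off

    @property
    def n_reference_bins(self) -> int:
        return sum(self._ref_nbins().values())

    def derived_lengths(self) -> dict[str, int]:
        return {
            c: sum(len(iv) for iv, _ in segs) for c, segs in self.segments.items()
        }

    def liftover(self) -> dict[str, np.ndarray]:
        """Per derived chromosome: derived bin index -> global reference bin.

        Because segment boundaries are bin-aligned, every derived bin
        lies inside exactly one segment and maps to exactly one
        reference bin.  Reference bins covered by several derived
        segments (duplications) appear multiple times.
        """
        offsets = self._ref_offsets()
        out: dict[str, np.ndarray] = {}
        for chrom, segs in self.segments.items():
            parts = []
            for k, (iv, orient) in enumerate(segs):
                if k < len(segs) - 1 and len(iv) % self.bin_size:
                    raise ValueError(
                        f"non-terminal segment {iv} not a whole number of bins"
                    )
                first = offsets[iv.chrom] + iv.start // self.bin_size
                nb = -(-len(iv) // self.bin_size)
                bins = np.arange(first, first + nb)
                if orient == INVERTED:
                    bins = bins[::-1]
                parts.append(bins)
            out[chrom] = (
                np.concatenate(parts) if parts else np.empty(0, dtype=int)
            )
        return out

    def reference_to_derived(self) -> dict[int, list[tuple[str, int]]]:
        """Inverse map: global reference bin -> [(derived chrom, derived bin)]."""
        inv: dict[int, list[tuple[str, int]]] = {}
        for chrom, ref_bins in self.liftover().items():
            for d, r in enumerate(ref_bins):
                inv.setdefault(int(r), []).append((chrom, d))
        return inv


def _check_aligned(iv: GenomicInterval, chrom_len: int, bin_size: int) -> None:
    if iv.end > chrom_len:
        raise ValueError(f"interval {iv} extends past chromosome end {chrom_len}")
    if iv.start % bin_size:
        raise ValueError(f"interval start not bin-aligned: {iv} (bin {bin_size})")
    if iv.end % bin_size and iv.end != chrom_len:
        raise ValueError(f"interval end not bin-aligned: {iv} (bin {bin_size})")
    if len(iv) < bin_size:
        raise ValueError(f"interval {iv} narrower than one bin ({bin_size})")


def build_derived_genome(
    reference: list[tuple[str, int]],
    events: list[SVEvent],
    bin_size: int,
) -> DerivedGenome:
    """Apply SV events to a reference genome and return the derived walk.

    Events must be non-overlapping on the reference after bin alignment;
    a colliding pair is rejected with both events named.  Balanced-
    translocation tails must run to their chromosome ends.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    chrom_len = dict(reference)
    if len(chrom_len) != len(reference):
        raise ValueError("duplicate chromosome names in reference")

    # per-chromosome edit list: (replaced interval, replacement segments, event)
    Edit = tuple[GenomicInterval, list[tuple[GenomicInterval, str]], SVEvent]
    edits: dict[str, list[Edit]] = {c: [] for c, _ in reference}

    for ev in events:
        for iv in ev.intervals:
            if iv.chrom not in chrom_len:
                raise ValueError(f"unknown chromosome {iv.chrom!r} in event {ev}")
            _check_aligned(iv, chrom_len[iv.chrom], bin_size)
        if ev.event_type == "tandem_duplication":
            (iv,) = ev.intervals
            edits[iv.chrom].append((iv, [(iv, FORWARD), (iv, ev.orientation)], ev))
        elif ev.event_type == "deletion":
            (iv,) = ev.intervals
            edits[iv.chrom].append((iv, [], ev))
        elif ev.event_type == "insertion_translocation":
            target, source = ev.intervals
            edits[target.chrom].append((target, [(source, ev.orientation)], ev))
        else:  # balanced_translocation
            tail_a, tail_b = ev.intervals
            for tail in (tail_a, tail_b):
                if tail.end != chrom_len[tail.chrom]:
                    raise ValueError(
                        f"balanced translocation tail {tail} must reach the "
                        f"chromosome end ({chrom_len[tail.chrom]})"
                    )
            edits[tail_a.chrom].append((tail_a, [(tail_b, ev.orientation)], ev))
            edits[tail_b.chrom].append((tail_b, [(tail_a, ev.orientation)], ev))

    segments: dict[str, list[tuple[GenomicInterval, str]]] = {}
    for chrom, length in reference:
        chrom_edits = sorted(edits[chrom], key=lambda e: e[0].start)
        for (iv1, _, ev1), (iv2, _, ev2) in zip(chrom_edits, chrom_edits[1:]):
            if iv1.end > iv2.start:
                raise ValueError(
                    f"overlapping events on {chrom}: {ev1.event_type} at {iv1} "
                    f"collides with {ev2.event_type} at {iv2}"
                )
        walk: list[tuple[GenomicInterval, str]] = []
        cursor = 0
        for iv, replacement, _ in chrom_edits:
            if iv.start > cursor:
                walk.append((GenomicInterval(chrom, cursor, iv.start), FORWARD))
            walk.extend(replacement)
            cursor = iv.end
        if cursor < length:
            walk.append((GenomicInterval(chrom, cursor, length), FORWARD))
        segments[chrom] = walk

    return DerivedGenome(
        reference=list(reference),
        bin_size=bin_size,
        segments=segments,
        events=list(events),
    )
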