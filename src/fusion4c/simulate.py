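"""Synthetic Hi-C maps and SV/fusion call sets with known ground truth.

The contact-map generator works in *derived* (rearranged) coordinates:
expected counts follow a power-law distance decay for cis pairs, a flat
low rate for trans pairs, and an optional within-compartment boost for
pairs sharing a planted A/B label.  Counts are Poisson-sampled at a
configured total depth, then mapped back through the derived→reference
lift-over — so a rearrangement leaves exactly the ectopic-contact
footprint (e.g. the butterfly of elevated counts between duplication
flanks) that a reference-aligned map of a rearranged tumor genome shows.
Duplicated reference bins accumulate the contributions of all their
derived copies.

The call-set generator emulates a panel of SV callers: per caller, each
true junction is reported with probability ``1 − dropout``, both
breakpoints independently jittered with rounded Gaussian noise, plus a
configurable number of unrelated false-positive calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contact import BinTable, ContactMatrix
from .genome import DerivedGenome, SVEvent, build_derived_genome
from .sv_consensus import SVCall

__all__ = [
    "SimulationConfig",
    "checkerboard_labels",
    "simulate_contact_matrix",
    "simulate_callsets",
    "write_truth_bedpe",
    "write_labels_bedgraph",
]


@dataclass
class SimulationConfig:
    """Parameters of the contact-map generator.

    bin_size
        simulation bin width in bp.
    decay_exponent
        power-law slope of cis contact decay: expected weight at a
        separation of ``d`` bins is ``(d + 1) ** -decay_exponent``.
        Default 1.0, the canonical Hi-C cis slope.
    trans_rate
        relative weight of a trans bin pair on the same scale as the
        cis kernel (1.0 is the weight of a cis self-pair).
    depth
        expected genome-wide total read-pair count; all pair weights
        are rescaled to sum to this before Poisson sampling.
    compartment_labels
        optional per-reference-bin array of "A"/"B" labels; a pair of
        bins sharing a label has its weight multiplied by ``boost``.
    boost
        within-compartment contact multiplier, >= 1.
    seed
        RNG seed; same config + seed gives bit-identical matrices.
    """

    bin_size: int
    decay_exponent: float = 1.0
    trans_rate: float = 0.01
    depth: float = 1_000_000.0
    compartment_labels: np.ndarray | None = None
    boost: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.decay_exponent <= 0:
            raise ValueError("decay_exponent must be positive")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.boost < 1:
            raise ValueError("compartment boost must be >= 1")
        if self.trans_rate < 0:
            raise ValueError("trans_rate must be non-negative")


def checkerboard_labels(n_bins: int, block: int = 10, phase: int = 0) -> np.ndarray:
    """Alternating A/B blocks of ``block`` bins — a planted checkerboard."""
    k = (np.arange(n_bins) // block + phase) % 2
    return np.where(k == 0, "A", "B")


def expected_matrix(genome: DerivedGenome, config: SimulationConfig) -> np.ndarray:
    """Dense expected-count matrix over *reference* bins (before sampling).

    Vectorized companion of the sampler; scaled so its total over the
    upper triangle (diagonal included) equals ``config.depth``.
    """
    lam, iu, ju, refbin = _pair_weights(genome, config)
    scale = config.depth / lam.sum()
    n_ref = genome.n_reference_bins
    exp = np.zeros((n_ref, n_ref))
    ri, rj = refbin[iu], refbin[ju]
    lo, hi = np.minimum(ri, rj), np.maximum(ri, rj)
    np.add.at(exp, (lo, hi), lam * scale)
    exp = exp + exp.T - np.diag(np.diag(exp))
    return exp


def _pair_weights(genome: DerivedGenome, config: SimulationConfig):
    """Upper-triangle pair weights in derived coordinates + lift-over."""
    if genome.bin_size != config.bin_size:
        raise ValueError("genome and config bin sizes disagree")
    lift = genome.liftover()
    chrom_id, pos, refbin = [], [], []
    for k, (chrom, _) in enumerate(genome.reference):
        bins = lift.get(chrom, np.empty(0, dtype=int))
        chrom_id.append(np.full(len(bins), k))
        pos.append(np.arange(len(bins)))
        refbin.append(bins)
    chrom_id = np.concatenate(chrom_id)
    pos = np.concatenate(pos)
    refbin = np.concatenate(refbin)
    n_d = len(refbin)
    iu, ju = np.triu_indices(n_d)
    same_chrom = chrom_id[iu] == chrom_id[ju]
    sep = np.abs(pos[iu] - pos[ju])
    lam = np.where(
        same_chrom,
        (sep + 1.0) ** -config.decay_exponent,
        config.trans_rate,
    )
    if config.compartment_labels is not None:
        labels = np.asarray(config.compartment_labels)
        if labels.shape != (genome.n_reference_bins,):
            raise ValueError(
                "compartment_labels must have one label per reference bin"
            )
        dlab = labels[refbin]
        lam = np.where(dlab[iu] == dlab[ju], lam * config.boost, lam)
    return lam, iu, ju, refbin


def simulate_contact_matrix(
    genome: DerivedGenome,
    config: SimulationConfig,
    sample: str = "sim",
) -> tuple[ContactMatrix, dict]:
    """Sample a reference-coordinate contact map from a derived genome.

    Returns the matrix and a ground-truth record holding the planted
    events, their junction breakpoints (reference coordinates) and the
    planted compartment labels.
    """
    rng = np.random.default_rng(config.seed)
    lam, iu, ju, refbin = _pair_weights(genome, config)
    scale = config.depth / lam.sum()
    counts = rng.poisson(lam * scale)
    nz = counts > 0
    bins = BinTable(genome.reference, config.bin_size)
    matrix = ContactMatrix.from_coo(
        bins, refbin[iu[nz]], refbin[ju[nz]], counts[nz], sample=sample
    )
    truth = {
        "events": list(genome.events),
        "breakpoints": [ev.breakpoint_pair() for ev in genome.events],
        "compartment_labels": config.compartment_labels,
    }
    return matrix, truth


def simulate_sample(
    reference: list[tuple[str, int]],
    events: list[SVEvent],
    config: SimulationConfig,
    sample: str = "sim",
) -> tuple[ContactMatrix, dict]:
    """Convenience: build the derived genome and simulate in one call."""
    genome = build_derived_genome(reference, events, config.bin_size)
    return simulate_contact_matrix(genome, config, sample=sample)


# ---------------------------------------------------------------------------
# Multi-caller SV call sets


def _random_false_positive(
    rng: np.random.Generator,
    reference: list[tuple[str, int]],
    caller: str,
    sample: str,
    k: int,
) -> SVCall:
    chroms = [c for c, _ in reference]
    sizes = dict(reference)
    if len(chroms) > 1 and rng.random() < 0.15:  # occasional trans FP
        c1, c2 = rng.choice(len(chroms), size=2, replace=False)
        c1, c2 = chroms[c1], chroms[c2]
        p1 = int(rng.integers(0, sizes[c1]))
        p2 = int(rng.integers(0, sizes[c2]))
        sv_type = "BND"
    else:
        c1 = c2 = chroms[int(rng.integers(len(chroms)))]
        p1 = int(rng.integers(0, sizes[c1]))
        size = int(rng.integers(1_000, 1_000_000))
        p2 = min(p1 + size, sizes[c1] - 1)
        sv_type = str(rng.choice(["DEL", "DUP", "INV"]))
    return SVCall(
        chrom1=c1, pos1=p1, chrom2=c2, pos2=p2,
        sv_type=sv_type, caller=caller, sample=sample,
        name=f"{caller}_fp{k}",
    ).canonical()


def simulate_callsets(
    truth: list[SVEvent],
    n_callers: int = 4,
    jitter_sd: float = 300.0,
    dropout: float = 0.0,
    fp_per_caller: int = 0,
    seed: int = 0,
    reference: list[tuple[str, int]] | None = None,
    sample: str = "sim",
    caller_names: list[str] | None = None,
) -> dict[str, list[SVCall]]:
    """Per-caller SV call lists for a set of true events.

    Each true event's junction is emitted by each caller with
    probability ``1 − dropout``; both breakpoints get independent
    ``round(N(0, jitter_sd))`` offsets.  ``fp_per_caller`` unrelated
    random calls are added per caller (requires ``reference`` for
    placement).  True calls carry ``truth_id`` = the event's index in
    ``truth``; false positives carry ``truth_id=None``.
    """
    if n_callers < 1:
        raise ValueError("need at least one caller")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be non-negative")
    if not 0 <= dropout <= 1:
        raise ValueError("dropout must be a probability")
    if fp_per_caller > 0 and reference is None:
        raise ValueError("false-positive placement needs a reference genome")
    rng = np.random.default_rng(seed)
    callers = caller_names or [f"caller{k + 1}" for k in range(n_callers)]
    if len(callers) != n_callers:
        raise ValueError("caller_names length must equal n_callers")
    out: dict[str, list[SVCall]] = {c: [] for c in callers}
    for caller in callers:
        for idx, ev in enumerate(truth):
            if rng.random() < dropout:
                continue
            (c1, p1), (c2, p2) = ev.breakpoint_pair()
            q1 = max(0, p1 + int(round(rng.normal(0, jitter_sd)))) if jitter_sd else p1
            q2 = max(0, p2 + int(round(rng.normal(0, jitter_sd)))) if jitter_sd else p2
            out[caller].append(
                SVCall(
                    chrom1=c1, pos1=q1, chrom2=c2, pos2=q2,
                    sv_type=ev.sv_type, caller=caller, sample=sample,
                    truth_id=idx, name=ev.name or f"event{idx}",
                ).canonical()
            )
        for k in range(fp_per_caller):
            out[caller].append(
                _random_false_positive(rng, reference, caller, sample, k)
            )
    return out


# ---------------------------------------------------------------------------
# Ground-truth writers


def write_truth_bedpe(events: list[SVEvent], path) -> None:
    """Planted events as BEDPE (point breakpoints, 1-bp intervals)."""
    with open(path, "w") as fh:
        for idx, ev in enumerate(events):
            (c1, p1), (c2, p2) = ev.breakpoint_pair()
            name = ev.name or f"event{idx}"
            fh.write(
                f"{c1}\t{p1}\t{p1 + 1}\t{c2}\t{p2}\t{p2 + 1}\t"
                f"{name}\t.\t.\t.\t{ev.sv_type}\t{ev.event_type}\n"
            )


def write_labels_bedgraph(bins: BinTable, labels: np.ndarray, path) -> None:
    """Planted compartment labels as a +1/−1 bedGraph track."""
    values = np.where(np.asarray(labels) == "A", 1.0, -1.0)
    from .contact import write_bedgraph

    write_bedgraph(bins, values, path)
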