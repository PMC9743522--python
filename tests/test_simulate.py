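"""Contact-map and call-set simulator: determinism, kernel, ectopic signal."""

import numpy as np
import pytest

import fusion4c as f4c
from fusion4c.genome import GenomicInterval, SVEvent, build_derived_genome
from fusion4c.simulate import SimulationConfig, simulate_callsets

GI = GenomicInterval


def brute_force_expected(genome, config):
    """Independent expected-count oracle: explicit loops over derived pairs.

    Walks the segment lists by hand to enumerate every derived bin with
    its (derived chromosome, derived position, reference bin), applies
    the decay/trans/boost kernel pair by pair, and accumulates into
    reference coordinates.
    """
    # enumerate derived bins from the segment walks, independently of liftover()
    ref_offset, cum = {}, 0
    for chrom, length in genome.reference:
        ref_offset[chrom] = cum
        cum += -(-length // genome.bin_size)
    derived = []  # (derived chrom, derived pos, global ref bin)
    for chrom, segs in genome.segments.items():
        pos = 0
        for iv, orient in segs:
            nb = -(-len(iv) // genome.bin_size)
            local = list(range(nb))
            if orient == "inverted":
                local = local[::-1]
            for loc in local:
                refbin = ref_offset[iv.chrom] + iv.start // genome.bin_size + loc
                derived.append((chrom, pos, refbin))
                pos += 1
    labels = config.compartment_labels
    weights = {}
    total = 0.0
    for a in range(len(derived)):
        ca, pa, ra = derived[a]
        for b in range(a, len(derived)):
            cb, pb, rb = derived[b]
            if ca == cb:
                lam = (abs(pa - pb) + 1.0) ** -config.decay_exponent
            else:
                lam = config.trans_rate
            if labels is not None and labels[ra] == labels[rb]:
                lam *= config.boost
            lo, hi = min(ra, rb), max(ra, rb)
            weights[(lo, hi)] = weights.get((lo, hi), 0.0) + lam
            total += lam
    n = cum
    out = np.zeros((n, n))
    for (lo, hi), w in weights.items():
        out[lo, hi] += w * config.depth / total
    return out + out.T - np.diag(np.diag(out))


class TestContactSimulation:
    def test_same_seed_is_bit_identical(self):
        g = build_derived_genome([("chr1", 500_000)], [], 10_000)
        cfg = SimulationConfig(bin_size=10_000, depth=50_000, seed=42)
        m1, _ = f4c.simulate_contact_matrix(g, cfg)
        m2, _ = f4c.simulate_contact_matrix(g, cfg)
        assert (m1.mat != m2.mat).nnz == 0

    def test_decay_kernel_ratio_between_separations(self):
        """(d+1)^-1 kernel: separation 1 vs 3 has expected ratio 2.0."""
        g = build_derived_genome([("chr1", 1_000_000)], [], 10_000)
        cfg = SimulationConfig(bin_size=10_000, decay_exponent=1.0,
                               depth=1e6, seed=0)
        exp = f4c.expected_matrix(g, cfg)
        n = 100
        d1 = np.mean([exp[i, i + 1] for i in range(n - 1)])
        d3 = np.mean([exp[i, i + 3] for i in range(n - 3)])
        assert d1 / d3 == pytest.approx(2.0)

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError, match="depth"):
            SimulationConfig(bin_size=10_000, depth=0)

    def test_mass_conservation_across_seeds(self):
        g = build_derived_genome([("chr1", 500_000)], [], 10_000)
        depth = 20_000
        totals = []
        for seed in range(100):
            cfg = SimulationConfig(bin_size=10_000, depth=depth, seed=seed)
            m, _ = f4c.simulate_contact_matrix(g, cfg)
            totals.append(m.total())
        # Poisson total: SE of the mean over 100 seeds = sqrt(depth/100)
        se = np.sqrt(depth / 100)
        assert abs(np.mean(totals) - depth) < 5 * se

    def test_monotonic_decay_of_mean_count_with_separation(self):
        g = build_derived_genome([("chr1", 1_000_000)], [], 10_000)
        cfg = SimulationConfig(bin_size=10_000, depth=5e6, seed=7)
        m, _ = f4c.simulate_contact_matrix(g, cfg)
        dense = m.symmetric().toarray()
        n = dense.shape[0]
        means = [
            np.mean([dense[i, i + d] for i in range(n - d)]) for d in range(20)
        ]
        assert all(a >= b for a, b in zip(means, means[1:]))

    def test_expected_matrix_matches_brute_force_oracle(self):
        ev = SVEvent("tandem_duplication", (GI("chr1", 100_000, 200_000),))
        g = build_derived_genome(
            [("chr1", 400_000), ("chr2", 200_000)], [ev], 20_000
        )
        cfg = SimulationConfig(
            bin_size=20_000, depth=1e5, trans_rate=0.05, boost=1.5,
            compartment_labels=f4c.checkerboard_labels(30, block=3), seed=0,
        )
        np.testing.assert_allclose(
            f4c.expected_matrix(g, cfg), brute_force_expected(g, cfg),
            rtol=1e-10,
        )

    def test_tandem_duplication_elevates_breakpoint_flank_contacts(self):
        """Ectopic-signal property, checked on the expectation oracle."""
        ref = [("chr1", 1_000_000)]
        ev = SVEvent("tandem_duplication", (GI("chr1", 300_000, 600_000),))
        cfg = SimulationConfig(bin_size=10_000, depth=1e6, seed=0)
        exp_event = brute_force_expected(
            build_derived_genome(ref, [ev], 10_000), cfg
        )
        exp_null = brute_force_expected(
            build_derived_genome(ref, [], 10_000), cfg
        )
        # the junction joins the end of copy 1 (bin 59) to the start of
        # copy 2 (bin 30): that bin pair gains a separation-1 contact
        assert exp_event[30, 59] > exp_null[30, 59]
        # and the strictly elevated junction signal dominates its background
        assert exp_event[30, 59] / exp_null[30, 59] > 5


class TestCallsetSimulation:
    EVENTS = [
        SVEvent("tandem_duplication", (GI("chr1", 100_000, 200_000),)),
        SVEvent("deletion", (GI("chr1", 400_000, 450_000),)),
        SVEvent(
            "insertion_translocation",
            (GI("chr1", 600_000, 700_000), GI("chr2", 100_000, 150_000)),
        ),
    ]

    def test_no_noise_reports_every_event_exactly(self):
        sets = simulate_callsets(self.EVENTS, n_callers=3, jitter_sd=0,
                                 dropout=0, fp_per_caller=0, seed=1)
        assert len(sets) == 3
        for calls in sets.values():
            assert len(calls) == len(self.EVENTS)
            for call, ev in zip(sorted(calls, key=lambda c: c.truth_id),
                                self.EVENTS):
                want = tuple(sorted(ev.breakpoint_pair()))
                got = tuple(sorted([call.breakpoint1, call.breakpoint2]))
                assert got == want

    def test_full_dropout_empties_all_callsets(self):
        sets = simulate_callsets(self.EVENTS, n_callers=4, jitter_sd=100,
                                 dropout=1.0, seed=2)
        assert all(len(v) == 0 for v in sets.values())

    def test_false_positives_unlabelled_and_counted(self):
        sets = simulate_callsets(
            self.EVENTS, n_callers=2, jitter_sd=0, dropout=0,
            fp_per_caller=5, seed=3, reference=[("chr1", 1_000_000),
                                                ("chr2", 500_000)],
        )
        for calls in sets.values():
            fps = [c for c in calls if c.truth_id is None]
            assert len(fps) == 5

    def test_consensus_recovery_matches_regenerated_process(self):
        """Downstream consensus recall equals a brute-force recount of the
        same generative draws (regenerate with the same seed, recount)."""
        events = [
            SVEvent("tandem_duplication",
                    (GI("chr1", s, s + 50_000),))
            for s in range(100_000, 600_000, 100_000)
        ]
        kwargs = dict(n_callers=4, jitter_sd=300.0, dropout=0.25,
                      fp_per_caller=0, seed=9)
        sets = simulate_callsets(events, **kwargs)
        groups = f4c.match_calls(sets, tolerance=1000)
        recovered = {
            tid
            for g in groups
            if g.n_callers >= 2
            for tid in g.truth_ids
        }
        # independent recount: regenerate and cluster by brute force
        sets2 = simulate_callsets(events, **kwargs)
        flat = [c for lst in sets2.values() for c in lst]
        n = len(flat)
        adj = {k: set() for k in range(n)}
        for a in range(n):
            for b in range(a + 1, n):
                ca, cb = flat[a], flat[b]
                if (ca.chrom1, ca.chrom2) == (cb.chrom1, cb.chrom2) and \
                   abs(ca.pos1 - cb.pos1) <= 1000 and \
                   abs(ca.pos2 - cb.pos2) <= 1000:
                    adj[a].add(b)
                    adj[b].add(a)
        seen, expected = set(), set()
        for start in range(n):
            if start in seen:
                continue
            comp, stack = [], [start]
            while stack:
                x = stack.pop()
                if x in seen:
                    continue
                seen.add(x)
                comp.append(x)
                stack.extend(adj[x])
            callers = {flat[x].caller for x in comp}
            if len(callers) >= 2:
                expected |= {
                    flat[x].truth_id for x in comp
                    if flat[x].truth_id is not None
                }
        assert recovered == expected
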