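import numpy as np
import pytest

from oligomux import tables
from oligomux.fixtures import SyntheticTrackSpec, make_track
from oligomux.genome_io import GeneAnnotation, GenomicInterval, SignalTrack
from oligomux.probe_mining import CandidateProbe
from oligomux.sublibraries import (
    ChromatinDomain,
    DomainCallParams,
    StripeScheme,
    assign_probes,
    average_track,
    call_domains,
    define_stripes,
    gene_density,
    stripe_gene_ratio,
)


def _probe(chrom, start, end):
    return CandidateProbe(GenomicInterval(chrom, start, end), "A" * (end - start),
                          0.0, 50.0)


class TestDefineStripes:
    def test_published_ch7_coordinates_pass_through(self):
        scheme = tables.stripe_scheme("7")
        # printed coordinates: tel1 35931..2809682, mid 5587874..8357288,
        # tel2 11131025..13904776 (1-based); sizes land at 2.77/2.76/2.77 Mb
        assert scheme.tel1 == GenomicInterval("7", 35930, 2809682)
        assert scheme.mid == GenomicInterval("7", 5587873, 8357288)
        assert scheme.tel2 == GenomicInterval("7", 11131024, 13904776)

    def test_degenerate_tiling(self):
        paint = GenomicInterval("c", 0, 3_000_000)
        scheme = define_stripes(paint, nominal_size=1_000_000)
        assert scheme.tel1.start == paint.start
        assert scheme.tel2.end == paint.end
        assert scheme.tel1.end == scheme.mid.start
        assert scheme.mid.end == scheme.tel2.start

    def test_auto_mid_centered_within_probe_gap(self):
        rng = np.random.default_rng(21)
        paint = GenomicInterval("c", 0, 9_000)
        probes = []
        pos = 0
        while pos + 80 <= paint.length:
            start = pos + int(rng.integers(0, 60))
            if start + 80 > paint.length:
                break
            probes.append(_probe("c", start, start + 80))
            pos = start + 80
        scheme = define_stripes(paint, nominal_size=2_000, probes=probes)
        max_gap = max(
            b.interval.start - a.interval.end for a, b in zip(probes, probes[1:])
        )
        assert abs(scheme.mid.midpoint - paint.midpoint) <= max(max_gap, 80)
        boundaries = {p.interval.start for p in probes} | {p.interval.end for p in probes}
        assert scheme.mid.start in boundaries and scheme.mid.end in boundaries

    def test_paint_too_short_errors(self):
        with pytest.raises(ValueError, match="too short"):
            define_stripes(GenomicInterval("c", 0, 1_000), nominal_size=500)

    def test_size_far_from_nominal_rejected(self):
        with pytest.raises(ValueError, match="15%"):
            StripeScheme(
                "c",
                GenomicInterval("c", 0, 2_000_000),
                GenomicInterval("c", 4_000_000, 5_000_000),
                GenomicInterval("c", 9_000_000, 10_000_000),
                nominal_size=1_000_000,
            )


class TestAverageTrack:
    def test_mean_of_five_bins(self):
        track = SignalTrack("c", 10_000, [1, 2, 3, 4, 5])
        out = average_track(track)
        assert out.bin_size == 50_000
        assert list(out.values) == [3.0]

    def test_constant_idempotent(self):
        track = SignalTrack("c", 10_000, [7.5] * 25)
        assert np.allclose(average_track(track).values, 7.5)

    def test_matches_explicit_loop_oracle(self):
        rng = np.random.default_rng(31)
        values = rng.normal(size=53)
        values[[3, 17, 40, 41, 42, 43, 44]] = np.nan
        track = SignalTrack("c", 10_000, values)
        out = average_track(track)
        # independent re-computation by explicit loop over bin groups
        for w in range(out.n_bins):
            group = values[w * 5 : (w + 1) * 5]
            finite = group[~np.isnan(group)]
            if len(finite) == 0:
                assert np.isnan(out.values[w])
            else:
                assert out.values[w] == pytest.approx(finite.mean())

    def test_all_nan_window_stays_no_data(self):
        values = np.concatenate([np.full(5, np.nan), np.ones(5)])
        out = average_track(SignalTrack("c", 10_000, values))
        assert np.isnan(out.values[0]) and out.values[1] == 1.0

    def test_bin_size_mismatch(self):
        with pytest.raises(ValueError, match="bin_size"):
            average_track(SignalTrack("c", 5_000, [1.0]))


class TestCallDomains:
    PAINT = GenomicInterval("chr1", 0, 500_000)

    def test_uniformly_positive_is_single_inactive_domain(self):
        avg = SignalTrack("chr1", 50_000, np.full(10, 3.0))
        domains = call_domains(avg, self.PAINT)
        assert len(domains) == 1
        assert domains[0].state == "inactive"
        assert domains[0].interval == self.PAINT

    def test_boundaries_are_window_multiples(self):
        rng = np.random.default_rng(41)
        avg = SignalTrack("chr1", 50_000, rng.normal(size=10))
        domains = call_domains(avg, self.PAINT)
        for dom in domains:
            if dom.interval.start != self.PAINT.start:
                assert dom.interval.start % 50_000 == 0
            if dom.interval.end != self.PAINT.end:
                assert dom.interval.end % 50_000 == 0
            assert dom.interval.length >= 50_000

    def test_territory_conserved_and_no_adjacent_same_state(self):
        rng = np.random.default_rng(43)
        values = rng.normal(size=10)
        values[[2, 7]] = np.nan
        avg = SignalTrack("chr1", 50_000, values)
        domains = call_domains(avg, self.PAINT)
        for a, b in zip(domains, domains[1:]):
            assert a.interval.end <= b.interval.start
            if a.interval.end == b.interval.start:
                assert a.state != b.state
        covered = sum(d.interval.length for d in domains)
        gaps = 2 * 50_000  # two no-data windows
        assert covered + gaps == self.PAINT.length

    def test_no_data_windows_create_gaps(self):
        values = np.array([2.0, 2.0, np.nan, -2.0, -2.0])
        avg = SignalTrack("chr1", 50_000, values)
        domains = call_domains(avg, GenomicInterval("chr1", 0, 250_000))
        assert [(d.interval.start, d.interval.end, d.state) for d in domains] == [
            (0, 100_000, "inactive"),
            (150_000, 250_000, "active"),
        ]

    def test_edge_domains_meet_paint_edges(self):
        paint = GenomicInterval("chr1", 35_930, 480_000)
        avg = SignalTrack("chr1", 50_000, np.array([2.0, -2.0] * 5))
        domains = call_domains(avg, paint)
        assert domains[0].interval.start == paint.start
        assert domains[-1].interval.end == paint.end

    def test_planted_domain_recovery_under_noise(self):
        """SNR 4:1 planted blocks: >=95% of boundaries recovered within one
        window across 100 seeds."""
        from oligomux.fixtures import boundary_recovery

        layout = tuple(
            (s, s + 100_000, "inactive" if (s // 100_000) % 2 == 0 else "active")
            for s in range(0, 500_000, 100_000)
        )
        total, hits = 0, 0.0
        for seed in range(100):
            track, truth = make_track(
                SyntheticTrackSpec(length=500_000, domains=layout, seed=seed)
            )
            called = call_domains(average_track(track), self.PAINT)
            hits += boundary_recovery(called, truth)
            total += 1
        assert hits / total >= 0.95

    def test_empty_track_errors(self):
        with pytest.raises(ValueError, match="empty"):
            call_domains(SignalTrack("c", 50_000, np.full(5, np.nan)), self.PAINT)


class TestAssignProbes:
    DOMAINS = [
        ChromatinDomain(GenomicInterval("c", 0, 1_000), "inactive"),
        ChromatinDomain(GenomicInterval("c", 1_000, 2_000), "active"),
    ]

    def test_exact_interval_match_assigned(self):
        probe = _probe("c", 0, 1_000)
        result = assign_probes([probe], self.DOMAINS)
        assert result.assigned["inactive:1-1000"] == [probe]

    def test_straddling_probe_unassigned(self):
        probe = _probe("c", 960, 1_040)
        result = assign_probes([probe], self.DOMAINS)
        assert result.straddle_count == 1
        assert all(not v for v in result.assigned.values())

    def test_matches_brute_force_containment_scan(self):
        rng = np.random.default_rng(51)
        starts = np.sort(rng.choice(np.arange(0, 1_920), size=20, replace=False))
        probes = [_probe("c", int(s), int(s) + 80) for s in starts]
        result = assign_probes(probes, self.DOMAINS)
        for name, iv in [("inactive:1-1000", self.DOMAINS[0].interval),
                         ("active:1001-2000", self.DOMAINS[1].interval)]:
            expected = [p for p in probes if iv.contains(p.interval)]
            assert result.assigned[name] == expected

    def test_order_invariance(self):
        rng = np.random.default_rng(52)
        starts = rng.choice(np.arange(0, 1_920), size=15, replace=False)
        probes = [_probe("c", int(s), int(s) + 80) for s in starts]
        shuffled = list(probes)
        rng.shuffle(shuffled)
        a = assign_probes(probes, self.DOMAINS)
        b = assign_probes(shuffled, self.DOMAINS)
        assert a.assigned == b.assigned
        assert sorted(p.interval for p in a.unassigned) == sorted(
            p.interval for p in b.unassigned
        )

    def test_stripe_scheme_keys(self):
        scheme = define_stripes(GenomicInterval("c", 0, 3_000), nominal_size=1_000)
        probe = _probe("c", 100, 180)
        result = assign_probes([probe], scheme)
        assert result.assigned["tel1"] == [probe]


class TestGeneDensity:
    def test_midpoint_count_arithmetic(self):
        records = [
            (GenomicInterval("c", i * 1_000, i * 1_000 + 500), f"g{i}") for i in range(10)
        ]
        ann = GeneAnnotation(records)
        assert gene_density(ann, GenomicInterval("c", 0, 1_000_000)) == 10.0

    def test_symmetric_stripes_ratio_one(self):
        records = [(GenomicInterval("c", 100 + i * 200, 200 + i * 200), f"a{i}")
                   for i in range(5)]
        records += [(GenomicInterval("c", 2_100 + i * 200, 2_200 + i * 200), f"b{i}")
                    for i in range(5)]
        ann = GeneAnnotation(records)
        scheme = define_stripes(GenomicInterval("c", 0, 3_000), nominal_size=1_000)
        assert stripe_gene_ratio(ann, scheme) == 1.0

    def test_matches_brute_force_midpoint_count(self):
        rng = np.random.default_rng(61)
        records = []
        for i in range(200):
            start = int(rng.integers(0, 99_000))
            records.append((GenomicInterval("c", start, start + int(rng.integers(100, 900))),
                            f"g{i}"))
        ann = GeneAnnotation(records)
        interval = GenomicInterval("c", 20_000, 70_000)
        expected = sum(
            1 for iv, _ in records if interval.start <= (iv.start + iv.end) / 2 < interval.end
        )
        assert gene_density(ann, interval) == pytest.approx(expected / 0.05)

    def test_zero_tel2_density_errors(self):
        ann = GeneAnnotation([(GenomicInterval("c", 0, 100), "g1")])
        scheme = define_stripes(GenomicInterval("c", 0, 3_000), nominal_size=1_000)
        with pytest.raises(ValueError, match="tel2"):
            stripe_gene_ratio(ann, scheme)
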