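import numpy as np
import pandas as pd
import pytest

import ploidykit as pk
from ploidykit.calls import build_trio_genotypes
from ploidykit.recomb import (
    ConcordanceTrack,
    RecombinationWindow,
    breakpoint_overlap_test,
    concordance_track,
    consecutive_error_prob,
    detect_recombination_windows,
    estimate_genotype_error_rate,
    segment_array_bph_sph,
)


def _track(deltas, positions=None, chrom="chr1"):
    pos = positions if positions is not None else np.arange(1, len(deltas) + 1) * 1000
    df = pd.DataFrame({"pos": pos, "delta": np.asarray(deltas, dtype=np.int8)})
    return ConcordanceTrack({chrom: df}, {chrom: len(df)})


def brute_force_windows(deltas, positions):
    """Independent oracle: maximal runs of >= 3 identical nonzero deltas
    define states; each change of state between consecutive runs is one
    window from the last SNP of the old run to the first SNP of the new."""
    d = np.asarray(deltas)
    p = np.asarray(positions)
    keep = d != 0
    d, p = d[keep], p[keep]
    runs = []  # (state, first_idx, last_idx)
    i = 0
    while i < len(d):
        j = i
        while j + 1 < len(d) and d[j + 1] == d[i]:
            j += 1
        if j - i + 1 >= 3:
            runs.append((d[i], i, j))
        i = j + 1
    wins = []
    for (s1, _, e1), (s2, b2, _) in zip(runs, runs[1:]):
        if s1 != s2:
            wins.append((int(p[e1]), int(p[b2])))
    return wins


class TestConcordanceTrack:
    def test_worked_example_deltas(self, toy_spec, toy_parents, noiseless):
        mother, father, _ = toy_parents
        sim = pk.simulate_embryo_trio(
            mother, father, toy_spec, "maternal_triploid_MI", noiseless, seed=70
        )
        trio = build_trio_genotypes(sim, toy_spec)
        track = concordance_track(trio)
        # noiseless: the delta track equals the simulator's BPH/SPH truth
        truth = sim.truth_bph
        pos_all = trio.sites["pos"].to_numpy()
        ch_all = trio.sites["chrom"].to_numpy()
        for chrom, df in track:
            lookup = dict(zip(pos_all[ch_all == chrom],
                              truth[ch_all == chrom]))
            for row in df.itertuples(index=False):
                want = -1 if lookup[row.pos] else +1
                assert row.delta == want

    def test_father_het_sites_excluded(self, toy_spec, toy_parents, noiseless):
        trio = build_trio_genotypes(
            pk.simulate_embryo_trio(*toy_parents[:2], toy_spec,
                                    "maternal_triploid_MII", noiseless, seed=71),
            toy_spec,
        )
        track = concordance_track(trio)
        df = trio.sites
        informative = ((df["call_mother"] == 1)
                       & df["call_father"].isin([0, 2])
                       & (df["call_embryo"] != -1) & df["pass_filters"])
        n_track = sum(len(t) for _, t in track)
        # every tracked SNP is informative; father-het sites never enter
        assert n_track <= informative.sum()

    def test_diploid_embryo_rejected(self, toy_spec, toy_parents, noiseless):
        trio = build_trio_genotypes(
            pk.simulate_embryo_trio(*toy_parents[:2], toy_spec, "diploid", noiseless, seed=72),
            toy_spec,
        )
        with pytest.raises(ValueError):
            concordance_track(trio)


class TestWindowDetection:
    def test_constant_track_has_no_windows(self):
        _, n = detect_recombination_windows(_track([-1] * 20))
        assert n == 0

    def test_single_clean_switch(self):
        wins, n = detect_recombination_windows(_track([-1] * 10 + [1] * 10))
        assert n == 1
        w = wins[0]
        assert (w.start_pos, w.end_pos) == (10_000, 11_000)
        assert (w.state_before, w.state_after) == ("BPH", "SPH")

    def test_short_chromosome_yields_no_windows(self):
        _, n = detect_recombination_windows(_track([1, -1]))
        assert n == 0

    def test_window_count_equals_state_sign_changes(self):
        rng = np.random.default_rng(73)
        deltas = np.repeat(rng.choice([-1, 1], 12), rng.integers(3, 9, 12))
        wins, n = detect_recombination_windows(_track(deltas))
        states = [deltas[0]]
        for d in deltas:
            if d != states[-1]:
                states.append(d)
        assert n == len(states) - 1

    def test_matches_bruteforce_on_simulated_trios(self, toy_spec, platform_noise):
        # 200 seeded triploid trios: sliding-window detector vs exhaustive
        # run-scan oracle, identical windows
        rng = np.random.default_rng(74)
        mother, father, _ = pk.simulate_parents(toy_spec, 600, seed=rng)
        for i in range(200):
            sim = pk.simulate_embryo_trio(
                mother, father, toy_spec,
                "maternal_triploid_MI" if i % 2 else "maternal_triploid_MII",
                platform_noise, seed=rng,
            )
            trio = build_trio_genotypes(sim, toy_spec)
            track = concordance_track(trio)
            wins, _ = detect_recombination_windows(track)
            got = sorted((w.chrom, w.start_pos, w.end_pos) for w in wins)
            want = []
            for chrom, df in track:
                for s, e in brute_force_windows(df["delta"], df["pos"]):
                    want.append((chrom, s, e))
            assert got == sorted(want)

    def test_roundtrip_truth_crossovers_noiseless(self, toy_spec, noiseless):
        # at e=0, with >= 3 informative SNPs between consecutive switches,
        # every truth switch lies in exactly one window and vice versa
        rng = np.random.default_rng(75)
        checked = 0
        for _ in range(40):
            mother, father, panel = pk.simulate_parents(toy_spec, 800, seed=rng)
            sim = pk.simulate_embryo_trio(
                mother, father, toy_spec, "maternal_triploid_MII", noiseless, seed=rng
            )
            trio = build_trio_genotypes(sim, toy_spec)
            track = concordance_track(trio)
            wins, _ = detect_recombination_windows(track)
            for chrom, df in track:
                switches = sim.maternal_meiosis.switch_positions(chrom)
                pos = df["pos"].to_numpy()[df["delta"].to_numpy() != 0]
                if pos.size < 3:
                    continue
                # require >= 3 informative SNPs between consecutive switches
                edges = np.concatenate([[0], switches, [toy_spec[chrom].length_bp]])
                counts = [((pos > a) & (pos < b)).sum() for a, b in zip(edges, edges[1:])]
                # switches outside the informative span are undetectable
                inside = [(s, c_ok) for s, c_ok in zip(switches, zip(counts, counts[1:]))
                          if pos.min() < s < pos.max()]
                if not all(c1 >= 3 and c2 >= 3 for _, (c1, c2) in inside):
                    continue
                cwins = [w for w in wins if w.chrom == chrom]
                assert len(cwins) == len(inside)
                for w, (s, _) in zip(cwins, inside):
                    assert w.start_pos <= s <= w.end_pos
                checked += 1
        assert checked > 20  # the clean configuration occurred often enough

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            RecombinationWindow("chr1", 100, 100, "BPH", "SPH")
        with pytest.raises(ValueError):
            RecombinationWindow("chr1", 100, 200, "BPH", "BPH")


class TestErrorRate:
    def test_three_consecutive_errors_probability(self):
        assert consecutive_error_prob(0.0042, 3) == pytest.approx(7e-8, rel=0.06)

    def test_noiseless_rate_is_zero(self, toy_spec, toy_parents, noiseless):
        trio = build_trio_genotypes(
            pk.simulate_embryo_trio(*toy_parents[:2], toy_spec,
                                    "maternal_triploid_MII", noiseless, seed=76),
            toy_spec,
        )
        assert estimate_genotype_error_rate([trio]) == 0.0

    def test_recovers_injected_rate(self, toy_spec, platform_noise):
        rng = np.random.default_rng(77)
        trios = []
        total_sites = 0
        for _ in range(40):
            mother, father, _ = pk.simulate_parents(toy_spec, 800, seed=rng)
            sim = pk.simulate_embryo_trio(
                mother, father, toy_spec, "maternal_triploid_MII", platform_noise, seed=rng
            )
            trios.append(build_trio_genotypes(sim, toy_spec))
            total_sites += 800
        rate = estimate_genotype_error_rate(trios)
        eps = platform_noise.call_error_rate
        se = np.sqrt(eps * (1 - eps) / (total_sites * 0.4))  # ~40 % hom x hom sites
        assert abs(rate - eps) < 3 * se

    def test_no_usable_sites_errors(self):
        with pytest.raises(ValueError):
            estimate_genotype_error_rate([])


class TestArraySegmenter:
    def test_all_ones_arm_is_single_bph_segment(self, toy_spec):
        pos = np.linspace(31e6, 59e6, 200, dtype=int)  # q arm of chr3 (cen 30 Mb)
        sites = pd.DataFrame({"chrom": "chr3", "pos": pos, "value": 1})
        seg = segment_array_bph_sph(sites, toy_spec)
        q = seg.segments[seg.segments["arm"] == "q"]
        assert list(q["state"]) == ["BPH"]
        assert seg.breakpoints.empty or (seg.breakpoints["arm"] != "q").all()

    def test_constructed_breakpoint_located_within_window(self, toy_spec):
        rng = np.random.default_rng(78)
        pos = np.linspace(31e6, 59e6, 300, dtype=int)
        values = np.concatenate([np.ones(150), rng.integers(0, 2, 150)])
        sites = pd.DataFrame({"chrom": "chr3", "pos": pos, "value": values})
        seg = segment_array_bph_sph(sites, toy_spec)
        bps = seg.breakpoints[seg.breakpoints["arm"] == "q"]["pos"].to_numpy()
        assert len(bps) >= 1
        # first switch within +- one 50-SNP window of the construction point
        assert abs(np.searchsorted(pos, bps[0]) - 150) <= 50

    def test_short_arm_flagged_low_confidence(self, toy_spec):
        pos = np.linspace(31e6, 33e6, 20, dtype=int)
        sites = pd.DataFrame({"chrom": "chr3", "pos": pos, "value": 1})
        seg = segment_array_bph_sph(sites, toy_spec)
        assert seg.segments["low_confidence"].all()

    def test_isodiploid_arm_sph_then_bph_after_crossover(self, toy_spec, noiseless):
        # maternal isodiploid: SPH from the centromere, switching to BPH
        # past the first crossover; array values = embryo het at maternal-het sites
        rng = np.random.default_rng(79)
        for _ in range(20):
            mother, father, _ = pk.simulate_parents(toy_spec, 2000, seed=rng)
            sim = pk.simulate_embryo_trio(
                mother, father, toy_spec, "maternal_isodiploid", noiseless, seed=rng
            )
            name = "chr1"
            mm = sim.maternal_meiosis
            sl = sim.panel.chrom_slice(name)
            informative = mother.genotype[sl] == 1
            pos = sim.panel.positions(name)[informative]
            het = (sim.embryo_alt_copies[sl] == 1)[informative]
            cen = toy_spec[name].centromere_bp
            q = pos >= cen
            switches = mm.switch_positions(name)
            q_sw = switches[switches >= cen]
            if len(q_sw) != 1 or (pos[q] > q_sw[0]).sum() < 60 or (pos[q] < q_sw[0]).sum() < 60:
                continue
            sites = pd.DataFrame({"chrom": name, "pos": pos[q], "value": het[q].astype(int)})
            seg = segment_array_bph_sph(sites, toy_spec)
            states = seg.segments[seg.segments["arm"] == "q"]["state"].tolist()
            assert states[0] == "SPH" and "BPH" in states
            return
        pytest.skip("no chromosome arm with a single isolated crossover drawn")


class TestOverlapTest:
    def test_whole_chromosome_window_always_overlaps(self, toy_spec):
        L = toy_spec["chr4"].length_bp
        win = RecombinationWindow("chr4", 1, L - 1, "BPH", "SPH")
        bps = pd.DataFrame({"chrom": ["chr4"], "pos": [20_000_000]})
        obs, p = breakpoint_overlap_test([win], bps, toy_spec, n_perm=200, seed=1)
        assert obs == 1 and p == 1.0

    def test_no_breakpoints_gives_p_one(self, toy_spec):
        win = RecombinationWindow("chr4", 100, 200, "BPH", "SPH")
        obs, p = breakpoint_overlap_test(
            [win], pd.DataFrame({"chrom": [], "pos": []}), toy_spec, n_perm=200, seed=2
        )
        assert obs == 0 and p == 1.0

    def test_matches_analytic_placement_probability(self, toy_spec):
        # 1 window of length L on chromosome C, 1 breakpoint: null overlap
        # probability has the closed form (#valid starts) / (C - L + 1)
        C = toy_spec["chr4"].length_bp
        L = 8_000_000
        b = 9_000_000  # inside the observed window, so observed overlap = 1
        win = RecombinationWindow("chr4", 5_000_000, 5_000_000 + L, "BPH", "SPH")
        bps = pd.DataFrame({"chrom": ["chr4"], "pos": [b]})
        n_starts = C - L  # rng.integers(1, C - L + 1)
        valid = min(b, C - L) - max(b - L, 1) + 1
        analytic = valid / n_starts
        obs, p = breakpoint_overlap_test([win], bps, toy_spec, n_perm=20_000, seed=3)
        assert obs == 1
        se = np.sqrt(analytic * (1 - analytic) / 20_000)
        assert abs(p - analytic) < 4 * se + 1e-4

    def test_oversized_window_rejected(self, toy_spec):
        win = RecombinationWindow("chr4", 1, 50_000_001, "BPH", "SPH")
        with pytest.raises(ValueError):
            breakpoint_overlap_test(
                [win], pd.DataFrame({"chrom": ["chr4"], "pos": [1]}), toy_spec, 100, 4
            )
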