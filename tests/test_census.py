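"""Timelines, lifetime filter, product ranking and intermediates."""

import numpy as np
import pytest

from reaxtrack.census import (
    build_timelines,
    census_records,
    find_intermediates,
    lifetime_filter,
    rank_products,
)
from reaxtrack.io import BondFrame
from reaxtrack.synth import generate_box, generate_trajectory, preset_molecule_a


@pytest.fixture(scope="module")
def timelines_a(scenario_a_noiseless):
    frames, _, _, meta = scenario_a_noiseless
    return build_timelines(frames, meta=meta)


def static_frames(n):
    """n identical frames: one H2 molecule and one free O atom."""
    atoms = {1: "H", 2: "H", 3: "O"}
    return [BondFrame(k, k * 250.0, atoms, {(1, 2): 1.0}) for k in range(n)]


class TestBuildTimelines:
    def test_h_loss_swaps_reactant_and_product_counts(self, timelines_a,
                                                      scenario_a_noiseless):
        # the hydroperoxide-path copies lose a phenolic H at their 1A frame
        _, log, _, _ = scenario_a_noiseless
        first_1a = min(e.frame for e in log.events if e.descriptor == "1A")
        tl_reactant = timelines_a["C19H30O3"]
        tl_dehydro = timelines_a["C19H29O3"]
        assert tl_reactant.counts[first_1a - 1] - tl_reactant.counts[first_1a] == 1
        assert tl_dehydro.counts[first_1a - 1] == 0
        assert tl_dehydro.counts[first_1a] == 1

    def test_static_trajectory_lifetimes_equal_duration(self):
        timelines = build_timelines(static_frames(40), frame_interval_ps=0.25)
        for tl in timelines.values():
            assert tl.max_lifetime_ps == pytest.approx(40 * 0.25)

    def test_lifetimes_match_generator_log(self, timelines_a, scenario_a_noiseless):
        _, log, _, meta = scenario_a_noiseless
        interval = meta.frame_interval_ps
        for (atom_set, formula), frames_alive in log.occupancy_frames().items():
            tl = timelines_a[formula]
            assert tl.cumulative_lifetimes[atom_set] == pytest.approx(
                frames_alive * interval
            )

    def test_atom_count_mismatch_rejected(self):
        frames = static_frames(2)
        frames[1] = BondFrame(1, 250.0, {1: "H", 2: "H"}, {(1, 2): 1.0})
        with pytest.raises(ValueError, match="conserved"):
            build_timelines(frames)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_timelines([])

    def test_mass_balance_every_frame(self, timelines_a, scenario_a_noiseless):
        frames, _, _, _ = scenario_a_noiseless
        n_atoms = frames[0].n_atoms
        for k in range(len(frames)):
            total = 0
            for tl in timelines_a.values():
                for atom_set in tl.instances[k]:
                    total += len(atom_set)
            assert total == n_atoms


class TestLifetimeFilter:
    def make_timelines(self, present_frames, n=120, interval=0.25):
        atoms = {1: "O", 2: "O"}
        frames = []
        for k in range(n):
            bonds = {(1, 2): 2.0} if k in present_frames else {}
            frames.append(BondFrame(k, k * 250.0, atoms, bonds))
        return build_timelines(frames, frame_interval_ps=interval)

    def test_49_frames_at_quarter_ps_removed(self):
        timelines = self.make_timelines(set(range(49)))
        kept = lifetime_filter(timelines, 12.5)
        assert "O2" not in kept  # 12.25 ps < 12.5 ps

    def test_50_frames_retained_at_boundary(self):
        timelines = self.make_timelines(set(range(50)))
        kept = lifetime_filter(timelines, 12.5)
        assert "O2" in kept  # exactly 12.5 ps counts

    def test_cumulative_mode_sums_interrupted_runs(self):
        # 30 + 25 frames split by a gap: cumulative 13.75 ps passes,
        # longest contiguous run 7.5 ps does not
        present = set(range(30)) | set(range(60, 85))
        timelines = self.make_timelines(present)
        assert "O2" in lifetime_filter(timelines, 12.5)
        assert "O2" not in lifetime_filter(timelines, 12.5, contiguous=True)

    def test_zero_threshold_is_identity(self, timelines_a):
        assert lifetime_filter(timelines_a, 0.0) == timelines_a

    def test_monotone_and_idempotent(self, timelines_a):
        low = lifetime_filter(timelines_a, 5.0)
        high = lifetime_filter(timelines_a, 20.0)
        assert set(high) <= set(low)
        again = lifetime_filter(low, 5.0)
        assert set(again) == set(low)


class TestRankProducts:
    def test_steady_final_counts_rank_in_order(self, timelines_a, scenario_a_noiseless):
        _, _, _, meta = scenario_a_noiseless
        ranking = rank_products([timelines_a], window_ps=25,
                                frame_interval_ps=meta.frame_interval_ps)
        means = dict(ranking.entries)
        assert means["CO2"] == pytest.approx(3.0)
        assert means["C2H6O2"] == pytest.approx(3.0)
        assert means["O2"] == pytest.approx(17.0)  # 20 - 3 consumed
        # descending with lexicographic tie-break
        values = [v for _, v in ranking.entries]
        assert values == sorted(values, reverse=True)

    def test_mean_across_replicates_is_arithmetic(self):
        def tl_with_mean(mean_count):
            atoms = {1: "O", 2: "H", 3: "H"}
            frames = [BondFrame(k, 0.0, atoms,
                                {(1, 2): 1.0, (1, 3): 1.0} if k < mean_count * 4 else {})
                      for k in range(4)]
            return build_timelines(frames, frame_interval_ps=0.25)

        # window means for H2O across replicates: 0.25, 0.5, 0.75 -> mean 0.5
        reps = [tl_with_mean(0.25), tl_with_mean(0.5), tl_with_mean(0.75)]
        ranking = rank_products(reps, window_ps=1.0, frame_interval_ps=0.25)
        assert dict(ranking.entries)["H2O"] == pytest.approx(0.5)

    def test_replicate_order_invariance(self, timelines_a, scenario_a_noisy):
        frames_noisy, _, _, meta = scenario_a_noisy
        other = build_timelines(frames_noisy, meta=meta)
        r1 = rank_products([timelines_a, other], 25, meta.frame_interval_ps)
        r2 = rank_products([other, timelines_a], 25, meta.frame_interval_ps)
        assert r1.entries == r2.entries

    def test_feed_exclusion(self, timelines_a, scenario_a_noiseless):
        _, _, _, meta = scenario_a_noiseless
        ranking = rank_products([timelines_a], 25, meta.frame_interval_ps,
                                exclude={"C19H30O3", "O2"})
        formulas = [f for f, _ in ranking.entries]
        assert "O2" not in formulas and "C19H30O3" not in formulas
        assert "CO2" in formulas

    def test_window_longer_than_trajectory_rejected(self, timelines_a):
        with pytest.raises(ValueError, match="exceeds"):
            rank_products([timelines_a], window_ps=1e5, frame_interval_ps=0.25)


class TestFindIntermediates:
    def test_hydroperoxide_intermediates_include_radicals(self, timelines_a):
        inter = find_intermediates(timelines_a, "C2H6O2")
        assert "C2H5" in inter
        assert "C2H5O2" in inter
        assert "C19H30O3" in inter  # the parent molecule shares the ethyl atoms
        assert inter["C2H5"].first_ps < inter["C2H5O2"].first_ps

    def test_unreacted_feed_product_is_its_own_sole_intermediate(self, template_a):
        frame, layout = generate_box(template_a, 1, 0)
        frames = [BondFrame(k, k * 250.0, frame.atoms, frame.bonds)
                  for k in range(60)]
        timelines = build_timelines(frames, frame_interval_ps=0.25)
        inter = find_intermediates(timelines, "C19H30O3")
        assert set(inter) == {"C19H30O3"}

    def test_flicker_species_excluded_by_filter(self, scenario_a_noisy):
        frames, log, _, meta = scenario_a_noisy
        assert log.flickers, "scenario must contain flicker insertions"
        timelines = build_timelines(frames, meta=meta)
        inter = find_intermediates(timelines, "CO2", threshold_ps=12.5,
                                   frame_interval_ps=meta.frame_interval_ps)
        # every reported intermediate must outlive the filter
        surviving = lifetime_filter(timelines, 12.5,
                                    frame_interval_ps=meta.frame_interval_ps)
        assert set(inter) <= set(surviving)

    def test_product_absent_at_end_rejected(self, timelines_a):
        with pytest.raises(ValueError):
            find_intermediates(timelines_a, "C99H99")


class TestCensusRecords:
    def test_rows_cover_only_nonzero_counts(self, timelines_a):
        rows = census_records(timelines_a, "r0", 0.25)
        assert all(r["count"] > 0 for r in rows)
        formulas = {r["formula"] for r in rows}
        assert {"C19H30O3", "O2", "CO2"} <= formulas
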