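import numpy as np
import pytest

from bafdomains import (
    GenomicInterval,
    StateProfile,
    assign_states,
    build_state_matrix,
    hcluster_sites,
    reversibility_score,
    state_change_summary,
    state_composition,
)
from bafdomains.simulate import (
    MARKS,
    ScenarioConfig,
    induced_states,
    make_mark_tracks,
    plant_states,
)
from bafdomains.states import STATES, StateError, label_agreement

from conftest import constant_track, iv


MARK_LIST = list(MARKS)


def profile_from_rows(rows, labels=None):
    sites = [iv("chr1", i * 1_000, i * 1_000 + 500) for i in range(len(rows))]
    return StateProfile(sites, MARK_LIST, np.array(rows, dtype=float), labels)


def row(**kwargs):
    base = {m: 0.2 for m in MARK_LIST}
    base.update(kwargs)
    return [base[m] for m in MARK_LIST]


class TestBuildStateMatrix:
    def test_constant_tracks_give_constant_columns(self):
        sites = [iv("chr1", 0, 100), iv("chr1", 5_000, 5_100)]
        tracks = {m: constant_track(v) for m, v in
                  zip(MARK_LIST, [1.0, 2.0, 3.0, 4.0, 5.0])}
        profile = build_state_matrix(sites, tracks)
        assert profile.signal.shape == (2, 5)
        np.testing.assert_allclose(profile.signal[0], profile.signal[1])

    def test_missing_required_mark_errors(self):
        with pytest.raises(StateError, match="H3K27me3"):
            build_state_matrix(
                [iv("chr1", 0, 100)],
                {m: constant_track(1.0) for m in MARK_LIST[:3]},
            )

    def test_missing_chromosome_is_strict(self):
        tracks = {m: constant_track(1.0, chrom="chr1") for m in MARK_LIST}
        from bafdomains.signal import SignalError

        with pytest.raises(SignalError):
            build_state_matrix([iv("chr9", 0, 100)], tracks)


class TestAssignStates:
    @pytest.mark.parametrize(
        "signals, expected",
        [
            (row(H3K27me3=8.0), "polycomb_only"),
            (row(H3K27me3=6.0, H3K4me3=6.0), "bivalent"),
            (row(H3K4me3=10.0, H3K27ac=8.0), "active_promoter"),
            (row(H3K4me1=8.0, H3K27ac=8.0), "active_enhancer"),
            (row(H3K4me1=8.0), "primed_enhancer"),
            (row(), "no_signal"),
        ],
    )
    def test_rule_cases(self, signals, expected):
        labeled = assign_states(profile_from_rows([signals]), thresholds=1.0)
        assert labeled.labels == [expected]

    def test_every_site_gets_exactly_one_label(self, rng):
        rows = rng.exponential(2.0, size=(200, len(MARK_LIST)))
        labeled = assign_states(profile_from_rows(rows.tolist()))
        assert len(labeled.labels) == 200
        assert set(labeled.labels) <= set(STATES)

    def test_missing_threshold_errors(self):
        with pytest.raises(StateError):
            assign_states(profile_from_rows([row()]), thresholds={"H3K4me1": 1.0})


class TestHclusterSites:
    def test_k1_and_kn_edges(self):
        profile = profile_from_rows([row(), row(H3K27me3=9.0), row(H3K4me1=9.0)])
        assert list(hcluster_sites(profile, 1)) == [1, 1, 1]
        assert sorted(hcluster_sites(profile, 3)) == [1, 2, 3]
        with pytest.raises(StateError):
            hcluster_sites(profile, 4)

    def test_two_blobs_recovered_exactly(self, rng):
        from oracles import two_partition_oracle

        a = np.abs(rng.normal(0.3, 0.05, size=(6, len(MARK_LIST))))
        b = np.abs(rng.normal(9.0, 0.05, size=(5, len(MARK_LIST))))
        rows = np.vstack([a, b])
        profile = profile_from_rows(rows.tolist())
        got = hcluster_sites(profile, 2)
        # blob membership must match the exhaustive minimum-variance 2-partition
        x = np.log2(1 + rows)
        x = (x - x.mean(axis=0)) / np.where(x.std(axis=0) == 0, 1, x.std(axis=0))
        oracle = two_partition_oracle(x)
        same = [int(g == got[0]) for g in got]
        flipped = [1 - s for s in same]
        oracle_norm = [int(o == oracle[0]) for o in oracle]
        assert same == oracle_norm or flipped == oracle_norm

    def test_permutation_invariant_up_to_relabeling(self, rng):
        rows = rng.exponential(2.0, size=(30, len(MARK_LIST)))
        profile = profile_from_rows(rows.tolist())
        labels = hcluster_sites(profile, 4)
        perm = rng.permutation(30)
        shuffled = profile_from_rows(rows[perm].tolist())
        labels_shuffled = hcluster_sites(shuffled, 4)
        # matched partitions: co-membership must be identical
        for i in range(30):
            for j in range(i + 1, 30):
                assert (labels[perm[i]] == labels[perm[j]]) == (
                    labels_shuffled[i] == labels_shuffled[j]
                )


class TestStateChangeSummary:
    def test_no_change_gives_zeros(self):
        before = assign_states(profile_from_rows([row(H3K27me3=8.0), row()]))
        out = state_change_summary(before, before)
        np.testing.assert_allclose(out.to_numpy(), 0.0)

    def test_single_site_doubling_closed_form(self):
        s = 3.0
        before = assign_states(profile_from_rows([row(H3K4me1=s)]))
        after = profile_from_rows([row(H3K4me1=2 * s)])
        out = state_change_summary(before, after, pseudocount=1.0)
        expected = np.log2((2 * s + 1) / (s + 1))
        assert out.loc["primed_enhancer", "H3K4me1"] == pytest.approx(expected)

    def test_group_mean_is_arithmetic_mean(self):
        before = assign_states(profile_from_rows([row(), row()]))
        after = profile_from_rows([row(H3K27ac=1.0), row(H3K27ac=3.0)])
        out = state_change_summary(before, after, pseudocount=1.0)
        per_site = [np.log2((1.0 + 1) / (0.2 + 1)), np.log2((3.0 + 1) / (0.2 + 1))]
        assert out.loc["no_signal", "H3K27ac"] == pytest.approx(np.mean(per_site))

    def test_site_mismatch_errors(self):
        a = assign_states(profile_from_rows([row()]))
        b = assign_states(profile_from_rows([row(), row()]))
        with pytest.raises(StateError):
            state_change_summary(a, b)


class TestReversibility:
    def test_identical_labels_score_one(self):
        p = assign_states(profile_from_rows([row(H3K27me3=8.0), row()]))
        assert reversibility_score(p, p).score == 1.0

    def test_all_labels_differ_score_zero(self):
        ctrl = assign_states(profile_from_rows([row(H3K27me3=8.0), row()]))
        rev = assign_states(
            profile_from_rows([row(H3K4me1=8.0, H3K27ac=8.0), row(H3K27me3=8.0)])
        )
        assert reversibility_score(ctrl, rev).score == 0.0

    def test_partial_match_counted(self):
        rows_ctrl = [row(H3K27me3=8.0)] * 5 + [row()] * 5
        rows_rev = [row(H3K27me3=8.0)] * 5 + [row(H3K4me1=8.0)] * 5
        ctrl = assign_states(profile_from_rows(rows_ctrl))
        rev = assign_states(profile_from_rows(rows_rev))
        report = reversibility_score(ctrl, rev)
        assert report.score == pytest.approx(0.5)
        assert report.per_state.loc["polycomb_only", "reverted"] == 1.0
        assert report.per_state.loc["no_signal", "reverted"] == 0.0


class TestSyntheticStateRecovery:
    def test_noise_free_tracks_recover_planted_labels_exactly(self, rng):
        config = ScenarioConfig(seed=3)
        sites = [iv("chr1", i * 5_000, i * 5_000 + 1_000) for i in range(300)]
        planted = plant_states(config, len(sites), rng)
        tracks = make_mark_tracks(
            config, sites, {"control": planted}, rng, noise_sd=0.0
        )
        profile = build_state_matrix(sites, tracks["control"])
        labeled = assign_states(profile, thresholds=1.0)
        assert labeled.labels == planted

    def test_induction_map_activates_repressed_states(self):
        planted = ["polycomb_only", "bivalent", "primed_enhancer", "no_signal",
                   "active_promoter", "active_enhancer"]
        induced = induced_states(planted)
        assert induced == ["active_enhancer", "active_promoter",
                           "active_enhancer", "active_enhancer",
                           "active_promoter", "active_enhancer"]
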