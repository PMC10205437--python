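from itertools import permutations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dais.errors import InvalidFeatureError
from dais.feature_tracking import (
    FeatureTrack,
    MatchingConfig,
    build_tracks,
    is_match,
    pair_tracks,
    sim_raw,
)
from dais.persistent_homology import Diagram, PersistenceFeature


def feat(gens, frame=0, dim=1, birth=1.0, death=5.0, fid=0):
    return PersistenceFeature(
        frame_index=frame,
        dimension=dim,
        birth=birth,
        death=death,
        generators=frozenset(gens),
        feature_id=fid,
    )


def diagram(frame, *featurespecs):
    feats = [
        feat(g, frame=frame, fid=i, **kw)
        for i, (g, kw) in enumerate(featurespecs)
    ]
    return Diagram(frame_index=frame, features=feats)


CFG = MatchingConfig(delta=0.75, min_persistence=0.0, min_track_fraction=0.0)


class TestSimRaw:
    def test_identical_sets(self):
        p = feat({"a", "b", "c"})
        assert sim_raw(p, p) == 1.0

    def test_disjoint_sets(self):
        assert sim_raw(feat({"a"}), feat({"b"})) == 0.0

    def test_printed_formula_three_quarters(self):
        p = feat({"a", "b", "c"})
        q = feat({"a", "b", "c", "d"})
        assert sim_raw(p, q) == 0.75

    def test_empty_generators_invalid(self):
        with pytest.raises(InvalidFeatureError):
            sim_raw(feat(set()), feat({"a"}))

    @settings(max_examples=200, deadline=None)
    @given(
        a=st.sets(st.integers(0, 30), min_size=1, max_size=12),
        b=st.sets(st.integers(0, 30), min_size=1, max_size=12),
    )
    def test_symmetry_and_bounds(self, a, b):
        p, q = feat(a), feat(b)
        s = sim_raw(p, q)
        assert 0.0 <= s <= 1.0
        assert s == sim_raw(q, p)


class TestIsMatch:
    def test_exactly_at_delta_does_not_match(self):
        """Sim equal to the threshold is rejected — the gate is strict."""
        p = feat({"a", "b", "c"})
        q = feat({"a", "b", "c", "d"})  # sim = 0.75
        assert sim_raw(p, q) == 0.75
        assert not is_match(p, q, CFG)

    def test_just_above_delta_matches(self):
        p = feat(set(range(76)))
        q = feat(set(range(100)))  # sim = 0.76
        assert is_match(p, q, CFG)

    def test_identical_always_matches(self):
        p = feat({"a"})
        assert is_match(p, p, MatchingConfig(delta=0.99))

    def test_dimension_gate(self):
        p = feat({"a", "b"}, dim=1)
        q = feat({"a", "b"}, dim=2)
        assert not is_match(p, q, CFG)
        relaxed = MatchingConfig(delta=0.75, require_same_dimension=False)
        assert is_match(p, q, relaxed)


class TestBuildTracks:
    def test_identical_diagrams_full_tracks(self):
        dgs = [
            diagram(t, ({"a", "b", "c"}, {}), ({"x", "y", "z"}, {"birth": 2.0, "death": 8.0}))
            for t in range(10)
        ]
        tracks = build_tracks(dgs, CFG)
        assert len(tracks) == 2
        assert all(len(t) == 10 for t in tracks)

    def test_disappearing_feature_closes_track(self):
        dgs = [
            diagram(t, ({"a", "b"}, {}), ({"p", "q"}, {"birth": 2.0}))
            if t < 5
            else diagram(t, ({"a", "b"}, {}))
            for t in range(10)
        ]
        tracks = build_tracks(dgs, CFG)
        lengths = sorted(len(t) for t in tracks)
        assert lengths == [5, 10]
        short = min(tracks, key=len)
        assert short.last_frame == 4  # disappeared after frame 4

    def test_generator_swap_breaks_tracks(self):
        """When two features exchange half their generators the overlap
        (0.5) falls below delta: old tracks end, new ones start."""
        g1, g2 = {"a", "b", "c", "d"}, {"w", "x", "y", "z"}
        s1, s2 = {"a", "b", "y", "z"}, {"w", "x", "c", "d"}
        dgs = [
            diagram(t, (g1 if t < 3 else s1, {}), (g2 if t < 3 else s2, {"birth": 2.0}))
            for t in range(6)
        ]
        tracks = build_tracks(dgs, CFG)
        assert sorted(len(t) for t in tracks) == [3, 3, 3, 3]

    def test_deterministic(self):
        dgs = [
            diagram(t, ({"a", "b", "c"}, {}), ({"a", "b", "d"}, {"birth": 1.1}))
            for t in range(5)
        ]
        t1 = build_tracks(dgs, CFG)
        t2 = build_tracks(dgs, CFG)
        assert [
            [(f.frame_index, f.generators) for _, f in tr.entries] for tr in t1
        ] == [
            [(f.frame_index, f.generators) for _, f in tr.entries] for tr in t2
        ]

    def test_feature_order_permutation_invariant(self):
        base = [
            ({"a", "b", "c"}, {}),
            ({"x", "y", "z"}, {"birth": 2.0}),
            ({"m", "n", "o"}, {"birth": 3.0}),
        ]
        dgs_fwd = [diagram(t, *base) for t in range(6)]
        dgs_rev = [diagram(t, *reversed(base)) for t in range(6)]
        as_sets = lambda tracks: sorted(
            tuple((t, tuple(sorted(f.generators))) for t, f in tr.entries)
            for tr in tracks
        )
        assert as_sets(build_tracks(dgs_fwd, CFG)) == as_sets(
            build_tracks(dgs_rev, CFG)
        )


def track(label, gens, n=5, dim=1, birth=1.0, death=5.0, tid=0):
    entries = [
        (t, feat(gens, frame=t, dim=dim, birth=birth, death=death, fid=tid))
        for t in range(n)
    ]
    return FeatureTrack(label, dim, entries, track_id=tid)


class TestPairTracks:
    def test_case_copy_pairs_everything(self):
        ctl = [track("control", {"a", "b"}, tid=0), track("control", {"x", "y"}, tid=1, birth=2.0)]
        cas = [track("case", {"a", "b"}, tid=0), track("case", {"x", "y"}, tid=1, birth=2.0)]
        res = pair_tracks(ctl, cas, CFG)
        assert len(res.pairs) == 2
        assert all(p.anchor_similarity == 1.0 for p in res.pairs)
        assert not res.unpaired_control and not res.unpaired_case

    def test_case_only_feature_reported_unpaired(self):
        ctl = [track("control", {"a", "b"}, tid=0)]
        cas = [track("case", {"a", "b"}, tid=0), track("case", {"a", "p", "q", "r"}, tid=1)]
        res = pair_tracks(ctl, cas, CFG)
        assert len(res.pairs) == 1
        assert [t.track_id for t in res.unpaired_case] == [1]

    def test_greedy_matches_exhaustive_on_3x3(self):
        """The greedy pairing must equal brute force over all 3!
        assignments under the greedy (descending-similarity) rule."""
        # engineered similarity structure via shared generators
        gens_c = [{"a", "b", "c", "d"}, {"e", "f", "g", "h"}, {"i", "j", "k", "l"}]
        gens_k = [
            {"a", "b", "c", "x"},  # 3/4 with c0
            {"e", "f", "g", "h"},  # 1.0 with c1
            {"i", "j", "k", "d"},  # 3/4 with c2
        ]
        cfg = MatchingConfig(delta=0.5, min_track_fraction=0.0)
        ctl = [track("control", g, tid=i) for i, g in enumerate(gens_c)]
        cas = [track("case", g, tid=i) for i, g in enumerate(gens_k)]
        res = pair_tracks(ctl, cas, cfg)
        got = {(p.control_track.track_id, p.case_track.track_id) for p in res.pairs}

        # brute-force greedy: repeatedly take the globally best admissible pair
        sims = {
            (i, j): sim_raw(ctl[i].entries[0][1], cas[j].entries[0][1])
            for i in range(3)
            for j in range(3)
        }
        want, used_i, used_j = set(), set(), set()
        for (i, j), s in sorted(sims.items(), key=lambda kv: -kv[1]):
            if s > cfg.delta and i not in used_i and j not in used_j:
                want.add((i, j))
                used_i.add(i)
                used_j.add(j)
        assert got == want

    def test_short_tracks_dropped_with_frame_count(self):
        ctl = [track("control", {"a", "b"}, n=2, tid=0)]
        cas = [track("case", {"a", "b"}, n=2, tid=0)]
        res = pair_tracks(ctl, cas, MatchingConfig(), n_frames=100)
        assert res.pairs == []
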