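"""Two-condition matching and threshold-based differential calling."""

import numpy as np
import pytest

import srnapipe as sp
from conftest import make_candidate


def cand(start, end, read_count=50, strand="+", cls="IGR", uid="u"):
    return make_candidate(srna_class=cls, start=start, end=end,
                          read_count=read_count, strand=strand, uid=uid)


class TestMatchUnits:
    def test_identical_intervals(self):
        pairs, un_nl, un_hl = sp.match_units([cand(100, 199, uid="n1")],
                                             [cand(100, 199, uid="h1")])
        assert len(pairs) == 1 and pairs[0][2] == pytest.approx(1.0)
        assert un_nl == [] and un_hl == []

    def test_ten_percent_overlap_boundary(self):
        # 10 shared nt over two 100-nt units: exactly at the threshold
        pairs, *_ = sp.match_units([cand(100, 199, uid="n1")],
                                   [cand(190, 289, uid="h1")])
        assert len(pairs) == 1 and pairs[0][2] == pytest.approx(0.10)

    def test_below_threshold_unmatched(self):
        pairs, un_nl, un_hl = sp.match_units([cand(100, 199, uid="n1")],
                                             [cand(191, 290, uid="h1")])
        assert pairs == [] and len(un_nl) == len(un_hl) == 1

    def test_opposite_strands_never_match(self):
        pairs, un_nl, un_hl = sp.match_units([cand(100, 199, strand="+", uid="n1")],
                                             [cand(100, 199, strand="-", uid="h1")])
        assert pairs == [] and len(un_nl) == len(un_hl) == 1

    def test_shorter_unit_is_denominator(self):
        # 50-nt HL unit fully inside a 200-nt NL unit: overlap fraction 1.0
        pairs, *_ = sp.match_units([cand(100, 299, uid="n1")],
                                   [cand(150, 199, uid="h1")])
        assert pairs[0][2] == pytest.approx(1.0)

    def test_one_to_one_greedy(self):
        nl = [cand(100, 199, uid="n1"), cand(120, 219, uid="n2")]
        hl = [cand(100, 199, uid="h1")]
        pairs, un_nl, un_hl = sp.match_units(nl, hl)
        assert len(pairs) == 1
        assert pairs[0][0].unit.id == "n1"          # maximal-overlap pair wins
        assert [c.unit.id for c in un_nl] == ["n2"]

    def test_jittered_pairs_plus_singletons(self):
        rng = np.random.default_rng(12)
        nl, hl = [], []
        for k in range(20):
            s = 1000 * (k + 1)
            e = s + int(rng.integers(80, 200))
            nl.append(cand(s, e, uid=f"n{k}"))
            hl.append(cand(s + int(rng.integers(0, 4)), e - int(rng.integers(0, 4)),
                           uid=f"h{k}"))
        for k in range(5):
            nl.append(cand(50_000 + 1000 * k, 50_100 + 1000 * k, uid=f"s{k}"))
        pairs, un_nl, un_hl = sp.match_units(nl, hl)
        assert len(pairs) == 20 and len(un_nl) == 5 and un_hl == []
        assert all(a.unit.id[1:] == b.unit.id[1:] for a, b, _ in pairs)


class TestCallStatus:
    def call(self, nl_reads, hl_reads, **kw):
        params = sp.DiffParams(**kw)
        nl = cand(100, 199, read_count=nl_reads, uid="n1") if nl_reads is not None else None
        hl = cand(100, 199, read_count=hl_reads, uid="h1") if hl_reads is not None else None
        return sp.call_status(nl, hl, params, overlap_frac=1.0)

    def test_up_regulated(self):
        c = self.call(10, 30)
        assert (c.status, c.ratio) == ("up", pytest.approx(3.0))

    def test_down_boundary_inclusive(self):
        c = self.call(40, 20)
        assert (c.status, c.ratio) == ("down", pytest.approx(0.5))

    def test_up_boundary_inclusive(self):
        assert self.call(20, 40).status == "up"

    def test_dead_zone_unchanged(self):
        assert self.call(12, 18).status == "unchanged"

    def test_nl_only_unique(self):
        assert self.call(15, None).status == "unique_NL"

    def test_hl_only_unique(self):
        assert self.call(None, 15).status == "unique_HL"

    def test_below_min_reads_dropped(self):
        assert self.call(9, 8) is None
        assert self.call(9, None) is None

    def test_min_reads_is_either_library(self):
        # "at least 10 reads under NL or HL" reads as max(NL, HL) >= 10
        assert self.call(3, 12).status == "up"

    def test_matched_pair_with_zero_nl_is_unique(self):
        assert self.call(0, 30).status == "unique_HL"

    def test_normalization(self):
        nl = cand(100, 199, read_count=100, uid="n1")
        hl = cand(100, 199, read_count=100, uid="h1")
        params = sp.DiffParams(normalize=True)
        out = sp.call_status(nl, hl, params, 1.0,
                             nl_library_size=1_000_000, hl_library_size=4_000_000)
        assert out.ratio == pytest.approx(0.25) and out.status == "down"


def random_candidate_sets(seed):
    rng = np.random.default_rng(seed)
    nl, hl = [], []
    for k in range(40):
        s = 500 * (k + 1)
        e = s + int(rng.integers(50, 250))
        strand = "+-"[rng.integers(0, 2)]
        if rng.random() < 0.8:
            nl.append(cand(s, e, int(rng.integers(0, 120)), strand, uid=f"n{k}"))
        if rng.random() < 0.8:
            hl.append(cand(s + int(rng.integers(0, 10)), e + int(rng.integers(0, 10)),
                           int(rng.integers(0, 120)), strand, uid=f"h{k}"))
    return nl, hl


class TestDiffCalls:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_label_swap_symmetry(self, seed):
        """Swapping the NL/HL libraries maps up<->down and unique_NL<->unique_HL."""
        nl, hl = random_candidate_sets(seed)
        fwd, d1 = sp.diff_calls(nl, hl)
        rev, d2 = sp.diff_calls(hl, nl)
        swap = {"up": "down", "down": "up", "unchanged": "unchanged",
                "unique_NL": "unique_HL", "unique_HL": "unique_NL"}
        assert d1 == d2
        fwd_counts = {}
        for c in fwd:
            fwd_counts[c.status] = fwd_counts.get(c.status, 0) + 1
        rev_counts = {}
        for c in rev:
            rev_counts[swap[c.status]] = rev_counts.get(swap[c.status], 0) + 1
        assert fwd_counts == rev_counts

    @pytest.mark.parametrize("seed", [1, 5])
    def test_conservation(self, seed):
        """Every candidate lands in exactly one pair call, unique call, or drop."""
        nl, hl = random_candidate_sets(seed)
        calls, dropped = sp.diff_calls(nl, hl)
        n_pair = sum(1 for c in calls if c.status in ("up", "down", "unchanged"))
        n_unique = sum(1 for c in calls if c.status.startswith("unique"))
        n_zero_side = sum(1 for c in calls
                          if c.status.startswith("unique") and c.nl_unit_id and c.hl_unit_id)
        assert 2 * n_pair + n_unique + n_zero_side + dropped == len(nl) + len(hl)

    def test_empty_inputs(self):
        calls, dropped = sp.diff_calls([], [])
        assert calls == [] and dropped == 0
        assert sp.diff_summary([]).empty


class TestDiffSummary:
    def test_counts_by_status_and_class(self):
        nl = [cand(1000, 1100, 10, uid="n1", cls="asRNA"),
              cand(3000, 3100, 40, uid="n2", cls="IGR"),
              cand(5000, 5100, 15, uid="n3", cls="LR5")]
        hl = [cand(1000, 1100, 30, uid="h1", cls="asRNA"),
              cand(3000, 3100, 20, uid="h2", cls="IGR")]
        calls, _ = sp.diff_calls(nl, hl)
        df = sp.diff_summary(calls)
        overall = df[df.srna_class == "all"].set_index("status")["count"]
        assert overall.to_dict() == {"up": 1, "down": 1, "unique_NL": 1}
        by_class = df[df.srna_class != "all"].set_index(["status", "srna_class"])["count"]
        assert by_class[("up", "asRNA")] == 1
        assert by_class[("unique_NL", "LR5")] == 1

    def test_all_ratio_one_unchanged(self):
        nl = [cand(1000 * k, 1000 * k + 99, 20, uid=f"n{k}") for k in range(1, 6)]
        hl = [cand(1000 * k, 1000 * k + 99, 20, uid=f"h{k}") for k in range(1, 6)]
        calls, _ = sp.diff_calls(nl, hl)
        assert all(c.status == "unchanged" for c in calls)

    def test_fold_change_histogram_counts_matched_only(self):
        nl = [cand(1000, 1099, 10, uid="n1"), cand(3000, 3099, 20, uid="n2")]
        hl = [cand(1000, 1099, 40, uid="h1")]
        calls, _ = sp.diff_calls(nl, hl)
        df = sp.fold_change_histogram(calls, bins=5)
        assert df["count"].sum() == 1
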