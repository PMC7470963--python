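"""RBP 3'UTR binding enrichment and the polyA-proximal metaprofile."""

import numpy as np
import pandas as pd
import pytest

from brudecay.rbp_rank import (
    NARROWPEAK_COLUMNS,
    polya_profile,
    rank_rbps,
    read_narrowpeak,
    replicate_consensus,
    score_rbp,
    select_gene_sets,
)


def peaks_frame(rows):
    """rows: (chrom, start, end, signalValue)"""
    return pd.DataFrame(
        [
            {
                "chrom": c, "start": s, "end": e, "name": f"p{i}", "score": 0,
                "strand": ".", "signalValue": sv, "pValue": -1.0,
                "qValue": -1.0, "peak": (e - s) // 2,
            }
            for i, (c, s, e, sv) in enumerate(rows)
        ],
        columns=NARROWPEAK_COLUMNS,
    )


class TestSelectGeneSets:
    def test_extremes_of_relative_change(self):
        rel = {"a": -0.5, "b": -0.1, "c": 0.2, "d": 0.4}
        most, least = select_gene_sets(rel, k=1)
        assert most == ["a"] and least == ["d"]

    def test_partitions_disjoint_and_sized(self):
        rng = np.random.default_rng(0)
        rel = {f"g{i}": float(v) for i, v in enumerate(rng.normal(0, 1, 50))}
        most, least = select_gene_sets(rel, k=20)
        assert len(most) == len(least) == 20
        assert not set(most) & set(least)

    def test_shrinks_k_when_genes_scarce(self):
        rel = {f"g{i}": float(i) for i in range(10)}
        with pytest.warns(UserWarning, match="using k=5"):
            most, least = select_gene_sets(rel, k=400)
        assert len(most) == len(least) == 5

    def test_degenerate_ties_broken_by_gene_id(self):
        rel = {"b": 0.0, "a": 0.0, "d": 0.0, "c": 0.0}
        most, least = select_gene_sets(rel, k=2)
        assert most == ["a", "b"] and least == ["c", "d"]


UTR3 = {
    **{f"m{i}": [("chr1", 1000 * i, 1000 * i + 500)] for i in range(3)},
    **{f"l{i}": [("chr2", 1000 * i, 1000 * i + 500)] for i in range(3)},
}


class TestScoreRBP:
    def test_scores_sum_peak_signal_in_utr(self):
        peaks = peaks_frame(
            [("chr1", 100, 200, 3.0), ("chr1", 300, 400, 2.0), ("chr2", 100, 200, 7.0)]
        )
        scores, _ = score_rbp(peaks, UTR3, ["m0", "m1", "m2"], ["l0", "l1", "l2"])
        assert scores["m0"] == 5.0 and scores["l0"] == 7.0 and scores["m1"] == 0.0

    def test_small_sample_rank_sum_p(self):
        # scores most={3,4,5}, least={0,1,2} -> one-sided p = 1/20
        peaks = peaks_frame(
            [("chr1", 0, 50, 3.0), ("chr1", 1000, 1050, 4.0), ("chr1", 2000, 2050, 5.0),
             ("chr2", 1000, 1050, 1.0), ("chr2", 2000, 2050, 2.0)]
        )
        _, p = score_rbp(peaks, UTR3, ["m0", "m1", "m2"], ["l0", "l1", "l2"])
        assert p == pytest.approx(0.05)

    def test_identical_binding_not_significant(self):
        peaks = peaks_frame(
            [("chr1", 1000 * i, 1000 * i + 50, 2.0) for i in range(3)]
            + [("chr2", 1000 * i, 1000 * i + 50, 2.0) for i in range(3)]
        )
        _, p = score_rbp(peaks, UTR3, ["m0", "m1", "m2"], ["l0", "l1", "l2"])
        assert p >= 0.5

    def test_peakless_rbp_ranks_last(self):
        empty = peaks_frame([("chr9", 0, 10, 1.0)])  # no UTR overlap
        _, p = score_rbp(empty, UTR3, ["m0", "m1"], ["l0", "l1"])
        assert p == 1.0

    def test_p_invariant_under_signal_rescaling(self):
        rows = [("chr1", 0, 50, 3.0), ("chr1", 1000, 1050, 9.0), ("chr2", 0, 50, 1.0)]
        _, p1 = score_rbp(peaks_frame(rows), UTR3, ["m0", "m1", "m2"], ["l0", "l1", "l2"])
        scaled = [(c, s, e, 100 * sv) for c, s, e, sv in rows]
        _, p2 = score_rbp(peaks_frame(scaled), UTR3, ["m0", "m1", "m2"], ["l0", "l1", "l2"])
        assert p1 == p2


class TestRankRBPs:
    def _simulation(self, seed, frac_most=0.8, frac_least=0.1, n_decoys=50):
        rng = np.random.default_rng(seed)
        n = 20
        utr3 = {
            **{f"m{i}": [("chr1", 2000 * i, 2000 * i + 500)] for i in range(n)},
            **{f"l{i}": [("chr2", 2000 * i, 2000 * i + 500)] for i in range(n)},
        }
        most = [f"m{i}" for i in range(n)]
        least = [f"l{i}" for i in range(n)]

        def place(gene_ids):
            rows = []
            for g in gene_ids:
                chrom, s, _ = utr3[g][0]
                rows.append((chrom, s + 10, s + 60, 1.0))
            return peaks_frame(rows)

        planted_genes = [g for g in most if rng.random() < frac_most] + [
            g for g in least if rng.random() < frac_least
        ]
        rbps = {"planted": place(planted_genes)}
        for d in range(n_decoys):
            hit = [g for g in most + least if rng.random() < 0.3]
            rbps[f"decoy{d:02d}"] = place(hit)
        return rbps, utr3, most, least

    def test_planted_rbp_ranks_first(self):
        rbps, utr3, most, least = self._simulation(seed=11)
        ranking = rank_rbps(rbps, utr3, most, least)
        assert ranking.iloc[0]["rbp_id"] == "planted"

    def test_null_simulation_rarely_ranks_fixed_decoy_first(self):
        # without a planted signal, decoy00 tops the ranking at chance rate
        firsts = 0
        n_runs = 40
        for seed in range(n_runs):
            rbps, utr3, most, least = self._simulation(
                seed=seed, frac_most=0.3, frac_least=0.3, n_decoys=19
            )
            ranking = rank_rbps(rbps, utr3, most, least)
            if ranking.iloc[0]["rbp_id"] == "decoy00":
                firsts += 1
        assert firsts / n_runs <= 0.15  # ~1/20 expected for 20 null RBPs


class TestReplicateConsensus:
    def test_identical_replicates_all_retained(self):
        p = peaks_frame([("chr1", 100, 200, 1.0), ("chr2", 0, 50, 2.0)])
        assert len(replicate_consensus(p, p.copy())) == 2

    def test_disjoint_replicates_empty(self):
        a = peaks_frame([("chr1", 100, 200, 1.0)])
        b = peaks_frame([("chr1", 300, 400, 1.0)])
        assert len(replicate_consensus(a, b)) == 0

    def test_single_base_overlap_retained(self):
        a = peaks_frame([("chr1", 100, 200, 1.0)])
        b = peaks_frame([("chr1", 199, 300, 1.0)])
        kept = replicate_consensus(a, b)
        assert len(kept) == 1
        # but adjacent (zero-overlap) peaks are not shared
        c = peaks_frame([("chr1", 200, 300, 1.0)])
        assert len(replicate_consensus(a, c)) == 0

    def test_empty_input_warns(self):
        a = peaks_frame([("chr1", 100, 200, 1.0)])
        with pytest.warns(UserWarning, match="empty"):
            out = replicate_consensus(a, a.iloc[0:0])
        assert len(out) == 0


class TestPolyAProfile:
    def test_density_unit_conversion(self):
        # 50 events in one 100-bp bin out of 10,000 total binding events:
        # density = 50 / 0.1 kb / 0.01 million = 50,000 per kb per million
        rows = [("chr1", 10_000 + 2 * i, 10_000 + 2 * i + 1, 1.0) for i in range(50)]
        rows += [("chrX", 5_000_000 + 10 * i, 5_000_000 + 10 * i + 1, 1.0)
                 for i in range(9_950)]  # far from any polyA site
        profile = polya_profile(
            peaks_frame(rows), [("chr1", 10_100, "+")], window=200, bin_size=100
        )
        assert profile.n_events_total == 10_000
        idx = np.flatnonzero(profile.density)
        assert len(idx) == 1 and profile.edges[idx[0]] == -100
        assert profile.density[idx[0]] == pytest.approx(50_000.0)
        # invariant: density x bin_kb x (total/1e6) recovers in-window events
        events = profile.density * 0.1 * (profile.n_events_total / 1e6)
        assert events.sum() == pytest.approx(profile.n_events_in_window)

    def test_uniform_placement_gives_flat_profile(self):
        rng = np.random.default_rng(2)
        n = 4000
        starts = rng.integers(9_000, 11_000, n)
        peaks = peaks_frame([("chr1", int(s), int(s) + 1, 1.0) for s in starts])
        profile = polya_profile(peaks, [("chr1", 10_000, "+")], window=1000, bin_size=100)
        counts = profile.density * 0.1 * (n / 1e6)  # events per bin
        lam = n / len(counts)
        assert np.all(np.abs(counts - lam) < 3 * np.sqrt(lam))

    def test_zero_peaks_zero_profile(self):
        profile = polya_profile(peaks_frame([]), [("chr1", 100, "+")], 200, 50)
        assert np.all(profile.density == 0)

    def test_strand_aware_offsets(self):
        # minus-strand gene: positions downstream in genome are upstream in RNA
        peaks = peaks_frame([("chr1", 10_150, 10_170, 1.0)])
        prof_minus = polya_profile(peaks, [("chr1", 10_000, "-")], 400, 100)
        idx = np.flatnonzero(prof_minus.density)
        assert prof_minus.edges[idx[0]] == -200  # offset = site - midpoint = -160

    def test_window_must_tile_bins(self):
        with pytest.raises(ValueError):
            polya_profile(peaks_frame([]), [], window=150, bin_size=100)


def test_narrowpeak_reader_roundtrip(tmp_path):
    df = peaks_frame([("chr1", 5, 50, 3.5), ("chr2", 7, 99, 1.25)])
    path = tmp_path / "x.narrowPeak"
    df.to_csv(path, sep="\t", header=False, index=False)
    back = read_narrowpeak(str(path))
    assert list(back["signalValue"]) == [3.5, 1.25]
    assert list(back.columns) == NARROWPEAK_COLUMNS
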