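import itertools

import numpy as np
import pytest

from unipeak.annotate import (
    FeatureSet,
    annotate_regions,
    consensus_labels,
    constraint_fraction,
    gene_body_count,
    longest_isoform,
    match_nearest,
    sequence_composition,
)
from unipeak.io import Interval, ScoreTrack
from unipeak.motifs import (
    PWM,
    MotifScorer,
    collapse_motif_sets,
    parse_meme,
    reverse_complement,
    scan_motifs,
)

from conftest import make_track


def features(positions, strands=None, kind="tss", chrom="chr1"):
    return FeatureSet(
        kind=kind,
        positions={chrom: np.asarray(positions, dtype=np.int64)},
        strands={chrom: np.asarray(strands)} if strands is not None else None,
    )


class TestMatchNearest:
    def test_within_range_and_signed_distance(self):
        (m,) = match_nearest([("chr1", 1000)], features([1400]))
        assert m is not None and m.feature_pos == 1400
        assert m.signed_distance == 400

    def test_strict_distance_boundary(self):
        (m500,) = match_nearest([("chr1", 1000)], features([1500]))
        (m501,) = match_nearest([("chr1", 1000)], features([1501]))
        assert m500 is not None and m501 is None

    def test_nearest_wins_and_ties_take_smaller_coordinate(self):
        (m,) = match_nearest([("chr1", 1000)], features([700, 1200]))
        assert m.feature_pos == 1200
        (tie,) = match_nearest([("chr1", 1000)], features([800, 1200]))
        assert tie.feature_pos == 800

    def test_minus_strand_flips_sign(self):
        (m,) = match_nearest([("chr1", 1000)], features([1400], strands=["-"]))
        assert m.signed_distance == -400 and m.strand == "-"

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(0)
        feats = np.sort(rng.choice(100_000, 200, replace=False))
        peaks = [("chr1", int(p)) for p in rng.integers(0, 100_000, 300)]
        got = match_nearest(peaks, features(feats), max_dist=500)
        for (chrom, peak), m in zip(peaks, got):
            best = min(feats, key=lambda f: (abs(int(f) - peak), int(f)))
            if abs(int(best) - peak) > 500:
                assert m is None
            else:
                assert m is not None and m.feature_pos == int(best)

    def test_chromosome_without_features(self):
        (m,) = match_nearest([("chr9", 10)], features([10]))
        assert m is None


class TestConsensus:
    def test_all_three_required(self):
        peaks = [("chr1", 1000), ("chr1", 5000), ("chr1", 9000)]
        kinds = {
            "polII_peak": features([1100, 5100], kind="polII_peak"),
            "cage_peak": features([1200, 9200], kind="cage_peak"),
            "tss": features([1300, 5300, 9300], kind="tss"),
        }
        matches = {k: match_nearest(peaks, fs) for k, fs in kinds.items()}
        labels = consensus_labels(matches)
        assert labels.tolist() == [True, False, False]

    def test_counts_equal_triple_intersection_oracle(self):
        rng = np.random.default_rng(1)
        peaks = [("chr1", int(p)) for p in rng.integers(0, 50_000, 100)]
        kinds = {
            k: features(np.sort(rng.choice(50_000, 60, replace=False)), kind=k)
            for k in ("polII_peak", "cage_peak", "tss")
        }
        matches = {k: match_nearest(peaks, fs) for k, fs in kinds.items()}
        labels = consensus_labels(matches)
        for (chrom, peak), label in zip(peaks, labels):
            oracle = all(
                any(abs(int(f) - peak) <= 500 for f in kinds[k].positions["chr1"])
                for k in kinds
            )
            assert label == oracle

    def test_consensus_monotone_in_max_dist(self):
        rng = np.random.default_rng(2)
        peaks = [("chr1", int(p)) for p in rng.integers(0, 50_000, 200)]
        kinds = {
            k: features(np.sort(rng.choice(50_000, 40, replace=False)), kind=k)
            for k in ("polII_peak", "cage_peak", "tss")
        }
        counts = []
        for d in (100, 300, 500, 1000):
            matches = {k: match_nearest(peaks, fs, max_dist=d) for k, fs in kinds.items()}
            counts.append(consensus_labels(matches).sum())
        assert counts == sorted(counts)


class TestSequenceComposition:
    def test_hand_examples(self):
        gc, cpg = sequence_composition("GCGC")
        assert gc == 1.0
        assert cpg == pytest.approx(1 / 3)  # one CG dinucleotide over 3 pairs
        gc, cpg = sequence_composition("ATAT")
        assert gc == 0.0 and cpg == 0.0

    def test_ns_excluded_from_denominators(self):
        gc, cpg = sequence_composition("GCNN")
        assert gc == 1.0  # 2 of 2 called bases
        assert cpg == 0.0  # only the GC pair is fully called
        gc, cpg = sequence_composition("NNNN")
        assert np.isnan(gc) and np.isnan(cpg)

    def test_soft_masked_bases_count(self):
        assert sequence_composition("acgt") == sequence_composition("ACGT")

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGTN"), 200, p=[0.24, 0.26, 0.25, 0.2, 0.05]))
        gc, cpg = sequence_composition(seq)
        called = [b for b in seq if b in "ACGT"]
        oracle_gc = sum(b in "GC" for b in called) / len(called)
        pairs = [
            seq[i : i + 2]
            for i in range(len(seq) - 1)
            if seq[i] in "ACGT" and seq[i + 1] in "ACGT"
        ]
        oracle_cpg = sum(p == "CG" for p in pairs) / len(pairs)
        assert gc == pytest.approx(oracle_gc, abs=1e-12)
        assert cpg == pytest.approx(oracle_cpg, abs=1e-12)


class TestConstraintFraction:
    def track(self, scores, start=100):
        records = [("chr1", start + i, start + i + 1, s) for i, s in enumerate(scores)]
        return ScoreTrack.from_records(records)

    def test_strict_threshold(self):
        track = self.track([3.0, 1.0, 2.5, 0.0])
        assert constraint_fraction("chr1", 100, 104, track) == 0.5
        track2 = self.track([2.0, 2.0, 2.0])
        assert constraint_fraction("chr1", 100, 103, track2) == 0.0

    def test_uncovered_positions_excluded(self):
        track = ScoreTrack.from_records([("chr1", 100, 102, 5.0)])
        # positions 100,101 scored (both > 2); 102..109 missing
        assert constraint_fraction("chr1", 100, 110, track) == 1.0
        assert np.isnan(constraint_fraction("chr1", 200, 210, track))

    def test_matches_brute_force(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(2.0, 1.5, 50)
        covered = rng.random(50) < 0.6
        records = [
            ("chr1", 100 + i, 101 + i, float(s))
            for i, (s, c) in enumerate(zip(scores, covered))
            if c
        ]
        track = ScoreTrack.from_records(records)
        got = constraint_fraction("chr1", 100, 150, track)
        cov = [s for s, c in zip(scores, covered) if c]
        assert got == pytest.approx(sum(s > 2 for s in cov) / len(cov), abs=1e-12)


class TestGeneBodyCount:
    def test_plus_strand_padding_boundary(self, meta):
        track = make_track([899, 900, 2100, 2101], meta=meta)
        n = gene_body_count(track, "chr1", tss=1000, tes=2000, strand="+")
        assert n == 2  # 900 and 2100 inclusive; 899 and 2101 out

    def test_minus_strand_mirrors_padding(self, meta):
        track = make_track([899, 900, 2100, 2101], meta=meta)
        n = gene_body_count(track, "chr1", tss=2000, tes=1000, strand="-")
        assert n == 2

    def test_strand_inconsistent_gene_rejected(self, meta):
        track = make_track([10], meta=meta)
        with pytest.raises(ValueError):
            gene_body_count(track, "chr1", tss=2000, tes=1000, strand="+")

    def test_matches_brute_force(self, meta):
        rng = np.random.default_rng(5)
        pos = rng.integers(0, 5000, 300)
        track = make_track(pos, meta=meta)
        track.add_hits("chr1", "-", rng.integers(0, 5000, 300))
        n = gene_body_count(track, "chr1", tss=1000, tes=3000, strand="+")
        allpos = np.concatenate(
            [
                np.repeat(*track.strand("chr1", "+")),
                np.repeat(*track.strand("chr1", "-")),
            ]
        )
        assert n == int(((allpos >= 900) & (allpos <= 3100)).sum())

    def test_longest_isoform(self):
        assert longest_isoform([(0, 100), (0, 500), (50, 200)]) == (0, 500)


class TestMotifScanner:
    def pwm(self, seed=0, width=5, set_id="setA", name="m"):
        rng = np.random.default_rng(seed)
        return PWM(name, rng.dirichlet(np.ones(4) * 0.5, size=width), set_id)

    def embed(self, core, seed=9, length=201):
        rng = np.random.default_rng(seed)
        seq = list(rng.choice(list("ACGT"), length))
        mid = length // 2
        seq[mid : mid + len(core)] = list(core)
        return "".join(seq)

    def test_consensus_scores_maximal_and_hits(self):
        pwm = self.pwm()
        seq = self.embed(pwm.consensus())
        fetch = lambda c, a, b: seq[a:b]
        table = scan_motifs([("chr1", 100)], [pwm], fetch, window=201)
        assert bool(table.iloc[0, 0])
        scorer = MotifScorer(pwm)
        best, _ = scorer.best_hit(seq)
        assert best == int(scorer.int_scores.max(axis=1).sum())

    def test_reverse_complement_hit_equivalent(self):
        pwm = self.pwm(seed=1)
        fwd_seq = self.embed(pwm.consensus(), seed=2)
        rc_seq = reverse_complement(fwd_seq)
        scorer = MotifScorer(pwm)
        assert scorer.best_hit(fwd_seq)[0] == scorer.best_hit(rc_seq)[0]

    @pytest.mark.parametrize("seed", range(3))
    def test_exact_dp_equals_enumeration(self, seed):
        """DP survival function equals exhaustive enumeration over all 4^5
        background words of a width-5 matrix."""
        scorer = MotifScorer(self.pwm(seed=seed))
        word_scores = np.array(
            [
                sum(int(scorer.int_scores[j, b]) for j, b in enumerate(word))
                for word in itertools.product(range(4), repeat=5)
            ]
        )
        thresholds = np.unique(
            np.concatenate([word_scores, word_scores + 1, [word_scores.min() - 1]])
        )
        for t in thresholds:
            assert scorer.pvalue(int(t)) == pytest.approx(
                (word_scores >= t).mean(), abs=1e-15
            )

    def test_set_collapse_is_row_or(self):
        import pandas as pd

        rng = np.random.default_rng(6)
        table = pd.DataFrame(
            rng.random((20, 6)) < 0.3, columns=[f"m{j}" for j in range(6)]
        )
        set_ids = {f"m{j}": f"set{j % 2}" for j in range(6)}
        collapsed = collapse_motif_sets(table, set_ids)
        for sid in ("set0", "set1"):
            members = [m for m, s in set_ids.items() if s == sid]
            np.testing.assert_array_equal(
                collapsed[sid].to_numpy(), table[members].any(axis=1).to_numpy()
            )

    def test_meme_round_trip(self, tmp_path):
        pwm = self.pwm(seed=7)
        path = tmp_path / "m.meme"
        with open(path, "w") as fh:
            fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
            fh.write(f"MOTIF {pwm.name} {pwm.set_id}\n")
            fh.write("letter-probability matrix: alength= 4 w= 5\n")
            for row in pwm.probs:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
        (loaded,) = parse_meme(path)
        assert loaded.set_id == pwm.set_id
        np.testing.assert_allclose(loaded.probs, pwm.probs, atol=1e-6)


def test_annotate_regions_dataframe():
    peaks = [("chr1", 1000), ("chr1", 8000)]
    fsets = {
        "polII_peak": features([1100], kind="polII_peak"),
        "cage_peak": features([1200, 8100], kind="cage_peak"),
        "tss": features([900, 8400], kind="tss"),
    }
    df = annotate_regions(peaks, fsets)
    assert df.loc["chr1:1000", "consensus_promoter"]
    assert not df.loc["chr1:8000", "consensus_promoter"]
    assert df.loc["chr1:1000", "tss_distance"] == -100
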