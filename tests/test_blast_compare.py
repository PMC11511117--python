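"""BLAST tabular parsing, best-hit labeling, cross-classification."""

import numpy as np
import pytest

import toxcascade as tc
from toxcascade.blast_compare import write_blast_tab


def _random_hits(n, rng, n_queries=8, n_subjects=6):
    hits = []
    for i in range(n):
        hits.append(
            tc.BlastHit(
                query_id=f"q{rng.integers(n_queries)}",
                subject_id=f"s{rng.integers(n_subjects)}",
                pct_identity=float(np.round(rng.uniform(50, 100), 2)),
                aln_length=int(rng.integers(20, 200)),
                mismatches=int(rng.integers(0, 30)),
                gap_opens=int(rng.integers(0, 5)),
                q_start=1,
                q_end=50,
                s_start=1,
                s_end=50,
                evalue=float(10.0 ** -rng.integers(5, 60)),
                bitscore=float(np.round(rng.uniform(40, 300), 1)),
            )
        )
    return hits


class TestParseBlastTab:
    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        assert tc.parse_blast_tab(p) == []

    def test_scientific_evalue_notation(self, tmp_path):
        p = tmp_path / "one.tsv"
        p.write_text("q1\ts1\t98.5\t60\t1\t0\t1\t60\t1\t60\t1e-60\t220.1\n")
        (hit,) = tc.parse_blast_tab(p)
        assert hit.evalue == pytest.approx(1e-60)
        assert hit.pct_identity == pytest.approx(98.5)
        assert hit.bitscore == pytest.approx(220.1)

    def test_wrong_column_count_names_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(
            "q1\ts1\t98.5\t60\t1\t0\t1\t60\t1\t60\t1e-60\t220.1\n"
            "q2\ts2\t90.0\n"
        )
        with pytest.raises(ValueError, match="line 2"):
            tc.parse_blast_tab(p)

    def test_round_trip_of_20_synthetic_hits(self, tmp_path):
        hits = _random_hits(20, np.random.default_rng(0))
        p = tmp_path / "rt.tsv"
        write_blast_tab(hits, p)
        assert tc.parse_blast_tab(p) == hits

    def test_invalid_field_values_rejected(self):
        with pytest.raises(ValueError):
            tc.BlastHit("q", "s", 120.0, 1, 0, 0, 1, 1, 1, 1, 1e-5, 50.0)
        with pytest.raises(ValueError):
            tc.BlastHit("q", "s", 90.0, 1, 0, 0, 1, 1, 1, 1, -1e-5, 50.0)


class TestBestHitLabels:
    def _mapping(self, n=6):
        classes = ["ICK", "KTx", "NaTx", "venom"]
        return {f"s{i}": classes[i % 4] for i in range(n)}

    def test_single_hit_below_threshold(self):
        hits = [tc.BlastHit("q1", "s2", 90, 50, 1, 0, 1, 50, 1, 50, 1e-20, 100.0)]
        labels = tc.best_hit_labels(hits, self._mapping())
        assert labels == {"q1": "NaTx"}

    def test_lowest_evalue_wins(self):
        hits = [
            tc.BlastHit("q1", "s0", 90, 50, 1, 0, 1, 50, 1, 50, 1e-5, 100.0),
            tc.BlastHit("q1", "s1", 90, 50, 1, 0, 1, 50, 1, 50, 1e-20, 80.0),
        ]
        labels = tc.best_hit_labels(hits, self._mapping(), max_evalue=1e-3)
        assert labels == {"q1": "KTx"}

    def test_evalue_tie_broken_by_bitscore_then_first(self):
        hits = [
            tc.BlastHit("q1", "s0", 90, 50, 1, 0, 1, 50, 1, 50, 1e-20, 80.0),
            tc.BlastHit("q1", "s1", 90, 50, 1, 0, 1, 50, 1, 50, 1e-20, 120.0),
            tc.BlastHit("q1", "s2", 90, 50, 1, 0, 1, 50, 1, 50, 1e-20, 120.0),
        ]
        labels = tc.best_hit_labels(hits, self._mapping())
        assert labels == {"q1": "KTx"}  # s1: higher bitscore, earlier than s2

    def test_queries_above_threshold_are_absent(self):
        hits = [tc.BlastHit("q1", "s0", 90, 50, 1, 0, 1, 50, 1, 50, 1e-4, 60.0)]
        assert tc.best_hit_labels(hits, self._mapping(), max_evalue=1e-10) == {}

    def test_missing_subject_raises_listing_it(self):
        hits = [tc.BlastHit("q1", "sX", 90, 50, 1, 0, 1, 50, 1, 50, 1e-20, 60.0)]
        with pytest.raises(KeyError, match="sX"):
            tc.best_hit_labels(hits, self._mapping())

    def test_agrees_with_brute_force_and_ignores_line_order(self):
        rng = np.random.default_rng(5)
        mapping = self._mapping()
        for _ in range(10):
            hits = _random_hits(40, rng)
            got = tc.best_hit_labels(hits, mapping, max_evalue=1e-8)
            # brute force per query
            queries = {h.query_id for h in hits if h.evalue <= 1e-8}
            for q in queries:
                qhits = [h for h in hits if h.query_id == q and h.evalue <= 1e-8]
                best = min(
                    range(len(qhits)),
                    key=lambda i: (qhits[i].evalue, -qhits[i].bitscore, i),
                )
                assert got[q] == mapping[qhits[best].subject_id]
            # shuffling whole-query blocks cannot change the outcome when
            # the (evalue, bitscore) best hit is unique per query
            unique = {
                q: got[q]
                for q in got
                if len({(h.evalue, h.bitscore) for h in hits
                        if h.query_id == q and h.evalue <= 1e-8}) ==
                len([h for h in hits if h.query_id == q and h.evalue <= 1e-8])
            }
            shuffled = list(hits)
            rng.shuffle(shuffled)
            got2 = tc.best_hit_labels(shuffled, mapping, max_evalue=1e-8)
            for q, lab in unique.items():
                assert got2[q] == lab


class TestCrossClassification:
    def test_identical_labelings_are_diagonal(self):
        labels = {"q1": "ICK", "q2": "KTx", "q3": "NaTx"}
        cm, extras = tc.cross_classification(labels, dict(labels))
        assert np.array_equal(cm.counts, np.diag(cm.counts.diagonal()))
        assert cm.total == 3
        assert extras == {"blast_only": 0, "pipeline_only": 0}

    def test_single_reannotation_lands_off_diagonal(self):
        # a transcript called NaTx by similarity but KTx by the cascade
        cm, _ = tc.cross_classification(
            {"q1": "NaTx"}, {"q1": "KTx"}, labels=["ICK", "KTx", "NaTx", "venom"]
        )
        i, j = cm.labels.index("NaTx"), cm.labels.index("KTx")
        assert cm.counts[i, j] == 1
        assert cm.total == 1

    def test_totals_conserved_and_extras_counted(self):
        rng = np.random.default_rng(11)
        classes = ["ICK", "KTx", "NaTx", "venom"]
        blast = {f"q{i}": classes[rng.integers(4)] for i in range(30)}
        pipe = {f"q{i}": classes[rng.integers(4)] for i in range(10, 45)}
        cm, extras = tc.cross_classification(blast, pipe)
        assert cm.total == 20
        assert extras["blast_only"] == 10
        assert extras["pipeline_only"] == 15
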