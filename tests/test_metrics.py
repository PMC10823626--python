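"""Comparison metrics: cross-sample merge, overlap stats, fold/percent
arithmetic, low-expression panel."""

import pandas as pd
import pytest

from masiso.classify import ClassifiedIsoform
from masiso.collapse import mergeable
from masiso.metrics import (ComparisonMatrix, MatrixRow, fold_change,
                            low_expression_panel, mean_recall, merge_samples,
                            overlap_stats, panel_detection)


def _iso(cid, exons, support, category="FSM", matched=None, strand="+",
         contig="c1"):
    exons = tuple(tuple(e) for e in exons)
    length = sum(e - s for s, e in exons)
    return ClassifiedIsoform(cid, category, matched, ("g",), length, support,
                             contig, strand, exons)


BASE = [(1000, 1300), (1600, 2000)]


def test_merge_same_isoform_across_samples():
    samples = [[_iso("a", BASE, 5)], [], [_iso("b", BASE, 7)]]
    m = merge_samples(samples)
    assert len(m.rows) == 1
    assert m.rows[0].supports == (5, 0, 7)


def test_merge_disjoint_isoforms():
    samples = [[_iso("a", BASE, 3)], [_iso("b", [(9000, 9500)], 4)]]
    m = merge_samples(samples)
    assert len(m.rows) == 2
    assert sorted(m.rows, key=lambda r: r.exons[0][0])[0].supports == (3, 0)


def test_merge_drops_unknown_rows():
    samples = [[_iso("a", BASE, 3),
                _iso("u", [(90000, 90400)], 2, category="intergenic")]]
    assert len(merge_samples(samples, drop_unknown=True).rows) == 1
    assert len(merge_samples(samples, drop_unknown=False).rows) == 2


def test_merge_matches_bruteforce_pairwise_oracle(rng):
    samples = []
    for s in range(3):
        sample = []
        for i in range(40):
            start = int(rng.integers(0, 20)) * 700
            exons = [(start, start + 250), (start + 400, start + 650)]
            sample.append(_iso(f"s{s}_i{i}", exons, int(rng.integers(1, 9))))
        samples.append(sample)
    m = merge_samples(samples, drop_unknown=False)
    # oracle: count connected components over all isoforms by mergeability
    import networkx as nx
    pool = [iso for s in samples for iso in s]
    g = nx.Graph()
    g.add_nodes_from(range(len(pool)))
    for i in range(len(pool)):
        for j in range(i + 1, len(pool)):
            if mergeable(pool[i], pool[j]):
                g.add_edge(i, j)
    assert len(m.rows) == nx.number_connected_components(g)
    total = sum(sum(r.supports) for r in m.rows)
    assert total == sum(iso.support for iso in pool)


def test_merge_idempotent():
    samples = [[_iso("a", BASE, 5)], [_iso("b", [(5000, 5600)], 2)]]
    m1 = merge_samples(samples, drop_unknown=False)
    again = [[_iso(f"r{i}", r.exons, sum(r.supports))
              for i, r in enumerate(m1.rows)]]
    m2 = merge_samples(again, drop_unknown=False)
    assert sorted(r.exons for r in m2.rows) == sorted(r.exons for r in m1.rows)


def _matrix(cells, category="FSM"):
    rows = [MatrixRow("c1", "+", ((i * 1000, i * 1000 + 500),), category,
                      f"T{i}", tuple(c), tuple(() for _ in c))
            for i, c in enumerate(cells)]
    return ComparisonMatrix(tuple(f"S{j+1}" for j in range(len(cells[0]))), rows)


@pytest.mark.parametrize("n_all,n_unique,pct", [
    (17611, 103591, 17.0),
    (10003, 41831, 23.9),
    (5157, 19598, 26.3),
])
def test_overlap_percent_in_all_three(n_all, n_unique, pct):
    cells = [(1, 1, 1)] * n_all + [(1, 0, 0)] * (n_unique - n_all)
    stats = overlap_stats(_matrix(cells), 1)
    assert (stats.n_unique, stats.n_in_all) == (n_unique, n_all)
    assert stats.pct_in_all == pct


def test_overlap_percent_at_least_two():
    cells = [(1, 1, 1)] * 5157 + [(1, 1, 0)] * (9136 - 5157) \
        + [(1, 0, 0)] * (19598 - 9136)
    stats = overlap_stats(_matrix(cells), 1)
    assert stats.n_in_at_least_2 == 9136
    assert stats.pct_in_at_least_2 == 46.6
    assert stats.pct_in_all <= stats.pct_in_at_least_2 <= 100.0


def test_overlap_single_row_everywhere():
    stats = overlap_stats(_matrix([(3, 4, 5)]), 1)
    assert (stats.n_unique, stats.pct_in_all) == (1, 100.0)


def test_overlap_threshold_monotonicity(rng):
    cells = [tuple(int(rng.integers(0, 30)) for _ in range(3))
             for _ in range(300)]
    cells = [c for c in cells if any(c)]
    m = _matrix(cells)
    uniques = [overlap_stats(m, t).n_unique for t in (2, 4, 10)]
    assert uniques == sorted(uniques, reverse=True)


@pytest.mark.parametrize("num,den,expected", [
    (8432861, 2501016, 3.4),
    (11676, 0, 11676),
    (5, 5, 1.0),
    (0, 0, 1.0),
    (192220, 103591, 1.9),
    (42195, 19598, 2.2),
    (34020, 15362, 2.2),
])
def test_fold_change(num, den, expected):
    assert fold_change(num, den) == expected


@pytest.mark.parametrize("counts,total,expected", [
    ([64, 61, 61], 69, 89.9),
    ([62, 54, 50], 69, 80.2),
    ([69, 69, 69], 69, 100.0),
])
def test_mean_recall(counts, total, expected):
    assert mean_recall(counts, total) == expected


def test_mean_recall_rejects_bad_input():
    with pytest.raises(ValueError):
        mean_recall([], 69)
    with pytest.raises(ValueError):
        mean_recall([70], 69)


def test_low_expression_panel_intersection():
    t1 = pd.DataFrame({"transcript_id": ["A", "B", "C"], "tpm": [0.5, 0.5, 0.5]})
    t2 = pd.DataFrame({"transcript_id": ["A", "B", "C"], "tpm": [0.5, 0.5, 0.6]})
    t3 = pd.DataFrame({"transcript_id": ["A", "B"], "tpm": [0.5, 0.5]})
    assert low_expression_panel([t1, t2, t3]) == {"A", "B"}


def test_low_expression_panel_random_oracle(rng):
    tables = []
    ids = [f"T{i}" for i in range(200)]
    for _ in range(3):
        tpm = rng.choice([0.5, 0.3, 1.0, 2.0], size=len(ids))
        tables.append(pd.DataFrame({"transcript_id": ids, "tpm": tpm}))
    panel = low_expression_panel(tables)
    expected = {tid for i, tid in enumerate(ids)
                if all(abs(t["tpm"].iloc[i] - 0.5) <= 1e-9 for t in tables)}
    assert panel == expected


def test_panel_detection_percentages():
    panel = {f"P{i}" for i in range(534)}
    cells, matched = [], []
    for i in range(534):
        if i < 96:
            cells.append((1, 1, 1))
        elif i < 240:
            cells.append((1, 0, 0))
        else:
            continue
        matched.append(f"P{i}")
    rows = [MatrixRow("c1", "+", ((i * 1000, i * 1000 + 500),), "FSM",
                      matched[i], cells[i], ((), (), ()))
            for i in range(len(cells))]
    m = ComparisonMatrix(("S1", "S2", "S3"), rows)
    det = panel_detection(panel, m)
    assert (det.n_in_all, det.n_in_at_least_one) == (96, 240)
    assert (det.pct_in_all, det.pct_in_at_least_one) == (18.0, 44.9)


def test_panel_detection_empty_detection():
    panel = {"X"}
    m = ComparisonMatrix(("S1",), [])
    det = panel_detection(panel, m)
    assert det.pct_in_all == 0.0
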