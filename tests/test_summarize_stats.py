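import itertools
import math

import numpy as np
import pytest
import yaml
from scipy.stats import hypergeom

from ejscar.junction_classifier import JunctionCall
from ejscar.stats_util import pct_half_up, round_half_up
from ejscar.summarize_stats import (
    EXACT_MAX_TOTAL,
    PipelineError,
    class_table,
    compare_proportions,
    compare_sizes,
    from_counts,
    insertion_size_summary,
    run_pipeline,
    tabulate,
)


def _call(event, k=4, dl=0, dr=0, ins=""):
    return JunctionCall(
        read_id="x", event_class=event, k_retained=k, del_left=dl, del_right=dr,
        ins_seq=ins, mh_len=0,
    )


# ---------------------------------------------------------------- rounding


def test_half_up_rounding():
    # 22.5% must print as 23%, not 22% (banker's rounding would be wrong)
    assert round_half_up(22.5) == 23
    assert round_half_up(14.72, 1) == 14.7
    assert pct_half_up(18, 80) == 23
    assert math.isnan(pct_half_up(0, 0))


# ---------------------------------------------------------------- tabulate


def test_tabulate_published_fractions():
    t = from_counts(
        "distant", {"HiFi": 69, "Insertion": 7, "Deletion": 87, "DeletionWithInsertion": 27}
    )
    assert t.n_total == 190
    assert t.pct("HiFi") == 36
    assert t.pct_conservative == 40
    t2 = from_counts(
        "close", {"HiFi": 77, "Insertion": 9, "Deletion": 35, "DeletionWithInsertion": 14}
    )
    assert t2.pct("HiFi") == 57
    assert t2.pct_conservative == 64


def test_tabulate_from_calls_excludes_unalignable():
    calls = [_call("HiFi")] * 10 + [
        JunctionCall(read_id="u", event_class="Unalignable", k_retained=0,
                     del_left=0, del_right=0, ins_seq="", mh_len=0)
    ]
    t = tabulate(calls, "c")
    assert t.n_total == 10
    assert t.pct("HiFi") == 100


def test_tabulate_empty_is_undefined():
    t = tabulate([], "empty")
    assert t.n_total == 0
    assert math.isnan(t.pct("HiFi"))


def test_percentages_recompute_from_emitted_counts():
    t = from_counts(
        "a", {"HiFi": 48, "Insertion": 5, "Deletion": 73, "DeletionWithInsertion": 37}
    )
    frame = class_table([t])
    row = frame.iloc[0]
    for cls in ("HiFi", "Insertion", "Deletion", "DeletionWithInsertion"):
        assert row[f"pct_{cls}"] == pct_half_up(row[f"n_{cls}"], row["n_total"])


# ---------------------------------------------------------------- Mann-Whitney


def test_compare_sizes_exact_example():
    # all 20 rank assignments enumerated; the two extreme ones give p = 0.1
    u, p = compare_sizes([1, 2, 3], [101, 102, 103])
    assert u == 0.0
    assert p == pytest.approx(0.1)


def test_compare_sizes_symmetries():
    a, b = [3, 9, 27, 12], [5, 8, 40]
    _, p_ab = compare_sizes(a, b)
    _, p_ba = compare_sizes(b, a)
    assert p_ab == pytest.approx(p_ba)
    _, p_same = compare_sizes(a, a)
    assert p_same == pytest.approx(1.0)


def test_compare_sizes_all_tied_warns():
    u, p = compare_sizes([5, 5], [5, 5, 5])
    assert p == 1.0


def test_compare_sizes_requires_data():
    with pytest.raises(ValueError):
        compare_sizes([], [1])


def _mw_oracle(a, b):
    """Full enumeration with rank-sum U (independent route: midranks)."""
    from scipy.stats import rankdata

    pooled = list(a) + list(b)
    n_a = len(a)

    def u_of(indices):
        ranks = rankdata(pooled)
        r1 = sum(ranks[i] for i in indices)
        return r1 - n_a * (n_a + 1) / 2

    center = n_a * len(b) / 2
    obs = u_of(range(n_a))
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n_a):
        total += 1
        if abs(u_of(combo) - center) >= abs(obs - center) - 1e-12:
            hits += 1
    return hits / total


def test_exact_branch_equals_enumeration_oracle():
    rng = np.random.default_rng(2024)
    for _ in range(40):
        n_a = int(rng.integers(1, 6))
        n_b = int(rng.integers(1, 10 - n_a + 1)) if n_a < 9 else 1
        a = list(rng.integers(0, 6, n_a))  # small support forces ties
        b = list(rng.integers(0, 6, n_b))
        if len(set(a) | set(b)) == 1:
            continue
        _, p = compare_sizes(a, b)
        assert p == pytest.approx(_mw_oracle(a, b)), (a, b)


def test_large_samples_use_asymptotic():
    rng = np.random.default_rng(3)
    a = list(rng.integers(0, 50, EXACT_MAX_TOTAL))
    b = list(rng.integers(20, 70, EXACT_MAX_TOTAL))
    from scipy.stats import mannwhitneyu

    u, p = compare_sizes(a, b)
    ref = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    assert p == pytest.approx(float(ref.pvalue))


# ---------------------------------------------------------------- proportions


def _fisher_oracle(x1, n1, x2, n2):
    """Two-sided Fisher p by hypergeometric enumeration over the 2x2 support."""
    m = x1 + x2
    lo, hi = max(0, m - n2), min(n1, m)
    p_obs = hypergeom.pmf(x1, n1 + n2, m, n1)
    total = 0.0
    for k in range(lo, hi + 1):
        pk = hypergeom.pmf(k, n1 + n2, m, n1)
        if pk <= p_obs * (1 + 1e-9):
            total += pk
    return min(1.0, total)


def test_compare_proportions_examples():
    assert compare_proportions(5, 10, 5, 10)["p_value"] == pytest.approx(1.0)
    res = compare_proportions(10, 10, 0, 10)
    assert res["p_value"] == pytest.approx(_fisher_oracle(10, 10, 0, 10))
    assert res["difference"] == pytest.approx(1.0)


def test_compare_proportions_matches_enumeration():
    rng = np.random.default_rng(99)
    for _ in range(60):
        n1 = int(rng.integers(1, 31))
        n2 = int(rng.integers(1, 31))
        x1 = int(rng.integers(0, n1 + 1))
        x2 = int(rng.integers(0, n2 + 1))
        p = compare_proportions(x1, n1, x2, n2)["p_value"]
        assert p == pytest.approx(_fisher_oracle(x1, n1, x2, n2), abs=1e-9), (x1, n1, x2, n2)


def test_compare_proportions_symmetry_and_errors():
    p1 = compare_proportions(3, 12, 7, 15)["p_value"]
    p2 = compare_proportions(7, 15, 3, 12)["p_value"]
    assert p1 == pytest.approx(p2)
    with pytest.raises(ValueError):
        compare_proportions(1, 0, 1, 2)
    with pytest.raises(ValueError):
        compare_proportions(5, 4, 1, 2)


# ---------------------------------------------------------------- insertions


def test_insertion_summary_threshold_boundary():
    calls = [_call("Insertion", ins="A" * 45) for _ in range(3)]
    calls += [_call("HiFi")] * 7
    s = insertion_size_summary(calls, threshold=45)
    assert s["n_long"] == 3  # >= 45 is inclusive by default
    s_strict = insertion_size_summary(calls, threshold=45, inclusive=False)
    assert s_strict["n_long"] == 0


def test_insertion_summary_no_insertions():
    s = insertion_size_summary([_call("HiFi")] * 5)
    assert s["n_insertions"] == 0
    assert s["pct_long"] == 0.0
    assert math.isnan(s["median_size"])


def test_insertion_summary_coupling():
    calls = [
        _call("DeletionWithInsertion", k=0, dl=80, dr=30, ins="C" * 50),
        _call("DeletionWithInsertion", k=0, dl=10, dr=0, ins="C" * 50),
        _call("Insertion", ins="C" * 50),
    ]
    s = insertion_size_summary(calls)
    assert s["n_long"] == 3
    assert s["n_long_coupled"] == 2  # the conservative k=4 insertion is uncoupled
    assert s["n_long_coupled_del_gt100"] == 1  # 80+30+4 = 114 > 100


# ---------------------------------------------------------------- pipeline


@pytest.fixture()
def pipeline_inputs(tmp_path, distant_cfg, distant_sims):
    from ejscar.synthetic_data import reporter_sequence, write_reads_fasta

    sims = distant_sims[:80]
    write_reads_fasta(sims, tmp_path / "reads.fasta")
    sub = distant_cfg.substrate
    (tmp_path / "substrate.yaml").write_text(
        yaml.safe_dump(
            {
                "name": sub.name,
                "left_arm": sub.left_arm,
                "right_arm": sub.right_arm,
                "overhang": sub.overhang,
                "spacer_len": sub.spacer_len,
            }
        )
    )
    reporter, cuts = reporter_sequence(sub, distant_cfg.spacer_seq)
    (tmp_path / "reporter.fasta").write_text(f">reporter\n{reporter}\n")
    (tmp_path / "genome.fasta").write_text(f">chr1\n{distant_cfg.donor_genome}\n")
    (tmp_path / "refs.yaml").write_text(
        yaml.safe_dump(
            {
                "sources": [
                    {"label": "reporter", "path": "reporter.fasta", "cut_sites": list(cuts)},
                    {"label": "genome", "path": "genome.fasta"},
                ]
            }
        )
    )
    return tmp_path


def test_pipeline_end_to_end(pipeline_inputs, distant_sims):
    out = pipeline_inputs / "out"
    result = run_pipeline(
        pipeline_inputs / "reads.fasta",
        pipeline_inputs / "substrate.yaml",
        pipeline_inputs / "refs.yaml",
        out,
        condition="distant",
    )
    # tables consistent with simulator truth
    truth_classes = [s.truth.c_event_class for s in distant_sims[:80]]
    for cls in ("HiFi", "Insertion", "Deletion", "DeletionWithInsertion"):
        assert result["table"].counts[cls] == truth_classes.count(cls)
    for name in ("calls.tsv", "class_table.tsv", "origins.tsv", "origin_table.tsv",
                 "insertion_summary.tsv", "run_log.json"):
        assert (out / name).exists()
    # deterministic re-run is byte-identical
    before = {p.name: p.read_bytes() for p in out.iterdir()}
    run_pipeline(
        pipeline_inputs / "reads.fasta",
        pipeline_inputs / "substrate.yaml",
        pipeline_inputs / "refs.yaml",
        out,
        condition="distant",
    )
    after = {p.name: p.read_bytes() for p in out.iterdir()}
    assert before == after


def test_pipeline_empty_fasta(pipeline_inputs):
    empty = pipeline_inputs / "empty.fasta"
    empty.write_text("")
    out = pipeline_inputs / "out_empty"
    result = run_pipeline(
        empty, pipeline_inputs / "substrate.yaml", None, out, condition="none"
    )
    assert result["table"].n_total == 0
    assert (out / "class_table.tsv").exists()


def test_pipeline_failure_removes_outputs(pipeline_inputs):
    bad = pipeline_inputs / "bad_substrate.yaml"
    bad.write_text(yaml.safe_dump({"name": "x", "overhang": "AT"}))
    out = pipeline_inputs / "out_bad"
    with pytest.raises(PipelineError, match="load_inputs"):
        run_pipeline(pipeline_inputs / "reads.fasta", bad, None, out)
    assert not any(out.iterdir())
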