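import math

import numpy as np
import pytest

from ejscar.insertion_origin import (
    CATEGORIES,
    InsertionOrigin,
    InsertionTooShortError,
    ReferenceCollection,
    ReferenceConfigError,
    ReferenceSource,
    categorize_insertion,
    origin_table,
    search_insertion,
)
from ejscar.junction_classifier import JunctionCall, call_junction
from ejscar.synthetic_data import reporter_sequence


def _revcomp(s):
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def test_reference_collection_validation():
    with pytest.raises(ReferenceConfigError):
        ReferenceCollection([])
    src = ReferenceSource("a", "ACGT" * 10)
    with pytest.raises(ReferenceConfigError):
        ReferenceCollection([src, ReferenceSource("a", "ACGT" * 5)])
    with pytest.raises(ReferenceConfigError):
        ReferenceSource("bad", "ACGU" * 10)


def test_search_verbatim_copy(distant_cfg, distant_refs):
    donor = distant_cfg.donor_genome
    ins = donor[5000:5050]
    hit = search_insertion(ins, distant_refs)
    assert hit is not None
    assert hit.source_label == "genome"
    assert hit.identity == 1.0
    assert (hit.ref_start, hit.ref_end) == (5000, 5050)
    assert (hit.q_start, hit.q_end) == (0, 50)
    assert hit.strand == "+"


def test_search_reverse_complement(distant_cfg, distant_refs):
    donor = distant_cfg.donor_genome
    ins = _revcomp(donor[8000:8060])
    hit = search_insertion(ins, distant_refs)
    assert hit is not None and hit.strand == "-"
    assert (hit.ref_start, hit.ref_end) == (8000, 8060)


def test_search_random_absent(distant_refs):
    rng = np.random.default_rng(123)
    # verify absence by exhaustive 20-mer scan, then expect no hit
    while True:
        q = "".join("ACGT"[i] for i in rng.integers(0, 4, 50))
        pool = [s.sequence for s in distant_refs] + [
            _revcomp(s.sequence) for s in distant_refs
        ]
        if not any(q[i : i + 20] in seq for seq in pool for i in range(31)):
            break
    assert search_insertion(q, distant_refs) is None


def test_search_threshold_and_empty():
    with pytest.raises(InsertionTooShortError):
        search_insertion("ACGT" * 11, ReferenceCollection([ReferenceSource("x", "A" * 100)]))


def test_tie_broken_by_source_order(distant_cfg):
    # the same 50-mer present in two sources resolves to the earlier one
    donor = distant_cfg.donor_genome
    seg = donor[100:150]
    refs = ReferenceCollection(
        [
            ReferenceSource("reporter", "T" * 200 + seg + "G" * 200),
            ReferenceSource("genome", donor),
        ]
    )
    hit = search_insertion(seg, refs)
    assert hit.source_label == "reporter"


def _call_with_ins(ins, dl=0, dr=0, k=4, del_right=None):
    return JunctionCall(
        read_id="t",
        event_class="DeletionWithInsertion" if dl or dr else "Insertion",
        k_retained=k if not (dl or dr) else 0,
        del_left=dl,
        del_right=dr,
        ins_seq=ins,
        mh_len=0,
        k_left=k if not (dl or dr) else 0,
        k_right=0,
    )


def test_categorize_partial_duplication_adjacency(distant_cfg, distant_refs):
    sub = distant_cfg.substrate
    reporter, cuts = reporter_sequence(sub, distant_cfg.spacer_seq)
    # 60 nt copied from 300 bp upstream of the left cut
    start = cuts[0] - 300
    ins = reporter[start : start + 60]
    origin = categorize_insertion(_call_with_ins(ins), distant_refs, sub)
    assert origin.category == "partial_duplication"
    assert origin.adjacent_side == "5'"
    assert origin.border5_unidentified_len == 0
    assert origin.border3_unidentified_len == 0


def test_categorize_ecs_with_n_additions(distant_cfg, distant_refs):
    rng = np.random.default_rng(7)
    donor = distant_cfg.donor_genome
    n5 = "".join("ACGT"[i] for i in rng.integers(0, 4, 8))
    n3 = "".join("ACGT"[i] for i in rng.integers(0, 4, 5))
    ins = n5 + donor[3000:3050] + n3
    origin = categorize_insertion(_call_with_ins(ins), distant_refs, distant_cfg.substrate)
    assert origin.category == "ECS"
    assert origin.border5_unidentified_len == 8
    assert origin.border3_unidentified_len == 5
    # N-added borders are not assessable for microhomology
    assert origin.border_mh5 is None and origin.border_mh3 is None


def test_categorize_unidentified(distant_cfg, distant_refs):
    rng = np.random.default_rng(21)
    while True:
        q = "".join("ACGT"[i] for i in rng.integers(0, 4, 50))
        if search_insertion(q, distant_refs) is None:
            break
    origin = categorize_insertion(_call_with_ins(q), distant_refs, distant_cfg.substrate)
    assert origin.category == "unidentified"
    assert origin.has_unidentified_border
    assert origin.border_mh5 is None and origin.border_mh3 is None


def test_categorize_rejects_short(distant_cfg, distant_refs):
    with pytest.raises(InsertionTooShortError):
        categorize_insertion(_call_with_ins("ACGT" * 10), distant_refs, distant_cfg.substrate)


def test_border_mh_recovered_from_simulation(distant_refs):
    """ECS captures planted with border microhomologies and no N-additions are
    recovered with exactly those border MH values."""
    from ejscar.synthetic_data import preset_config, simulate_junctions

    cfg = preset_config(
        "distant",
        seed=17,
        n_reads=40,
        class_probs={"HiFi": 0.0, "Insertion": 0.5, "Deletion": 0.0, "DeletionWithInsertion": 0.5},
        ins_origin_probs={"partial_duplication": 0.0, "ECS": 1.0, "untemplated": 0.0},
        ins_long_weight=1.0,
        n_add_prob=0.0,
    )
    sub = cfg.substrate
    checked = 0
    for s in simulate_junctions(cfg):
        t = s.truth
        if t.boundary_ambiguous or len(t.ins_seq) < 45:
            continue
        call = call_junction(s.read, sub)
        origin = categorize_insertion(call, distant_refs, sub)
        assert origin.category == "ECS"
        assert origin.border_mh5 == t.border_mh5
        assert origin.border_mh3 == t.border_mh3
        checked += 1
    assert checked >= 20


def test_origin_partition(distant_cfg, distant_sims, distant_refs):
    sub = distant_cfg.substrate
    origins = []
    for s in distant_sims:
        call = call_junction(s.read, sub)
        if call.ins_len >= 45:
            origins.append(categorize_insertion(call, distant_refs, sub))
    assert len(origins) >= 10
    assert sum(sum(o.category == c for o in origins) for c in CATEGORIES) == len(origins)


def test_origin_table_empty_condition():
    table = origin_table({"empty": ([], 0)})
    row = table.iloc[0]
    assert row["n_ins_gt45"] == 0
    assert math.isnan(row["pct_ins_gt45"])
    assert math.isnan(row["pct_unidentified_border"])


def test_manifest_loading(tmp_path, distant_cfg):
    import yaml

    reporter, cuts = reporter_sequence(distant_cfg.substrate, distant_cfg.spacer_seq)
    (tmp_path / "reporter.fasta").write_text(f">reporter\n{reporter}\n")
    (tmp_path / "genome.fasta").write_text(f">chr1\n{distant_cfg.donor_genome}\n")
    manifest = {
        "sources": [
            {"label": "reporter", "path": "reporter.fasta", "cut_sites": list(cuts)},
            {"label": "genome", "path": "genome.fasta"},
        ]
    }
    path = tmp_path / "refs.yaml"
    path.write_text(yaml.safe_dump(manifest))
    refs = ReferenceCollection.from_manifest(path)
    assert [s.label for s in refs] == ["reporter", "genome"]
    assert refs["reporter"].cut_sites == cuts
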