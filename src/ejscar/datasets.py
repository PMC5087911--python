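"""Bundled example count tables from a published two-cut reporter study.

Per-condition junction counts from Sanger-sequenced repair junctions of
I-SceI-induced double-strand ends separated by 3200 bp (cell lines GC92 and
GC49, "distant") or 34 bp (GCK20, "close"), under control, 53BP1, CtIP and
combined silencing.  These counts serve as fixture inputs for the summary
tables; the percentages the package derives from them are the published
table values.
"""

from __future__ import annotations

from .insertion_origin import InsertionOrigin

__all__ = [
    "CLASS_COUNTS",
    "ORIGIN_COUNTS",
    "origin_fixture",
]

#: condition -> event-class counts (denominator = sequenced junctions)
CLASS_COUNTS: dict[str, dict[str, int]] = {
    # distant ends, GC92
    "GC92_siControl": {"HiFi": 69, "Insertion": 7, "Deletion": 87, "DeletionWithInsertion": 27},
    "GC92_si53BP1": {"HiFi": 48, "Insertion": 5, "Deletion": 73, "DeletionWithInsertion": 37},
    "GC92_siCtIP": {"HiFi": 94, "Insertion": 4, "Deletion": 52, "DeletionWithInsertion": 15},
    "GC92_si53BP1_siCtIP": {"HiFi": 40, "Insertion": 0, "Deletion": 42, "DeletionWithInsertion": 13},
    # distant ends, GC49
    "GC49_siControl": {"HiFi": 18, "Insertion": 8, "Deletion": 38, "DeletionWithInsertion": 16},
    "GC49_si53BP1": {"HiFi": 20, "Insertion": 3, "Deletion": 71, "DeletionWithInsertion": 29},
    # close ends, GCK20
    "GCK20_siControl": {"HiFi": 77, "Insertion": 9, "Deletion": 35, "DeletionWithInsertion": 14},
    "GCK20_si53BP1": {"HiFi": 63, "Insertion": 5, "Deletion": 37, "DeletionWithInsertion": 15},
    "GCK20_siCtIP": {"HiFi": 59, "Insertion": 4, "Deletion": 15, "DeletionWithInsertion": 8},
    "GCK20_si53BP1_siCtIP": {"HiFi": 45, "Insertion": 1, "Deletion": 23, "DeletionWithInsertion": 9},
}

#: condition -> origin counts for insertions > 45 bp at distant ends
#: (n_total = sequenced junctions; unidentified_border denominator = n_gt45)
ORIGIN_COUNTS: dict[str, dict[str, int]] = {
    "GC92_siControl": {
        "n_total": 190, "n_gt45": 12, "coupled_del_gt100": 10,
        "partial_duplication": 4, "ECS": 8, "other": 0, "unidentified_border": 10,
    },
    "GC92_si53BP1": {
        "n_total": 163, "n_gt45": 24, "coupled_del_gt100": 16,
        "partial_duplication": 10, "ECS": 12, "other": 2, "unidentified_border": 20,
    },
    "GC92_siCtIP": {
        "n_total": 165, "n_gt45": 5, "coupled_del_gt100": 2,
        "partial_duplication": 4, "ECS": 1, "other": 0, "unidentified_border": 2,
    },
    "GC92_si53BP1_siCtIP": {
        "n_total": 96, "n_gt45": 3, "coupled_del_gt100": 1,
        "partial_duplication": 1, "ECS": 0, "other": 2, "unidentified_border": 2,
    },
    "GC49_siControl": {
        "n_total": 81, "n_gt45": 2, "coupled_del_gt100": 0,
        "partial_duplication": 1, "ECS": 1, "other": 0, "unidentified_border": 0,
    },
    "GC49_si53BP1": {
        "n_total": 123, "n_gt45": 8, "coupled_del_gt100": 4,
        "partial_duplication": 7, "ECS": 1, "other": 0, "unidentified_border": 6,
    },
}


def origin_fixture(condition: str) -> tuple[list[InsertionOrigin], int]:
    """Expand one condition's origin counts into per-insertion records.

    Synthetic stand-ins for the study's per-insertion annotations (which are
    not machine-readable): each record carries only the attributes the origin
    summary counts, assigned so every marginal count of the published table
    is reproduced.  Returns ``(origins, n_total)`` for
    :func:`ejscar.insertion_origin.origin_table`.
    """
    c = ORIGIN_COUNTS[condition]
    categories = (
        ["partial_duplication"] * c["partial_duplication"]
        + ["ECS"] * c["ECS"]
        + ["other"] * c["other"]
    )
    categories += ["unidentified"] * (c["n_gt45"] - len(categories))
    origins = []
    n_unident = c["unidentified_border"]
    n_coupled = c["coupled_del_gt100"]
    for i, cat in enumerate(categories):
        origins.append(
            InsertionOrigin(
                read_id=f"{condition}_ins{i:02d}",
                ins_len=46,
                category=cat,
                hit=None,
                border5_unidentified_len=0,
                border3_unidentified_len=0,
                border_mh5=None,
                border_mh3=None,
                coupled_deletion_gt100=i < n_coupled,
            )
        )
    # distribute the remaining unidentified-border flags over identified
    # insertions (borders carry N-additions)
    n_flagged = sum(o.has_unidentified_border for o in origins)
    out = []
    for o in origins:
        if n_flagged < n_unident and not o.has_unidentified_border:
            o = InsertionOrigin(
                read_id=o.read_id,
                ins_len=o.ins_len,
                category=o.category,
                hit=None,
                border5_unidentified_len=3,
                border3_unidentified_len=0,
                border_mh5=None,
                border_mh3=o.border_mh3,
                coupled_deletion_gt100=o.coupled_deletion_gt100,
            )
            n_flagged += 1
        out.append(o)
    return out, c["n_total"]
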