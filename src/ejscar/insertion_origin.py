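"""Origin assignment for large inserted segments at repair junctions.

Inserted segments of at least 45 bp are searched against an ordered reference
collection (reporter, nuclease expression plasmid, mitochondrion, genome,
repeat elements, other) with a local aligner, mirroring the BLAST-based
workflow such assays use, but self-contained and deterministic.  Each
insertion is then placed in one of four categories:

* ``partial_duplication`` — best hit lies in the reporter itself, i.e. the
  insertion copies sequence adjacent (5' or 3') to a cleavage site;
* ``ECS`` — ectopic chromosomal sequence, best hit in the genome (or a
  genomic repeat element) source;
* ``other`` — best hit in any remaining source (expression plasmid,
  mitochondrion, ...);
* ``unidentified`` — no hit covering the minimum identified core.

Insertion bases outside the hit interval are "unidentified nucleotides"
(N-additions); borders carrying them cannot be assessed for microhomology.
Identified borders are scored for exact microhomology between the recipient
flank and the donor sequence immediately beyond the copied interval — the
annealing signature expected under microhomology-mediated template switching.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio import Align, SeqIO

from .junction_classifier import JunctionCall, recipient_flanks
from .reporter_model import ReporterSubstrate
from .stats_util import pct_half_up

__all__ = [
    "ReferenceSource",
    "ReferenceCollection",
    "AlignmentHit",
    "InsertionOrigin",
    "InsertionTooShortError",
    "search_insertion",
    "categorize_insertion",
    "border_microhomology",
    "origin_table",
    "DEFAULT_SOURCE_ORDER",
    "DEFAULT_CATEGORY_MAP",
    "MIN_INSERTION_LEN",
    "ORIGIN_TABLE_COLUMNS",
]

_ACGTN = re.compile(r"^[ACGTN]+$")

#: size threshold for origin search of inserted segments
MIN_INSERTION_LEN = 45

#: search order; earlier sources win alignment-score ties
DEFAULT_SOURCE_ORDER = (
    "reporter",
    "isce_plasmid",
    "mitochondrion",
    "genome",
    "repeats",
    "other",
)

DEFAULT_CATEGORY_MAP: dict[str, str] = {
    "reporter": "partial_duplication",
    "genome": "ECS",
    "repeats": "ECS",
}

CATEGORIES = ("partial_duplication", "ECS", "other", "unidentified")


class InsertionTooShortError(ValueError):
    """Insertion below the origin-search size threshold."""


class ReferenceConfigError(ValueError):
    """Malformed reference collection."""


@dataclass(frozen=True)
class ReferenceSource:
    """One search target: a label, its sequence, and optional cut-site
    coordinates (used for cut-site adjacency of reporter duplications)."""

    label: str
    sequence: str
    cut_sites: tuple[int, ...] = ()

    def __post_init__(self):
        seq = self.sequence.upper()
        if not seq or not _ACGTN.match(seq):
            raise ReferenceConfigError(
                f"source '{self.label}': sequence must be non-empty ACGT/N"
            )
        object.__setattr__(self, "sequence", seq)


class ReferenceCollection:
    """Ordered reference sources for insertion-origin search."""

    def __init__(self, sources: Sequence[ReferenceSource]):
        if not sources:
            raise ReferenceConfigError("reference collection is empty")
        labels = [s.label for s in sources]
        if len(set(labels)) != len(labels):
            raise ReferenceConfigError(f"duplicate source labels in {labels}")
        self.sources = list(sources)

    def __iter__(self):
        return iter(self.sources)

    def __len__(self):
        return len(self.sources)

    def __getitem__(self, label: str) -> ReferenceSource:
        for s in self.sources:
            if s.label == label:
                return s
        raise KeyError(label)

    @classmethod
    def from_manifest(cls, manifest: str | Path | Mapping) -> "ReferenceCollection":
        """Load from a YAML manifest mapping source labels to FASTA paths.

        Schema: ``sources: [{label, path, cut_sites: [..]}, ...]``; paths are
        resolved relative to the manifest file.  Multi-record FASTAs are
        concatenated with 20-N separators so coordinates stay searchable
        without cross-record chimeric hits.
        """
        base = Path(".")
        if isinstance(manifest, (str, Path)):
            base = Path(manifest).parent
            with open(manifest) as fh:
                manifest = yaml.safe_load(fh)
        sources = []
        for entry in manifest["sources"]:
            path = Path(entry["path"])
            if not path.is_absolute():
                path = base / path
            seqs = [str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")]
            sources.append(
                ReferenceSource(
                    label=entry["label"],
                    sequence=("N" * 20).join(seqs),
                    cut_sites=tuple(entry.get("cut_sites", ())),
                )
            )
        return cls(sources)


@dataclass(frozen=True)
class AlignmentHit:
    """Best local alignment of an insertion against one reference source."""

    source_label: str
    ref_start: int
    ref_end: int
    strand: str  # "+" | "-"
    identity: float
    score: float
    q_start: int
    q_end: int


@dataclass(frozen=True)
class InsertionOrigin:
    """Origin call for one inserted segment of at least 45 bp."""

    read_id: str
    ins_len: int
    category: str
    hit: AlignmentHit | None
    border5_unidentified_len: int
    border3_unidentified_len: int
    border_mh5: int | None  # None = not assessable (unidentified border)
    border_mh3: int | None
    coupled_deletion_gt100: bool
    adjacent_side: str | None = None  # "5'" | "3'" for reporter duplications
    hr_suspect: bool = False

    @property
    def has_unidentified_border(self) -> bool:
        return (
            self.category == "unidentified"
            or self.border5_unidentified_len > 0
            or self.border3_unidentified_len > 0
        )


def _make_aligner() -> Align.PairwiseAligner:
    # megablast-like scoring; gaps cost more than mismatches so short
    # verbatim copies align unbroken
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1.0
    aligner.mismatch_score = -2.0
    aligner.open_gap_score = -2.5
    aligner.extend_gap_score = -2.5
    return aligner


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _best_in_source(
    aligner: Align.PairwiseAligner,
    source: ReferenceSource,
    query: str,
    min_core: int,
    min_identity: float,
) -> AlignmentHit | None:
    best = None
    for strand, q in (("+", query), ("-", _revcomp(query))):
        alns = aligner.align(source.sequence, q)
        try:
            aln = alns[0]  # deterministic first optimal alignment
        except IndexError:
            continue
        counts = aln.counts()
        span = counts.identities + counts.mismatches + counts.gaps
        if span < min_core:
            continue
        identity = counts.identities / span
        if identity < min_identity:
            continue
        ref_blocks, q_blocks = aln.aligned
        ref_start, ref_end = int(ref_blocks[0][0]), int(ref_blocks[-1][1])
        qs, qe = int(q_blocks[0][0]), int(q_blocks[-1][1])
        if strand == "-":
            qs, qe = len(query) - qe, len(query) - qs
        hit = AlignmentHit(
            source_label=source.label,
            ref_start=ref_start,
            ref_end=ref_end,
            strand=strand,
            identity=identity,
            score=float(alns.score),
            q_start=qs,
            q_end=qe,
        )
        # "+" strand wins ties (strictly-greater required to replace); within
        # a strand the aligner's first optimal alignment is taken, which is
        # deterministic for a fixed reference
        if best is None or hit.score > best.score:
            best = hit
    return best


def search_insertion(
    ins_seq: str,
    refs: ReferenceCollection,
    min_core: int = 20,
    min_identity: float = 0.9,
) -> AlignmentHit | None:
    """Best local alignment of an inserted segment against the references.

    Accepts hits with >= ``min_identity`` identity over >= ``min_core``
    aligned bases; ties broken by source order (earlier source wins), then by
    leftmost reference interval; the reverse complement is searched too.
    Requires ``len(ins_seq) >= 45``.
    """
    if len(ins_seq) < MIN_INSERTION_LEN:
        raise InsertionTooShortError(
            f"insertion of {len(ins_seq)} bp below the {MIN_INSERTION_LEN}-bp search threshold"
        )
    if len(refs) == 0:
        raise ReferenceConfigError("reference collection is empty")
    aligner = _make_aligner()
    best: AlignmentHit | None = None
    for source in refs:
        hit = _best_in_source(aligner, source, ins_seq.upper(), min_core, min_identity)
        if hit is not None and (best is None or hit.score > best.score):
            best = hit  # earlier sources win ties (strict > required to replace)
    return best


def border_microhomology(
    call: JunctionCall,
    hit: AlignmentHit,
    sub: ReporterSubstrate,
    refs: ReferenceCollection,
) -> tuple[int | None, int | None]:
    """Exact microhomology at each identified insertion border.

    For each border the recipient flank at the junction is compared with the
    donor sequence immediately beyond the copied interval (in insert
    orientation); the match length is the annealing signature expected under
    microhomology-mediated template switching.  A border preceded/followed by
    unidentified bases returns ``None`` (not assessable).
    """
    flank5, flank3 = recipient_flanks(call, sub)
    donor = refs[hit.source_label].sequence
    if hit.strand == "-":
        # work in insert orientation: reverse-complement the donor and map
        # the interval accordingly
        n = len(donor)
        donor = _revcomp(donor)
        s = n - hit.ref_end
        e = n - hit.ref_start
    else:
        s, e = hit.ref_start, hit.ref_end

    mh5: int | None = None
    if hit.q_start == 0:
        mh5 = 0
        limit = min(s, len(flank5))
        for h in range(1, limit + 1):
            if donor[s - h : s] == flank5[-h:]:
                mh5 = h
            else:
                break
    mh3: int | None = None
    if hit.q_end == call.ins_len:
        mh3 = 0
        limit = min(len(donor) - e, len(flank3))
        for h in range(1, limit + 1):
            if donor[e : e + h] == flank3[:h]:
                mh3 = h
            else:
                break
    return mh5, mh3


def categorize_insertion(
    call: JunctionCall,
    refs: ReferenceCollection,
    sub: ReporterSubstrate,
    min_core: int = 20,
    min_identity: float = 0.9,
    adjacency_window: int = 1000,
    hr_mh_threshold: int = 4,
    category_map: Mapping[str, str] | None = None,
) -> InsertionOrigin:
    """Full origin call for one junction's inserted segment (>= 45 bp).

    Reporter duplications are additionally annotated with whether the copied
    interval lies within ``adjacency_window`` of a cut site and on which side
    (5' = upstream of a cut, 3' = downstream), and flagged ``hr_suspect``
    when the copy extends into the excised intervening sequence with a border
    microhomology of at least ``hr_mh_threshold`` bp (a pattern compatible
    with a homology-primed sister-chromatid event).
    """
    if call.ins_len < MIN_INSERTION_LEN:
        raise InsertionTooShortError(
            f"read '{call.read_id}': insertion of {call.ins_len} bp below threshold"
        )
    cmap = dict(DEFAULT_CATEGORY_MAP if category_map is None else category_map)
    hit = search_insertion(call.ins_seq, refs, min_core=min_core, min_identity=min_identity)
    coupled = call.del_total > 100
    if hit is None:
        return InsertionOrigin(
            read_id=call.read_id,
            ins_len=call.ins_len,
            category="unidentified",
            hit=None,
            border5_unidentified_len=call.ins_len,
            border3_unidentified_len=call.ins_len,
            border_mh5=None,
            border_mh3=None,
            coupled_deletion_gt100=coupled,
        )
    category = cmap.get(hit.source_label, "other")
    b5 = hit.q_start
    b3 = call.ins_len - hit.q_end
    mh5, mh3 = border_microhomology(call, hit, sub, refs)

    adjacent_side = None
    hr_suspect = False
    if category == "partial_duplication":
        source = refs[hit.source_label]
        for cut in source.cut_sites:
            if hit.ref_end <= cut and cut - hit.ref_end <= adjacency_window:
                adjacent_side = "5'"
                break
            if hit.ref_start >= cut and hit.ref_start - cut <= adjacency_window:
                adjacent_side = "3'"
                break
            if hit.ref_start < cut < hit.ref_end:
                adjacent_side = "5'" if cut - hit.ref_start >= hit.ref_end - cut else "3'"
                break
        if len(source.cut_sites) >= 2:
            lo, hi = min(source.cut_sites), max(source.cut_sites)
            in_spacer = hit.ref_start < hi and hit.ref_end > lo
            big_mh = max([m for m in (mh5, mh3) if m is not None], default=0)
            hr_suspect = in_spacer and big_mh >= hr_mh_threshold
    return InsertionOrigin(
        read_id=call.read_id,
        ins_len=call.ins_len,
        category=category,
        hit=hit,
        border5_unidentified_len=b5,
        border3_unidentified_len=b3,
        border_mh5=mh5,
        border_mh3=mh3,
        coupled_deletion_gt100=coupled,
        adjacent_side=adjacent_side,
        hr_suspect=hr_suspect,
    )


ORIGIN_TABLE_COLUMNS = [
    "condition",
    "n_total",
    "n_ins_gt45",
    "pct_ins_gt45",
    "n_coupled_del_gt100",
    "pct_coupled_del_gt100",
    "n_partial_duplication",
    "pct_partial_duplication",
    "n_ECS",
    "pct_ECS",
    "n_other",
    "pct_other",
    "n_unidentified",
    "pct_unidentified",
    "n_unidentified_border",
    "pct_unidentified_border",
]


def origin_table(
    per_condition: Mapping[str, tuple[Sequence[InsertionOrigin], int]],
    digits: int = 1,
) -> pd.DataFrame:
    """Per-condition origin summary shaped like the published origin tables.

    ``per_condition`` maps condition label to ``(origins, n_total)`` where
    ``n_total`` is the number of sequenced junctions of that condition (the
    denominator for all frequencies except the unidentified-border fraction,
    whose denominator is the number of large insertions).  Undefined
    percentages (zero denominator) are reported as NaN, never 0.
    """
    rows = []
    for condition, (origins, n_total) in per_condition.items():
        origins = list(origins)
        n_gt45 = len(origins)
        n_coupled = sum(o.coupled_deletion_gt100 for o in origins)
        by_cat = {c: sum(o.category == c for o in origins) for c in CATEGORIES}
        n_unident_border = sum(o.has_unidentified_border for o in origins)
        row = {
            "condition": condition,
            "n_total": n_total,
            "n_ins_gt45": n_gt45,
            "pct_ins_gt45": pct_half_up(n_gt45, n_total, digits),
            "n_coupled_del_gt100": n_coupled,
            "pct_coupled_del_gt100": pct_half_up(n_coupled, n_total, digits),
            "n_partial_duplication": by_cat["partial_duplication"],
            "pct_partial_duplication": pct_half_up(by_cat["partial_duplication"], n_total, digits),
            "n_ECS": by_cat["ECS"],
            "pct_ECS": pct_half_up(by_cat["ECS"], n_total, digits),
            "n_other": by_cat["other"],
            "pct_other": pct_half_up(by_cat["other"], n_total, digits),
            "n_unidentified": by_cat["unidentified"],
            "pct_unidentified": pct_half_up(by_cat["unidentified"], n_total, digits),
            "n_unidentified_border": n_unident_border,
            "pct_unidentified_border": pct_half_up(n_unident_border, n_gt45, digits),
        }
        rows.append(row)
    return pd.DataFrame(rows, columns=ORIGIN_TABLE_COLUMNS)


def origins_to_frame(origins: Iterable[InsertionOrigin]) -> pd.DataFrame:
    """Per-insertion table (one row per categorized insertion)."""
    rows = []
    for o in origins:
        rows.append(
            {
                "read_id": o.read_id,
                "ins_len": o.ins_len,
                "category": o.category,
                "source": o.hit.source_label if o.hit else "",
                "ref_start": o.hit.ref_start if o.hit else -1,
                "ref_end": o.hit.ref_end if o.hit else -1,
                "strand": o.hit.strand if o.hit else "",
                "identity": round(o.hit.identity, 4) if o.hit else float("nan"),
                "border5_unidentified_len": o.border5_unidentified_len,
                "border3_unidentified_len": o.border3_unidentified_len,
                "border_mh5": "NA" if o.border_mh5 is None else o.border_mh5,
                "border_mh3": "NA" if o.border_mh3 is None else o.border_mh3,
                "coupled_deletion_gt100": o.coupled_deletion_gt100,
                "adjacent_side": o.adjacent_side or "",
                "hr_suspect": o.hr_suspect,
            }
        )
    return pd.DataFrame(rows)
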