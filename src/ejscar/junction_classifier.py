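"""Classification of repair-junction reads against a two-cut reporter.

Each primer-trimmed read spans the repair junction: a prefix from the left
arm, an optional inserted segment, and a suffix from the right arm.  Reads
are parsed by anchored alignment: the maximal exact prefix match against
``left_arm + overhang`` and the maximal exact suffix match against
``overhang + right_arm``.  From the two anchors we derive per-side
double-stranded deletion sizes, the number of retained 3'-protruding
nucleotides (k), any inserted segment, and the junction microhomology
(anchor-overlap) length.

Event classes follow the conservative / non-conservative axis of two-cut
reporter assays:

* ``HiFi`` — direct ligation retaining 1-4 protruding nucleotides, no
  double-stranded loss, no insertion (error-free up to overhang trimming).
* ``Insertion`` — conservative (k >= 1, no ds loss) with inserted sequence.
* ``Deletion`` — ds loss on either arm, or loss of all four protruding
  nucleotides, without insertion.
* ``DeletionWithInsertion`` — the deletion condition plus inserted sequence.
* ``Unalignable`` — anchors below the minimum length; excluded from
  downstream denominators.

Boundary ambiguity (bases attributable to either side of the joint) is
resolved by the leftmost convention: the overlap is assigned to the left arm
and its length reported as ``mh_len``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .reporter_model import OVERHANG_LEN, ReporterSubstrate

__all__ = [
    "JunctionRead",
    "JunctionCall",
    "AnchorAlignment",
    "UnalignableError",
    "AmbiguousBaseError",
    "anchor_align",
    "call_junction",
    "junction_microhomology",
    "classify_batch",
    "trim_primers",
    "read_junction_fasta",
    "calls_to_frame",
    "CALL_COLUMNS",
]

logger = logging.getLogger(__name__)

_ACGT = re.compile(r"^[ACGT]+$")

DEFAULT_MIN_ANCHOR = 15

#: stable, documented column order of the per-read table
CALL_COLUMNS = [
    "read_id",
    "event_class",
    "k_retained",
    "del_left",
    "del_right",
    "del_total",
    "ins_len",
    "ins_seq",
    "mh_len",
    "conservative",
]


class AmbiguousBaseError(ValueError):
    """Read contains IUPAC ambiguity codes or non-nucleotide characters."""


class UnalignableError(ValueError):
    """Neither-or-one anchor reached the minimum exact match length."""


@dataclass(frozen=True)
class JunctionRead:
    """One primer-trimmed PCR-product sequence spanning a repair junction."""

    id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise AmbiguousBaseError(f"read '{self.id}': empty sequence")
        seq = self.sequence.upper()
        if not _ACGT.match(seq):
            bad = sorted(set(seq) - set("ACGT"))
            raise AmbiguousBaseError(
                f"read '{self.id}': non-ACGT characters {bad} (ambiguity codes rejected)"
            )
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class AnchorAlignment:
    left_match_len: int
    right_match_len: int
    middle: str


@dataclass(frozen=True)
class JunctionCall:
    """Full classification of one junction read.

    ``del_total`` counts all bases missing relative to the k=4 reference:
    per-side double-stranded losses plus the 4 - k lost overhang bases, so a
    pure overhang loss (k=0, no ds loss) is a 4-bp deletion.  ``conservative``
    means at least one protruding nucleotide was used (k >= 1).
    """

    read_id: str
    event_class: str
    k_retained: int
    del_left: int
    del_right: int
    ins_seq: str
    mh_len: int
    reason: str = ""
    # attribution of the retained overhang bases to the two anchors
    # (k_left + k_right == k_retained); needed to reconstruct the recipient
    # flanks around an inserted segment
    k_left: int = 0
    k_right: int = 0

    @property
    def del_total(self) -> int:
        return self.del_left + self.del_right + (OVERHANG_LEN - self.k_retained)

    @property
    def ins_len(self) -> int:
        return len(self.ins_seq)

    @property
    def conservative(self) -> bool:
        return self.k_retained >= 1


def _prefix_match(read: str, ref: str, per_mismatch: int = 0) -> int:
    """Longest prefix of ``read`` matching ``ref``, optionally tolerating
    one mismatch per ``per_mismatch`` matched bases (0 = exact)."""
    n = min(len(read), len(ref))
    mismatches = 0
    last_match = 0
    for i in range(n):
        if read[i] == ref[i]:
            last_match = i + 1
        else:
            mismatches += 1
            if per_mismatch == 0 or mismatches > (i + 1) // per_mismatch:
                break
    return last_match


def _suffix_match(read: str, ref: str, per_mismatch: int = 0) -> int:
    return _prefix_match(read[::-1], ref[::-1], per_mismatch)


def anchor_align(
    read: JunctionRead,
    sub: ReporterSubstrate,
    min_anchor: int = DEFAULT_MIN_ANCHOR,
    mismatch_per: int = 0,
) -> AnchorAlignment:
    """Anchor the read on the substrate arms extended through the overhang.

    ``left_match_len`` is the maximal exact (or mismatch-tolerant, when
    ``mismatch_per`` > 0, allowing <=1 mismatch per ``mismatch_per`` bp)
    prefix match of the read against ``left_arm + overhang``;
    ``right_match_len`` the symmetric suffix match against
    ``overhang + right_arm``.  ``middle`` is the read between the anchors
    (empty when they meet or overlap; overlap resolved leftmost).

    Raises :class:`UnalignableError` when either anchor is below
    ``min_anchor``.
    """
    seq = read.sequence
    left_ref = sub.left_arm + sub.overhang
    right_ref = sub.overhang + sub.right_arm
    a = _prefix_match(seq, left_ref, mismatch_per)
    b = _suffix_match(seq, right_ref, mismatch_per)
    if a < min_anchor or b < min_anchor:
        raise UnalignableError(
            f"read '{read.id}': anchors {a}/{b} bp below minimum {min_anchor} bp"
        )
    b_eff = min(b, len(seq) - a)  # leftmost convention
    middle = seq[a : len(seq) - b_eff]
    return AnchorAlignment(left_match_len=a, right_match_len=b, middle=middle)


def call_junction(
    read: JunctionRead,
    sub: ReporterSubstrate,
    min_anchor: int = DEFAULT_MIN_ANCHOR,
    mismatch_per: int = 0,
) -> JunctionCall:
    """Classify one read.  Raises :class:`UnalignableError` on anchor failure."""
    seq = read.sequence
    la, ra = len(sub.left_arm), len(sub.right_arm)
    aln = anchor_align(read, sub, min_anchor=min_anchor, mismatch_per=mismatch_per)
    a, b = aln.left_match_len, aln.right_match_len
    overlap = max(0, a + b - len(seq))
    b_adj = b - overlap

    del_left = max(0, la - a)
    del_right = max(0, ra - b_adj)
    ovl_left = max(0, a - la)  # overhang bases joined to the left anchor
    ovl_right = max(0, b_adj - ra)
    # total retained overhang is capped at the overhang length; any excess is
    # physically extra sequence and belongs to the inserted segment
    if ovl_left + ovl_right > OVERHANG_LEN:
        ovl_right = OVERHANG_LEN - ovl_left
    k = ovl_left + ovl_right
    right_keep = min(b_adj, ra) + ovl_right
    ins = seq[a : len(seq) - right_keep]

    if not ins and del_left == 0 and del_right == 0 and k >= 1:
        event = "HiFi"
    elif ins and del_left == 0 and del_right == 0 and k >= 1:
        event = "Insertion"
    elif not ins:
        event = "Deletion"
    else:
        event = "DeletionWithInsertion"
    return JunctionCall(
        read_id=read.id,
        event_class=event,
        k_retained=k,
        del_left=del_left,
        del_right=del_right,
        ins_seq=ins,
        mh_len=overlap,
        k_left=ovl_left,
        k_right=ovl_right,
    )


def recipient_flanks(call: JunctionCall, sub: ReporterSubstrate) -> tuple[str, str]:
    """Recipient sequence flanking the inserted segment in the read.

    The 5' flank is the retained left arm plus the overhang bases attributed
    to the left anchor; the 3' flank is symmetric.  Used to measure border
    microhomologies between an insertion's donor context and the recipient.
    """
    la = len(sub.left_arm)
    flank5 = sub.left_arm[: la - call.del_left] + sub.overhang[: call.k_left]
    flank3 = (
        sub.overhang[OVERHANG_LEN - call.k_right :]
        + sub.right_arm[call.del_right :]
    )
    return flank5, flank3


def junction_microhomology(left_flank: str, right_flank: str) -> int:
    """Microhomology at the joint of two flanks joined end to end.

    The maximal block of bases attributable to both sides, i.e. the longest
    suffix of ``left_flank`` that equals a prefix of ``right_flank``; equals
    the brute-force maximum over all split points of the joined sequence.
    """
    if not left_flank or not right_flank:
        raise ValueError("both flanks must be non-empty")
    best = 0
    limit = min(len(left_flank), len(right_flank))
    for h in range(1, limit + 1):
        i, ok = 0, True
        while i < h:
            if left_flank[len(left_flank) - h + i] != right_flank[i]:
                ok = False
                break
            i += 1
        if ok:
            best = h
    return best


def classify_batch(
    reads: Iterable[JunctionRead],
    sub: ReporterSubstrate,
    min_anchor: int = DEFAULT_MIN_ANCHOR,
    mismatch_per: int = 0,
) -> tuple[list[JunctionCall], dict]:
    """Classify a batch of reads, order-preserving.

    Returns the calls (Unalignable reads included, flagged by class, so the
    caller can exclude them from denominators) and a run log with counts.
    """
    calls: list[JunctionCall] = []
    n_unalignable = 0
    reads = list(reads)
    if not reads:
        logger.warning("classify_batch: empty input")
    for read in reads:
        try:
            calls.append(
                call_junction(read, sub, min_anchor=min_anchor, mismatch_per=mismatch_per)
            )
        except UnalignableError as exc:
            n_unalignable += 1
            calls.append(
                JunctionCall(
                    read_id=read.id,
                    event_class="Unalignable",
                    k_retained=0,
                    del_left=0,
                    del_right=0,
                    ins_seq="",
                    mh_len=0,
                    reason=str(exc),
                )
            )
    log = {
        "n_reads": len(reads),
        "n_unalignable": n_unalignable,
        "n_classified": len(reads) - n_unalignable,
        "min_anchor": min_anchor,
        "mismatch_per": mismatch_per,
    }
    if n_unalignable:
        logger.info("classify_batch: %d/%d reads unalignable", n_unalignable, len(reads))
    return calls, log


def trim_primers(sequence: str, primers: Sequence[str]) -> str:
    """Remove exact primer matches (and anything outside them) when present.

    Sanger clones carry vector/primer context; reads are expected pre-trimmed
    but this removes a leading forward primer and a trailing reverse-complement
    reverse primer if found.
    """
    seq = sequence.upper()
    if not primers:
        return seq
    fwd = primers[0].upper()
    i = seq.find(fwd)
    if i >= 0:
        seq = seq[i + len(fwd):]
    if len(primers) > 1:
        rev = _revcomp(primers[1].upper())
        j = seq.rfind(rev)
        if j >= 0:
            seq = seq[:j]
    return seq


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def read_junction_fasta(path: str | Path) -> list[JunctionRead]:
    """Load junction reads from a FASTA file."""
    return [JunctionRead(id=r.id, sequence=str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]


def calls_to_frame(calls: Iterable[JunctionCall]) -> pd.DataFrame:
    """Per-read table in the stable :data:`CALL_COLUMNS` order."""
    rows = [
        {
            "read_id": c.read_id,
            "event_class": c.event_class,
            "k_retained": c.k_retained,
            "del_left": c.del_left,
            "del_right": c.del_right,
            "del_total": c.del_total,
            "ins_len": c.ins_len,
            "ins_seq": c.ins_seq,
            "mh_len": c.mh_len,
            "conservative": c.conservative,
        }
        for c in calls
    ]
    return pd.DataFrame(rows, columns=CALL_COLUMNS)
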