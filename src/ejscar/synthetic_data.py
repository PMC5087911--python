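"""Seeded generator of junction reads with ground truth.

Emulates the event repertoire observed when two nuclease-induced
double-strand ends are rejoined in a chromosomal reporter:

* HiFi rejoins retaining 1-4 of the 3'-protruding nucleotides;
* deletions with per-side sizes from a short-deletion mode (geometric) plus a
  long resection tail (uniform, 100-3000 bp by default);
* insertions that are partial duplications of reporter sequence adjacent to a
  cut site, or copies of ectopic donor-genome sequence captured with
  microhomology borders (the template-switching signature), or untemplated;
* non-templated N-additions flanking templated insertions.

Every read carries a full truth record.  Because a fixed substrate makes
roughly one in four event borders chance-match the adjacent reference base,
truth is stored both in raw generative coordinates and in leftmost-maximal
canonical coordinates (the convention the classifier reports); reads where
the two differ are flagged ``boundary_ambiguous``.

All randomness flows from a single mandatory integer seed through one
``numpy`` generator; structural choices use integer draws only, so output is
platform-stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .junction_classifier import JunctionRead
from .reporter_model import OVERHANG_LEN, ReporterSubstrate

__all__ = [
    "SimulationConfig",
    "SimulatedJunction",
    "JunctionTruth",
    "make_fixture_genome",
    "example_substrate",
    "preset_config",
    "simulate_junctions",
    "reconstruct_read",
    "write_truth",
    "read_truth",
    "write_reads_fasta",
    "reporter_sequence",
]

_BASES = "ACGT"

#: event-class mix of the distant-end (3200-bp gap) control condition
DISTANT_CLASS_PROBS = {
    "HiFi": 0.36,
    "Insertion": 0.04,
    "Deletion": 0.46,
    "DeletionWithInsertion": 0.14,
}
#: event-class mix of the close-end (34-bp gap) control condition
CLOSE_CLASS_PROBS = {
    "HiFi": 0.57,
    "Insertion": 0.07,
    "Deletion": 0.26,
    "DeletionWithInsertion": 0.10,
}

# border microhomology model: P(mh >= 2) = 2/3, matching the fraction of
# assessable insertion borders that show >= 2 bp of microhomology
DEFAULT_MH_PROBS = {0: 1 / 6, 1: 1 / 6, 2: 1 / 3, 3: 1 / 6, 4: 1 / 12, 5: 1 / 12}


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the junction simulator.

    Defaults represent the distant-end control condition: the Table-like
    class mix above, a deletion-size mixture with a substantial long-resection
    tail, and insertion origins dominated by templated capture.
    """

    substrate: ReporterSubstrate
    spacer_seq: str
    donor_genome: str
    seed: int
    n_reads: int = 190
    class_probs: dict = field(default_factory=lambda: dict(DISTANT_CLASS_PROBS))
    k_probs: dict = field(default_factory=lambda: {4: 0.7, 3: 0.1, 2: 0.1, 1: 0.1})
    # deletion size model: mixture of geometric (short) and uniform-long
    del_short_mean: float = 8.0
    del_long_weight: float = 0.35
    del_long_range: tuple = (100, 3000)
    # insertion origin + size model
    ins_origin_probs: dict = field(
        default_factory=lambda: {"partial_duplication": 0.35, "ECS": 0.45, "untemplated": 0.2}
    )
    ins_short_mean: float = 6.0
    ins_long_weight: float = 0.5
    ins_long_range: tuple = (45, 250)
    # border microhomology model for ECS capture
    mh_probs: dict = field(default_factory=lambda: dict(DEFAULT_MH_PROBS))
    # non-templated N-addition model (per border of a templated insertion)
    n_add_prob: float = 0.6
    n_add_range: tuple = (1, 25)
    # window adjacent to a cut site from which partial duplications are copied
    duplication_window: int = 1000
    min_anchor_margin: int = 25  # bases of arm always left intact

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("class_probs", "k_probs", "ins_origin_probs", "mh_probs"):
            probs = getattr(self, name)
            total = float(sum(probs.values()))
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {total!r})")
        if len(self.spacer_seq) != self.substrate.spacer_len:
            raise ValueError(
                f"spacer_seq length {len(self.spacer_seq)} != substrate spacer_len "
                f"{self.substrate.spacer_len}"
            )


@dataclass(frozen=True)
class JunctionTruth:
    """Raw generative coordinates plus leftmost-canonical coordinates.

    The read is reconstructible as
    ``left_arm[:la-del_left] + overhang[:k_left] + ins_seq +
    overhang[4-k_right:] + right_arm[del_right:]``.
    """

    event_class: str
    del_left: int
    del_right: int
    k_left: int
    k_right: int
    ins_seq: str
    origin: str | None = None  # partial_duplication | ECS | untemplated
    donor_label: str | None = None
    donor_start: int = -1
    donor_end: int = -1
    border_mh5: int | None = None  # None = not assessable (N-added border)
    border_mh3: int | None = None
    n_add5: int = 0
    n_add3: int = 0
    mh_fallback: bool = False
    # canonical (leftmost-maximal) coordinates, as the classifier reports
    c_event_class: str = ""
    c_k: int = 0
    c_del_left: int = 0
    c_del_right: int = 0
    c_ins_seq: str = ""
    c_mh_len: int = 0
    boundary_ambiguous: bool = False

    @property
    def k(self) -> int:
        return self.k_left + self.k_right


@dataclass(frozen=True)
class SimulatedJunction:
    read: JunctionRead
    truth: JunctionTruth


# ---------------------------------------------------------------------------
# fixture sequences


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def _kmers(seq: str, k: int) -> set:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def make_fixture_genome(
    seed: int,
    length: int = 20000,
    avoid: Sequence[str] = (),
    min_core: int = 20,
    max_tries: int = 20,
) -> str:
    """Reproducible random donor genome, disjoint from ``avoid`` sequences.

    Uniform base composition.  Disjointness means no shared ``min_core``-mer
    with any sequence in ``avoid`` (so nothing in the donor can masquerade as
    reporter sequence during origin search); collisions trigger regeneration.
    """
    if length < 10000:
        raise ValueError("donor genome must be at least 10 kb")
    rng = np.random.default_rng(seed)
    avoid_kmers = set()
    for seq in avoid:
        avoid_kmers |= _kmers(seq.upper(), min_core)
    for _ in range(max_tries):
        genome = _random_seq(rng, length)
        if not (_kmers(genome, min_core) & avoid_kmers):
            return genome
    raise RuntimeError("could not generate a donor genome disjoint from the substrate")


def example_substrate(
    seed: int = 20160331,
    arm_len: int = 3400,
    spacer_len: int = 3200,
    overhang: str = "ATAA",
    name: str = "toy-reporter",
) -> tuple[ReporterSubstrate, str]:
    """Seeded toy substrate (arms + spacer) for download-free testing.

    Arms default to 3.4 kb so kb-scale resection fits; ``spacer_len`` 3200
    models distant ends, 34 close ends.  Returns the substrate and the spacer
    sequence (needed to build the full reporter reference).
    """
    rng = np.random.default_rng(seed)
    left = _random_seq(rng, arm_len)
    right = _random_seq(rng, arm_len)
    spacer = _random_seq(rng, spacer_len)
    sub = ReporterSubstrate(
        name=name,
        left_arm=left,
        right_arm=right,
        overhang=overhang,
        spacer_len=spacer_len,
    )
    return sub, spacer


def reporter_sequence(sub: ReporterSubstrate, spacer_seq: str) -> tuple[str, tuple[int, int]]:
    """Full uncut reporter (left arm + spacer + right arm) and its two
    cut-site coordinates."""
    if len(spacer_seq) != sub.spacer_len:
        raise ValueError("spacer_seq length must equal substrate spacer_len")
    seq = sub.left_arm + spacer_seq + sub.right_arm
    return seq, (len(sub.left_arm), len(sub.left_arm) + sub.spacer_len)


def preset_config(kind: str, seed: int, n_reads: int = 190, **overrides) -> SimulationConfig:
    """Ready-made configs for the two study geometries.

    ``distant`` (3200-bp gap): error-prone mix, long resection tail, frequent
    templated capture.  ``close`` (34-bp gap): conservative mix, short
    deletions, rare long insertions.  Both are fully overridable.
    """
    rng_seed = int(seed) % (2**31 - 1)
    if kind == "distant":
        sub, spacer = example_substrate(spacer_len=3200)
        params = dict()
    elif kind == "close":
        sub, spacer = example_substrate(spacer_len=34)
        params = dict(
            class_probs=dict(CLOSE_CLASS_PROBS),
            del_long_weight=0.08,
            del_long_range=(100, 600),
            ins_long_weight=0.05,
            n_add_prob=0.3,
        )
    else:
        raise ValueError(f"unknown preset '{kind}' (expected 'distant' or 'close')")
    donor = make_fixture_genome(seed=7, length=20000, avoid=[sub.k4_sequence, spacer])
    params.update(overrides)
    return SimulationConfig(
        substrate=sub,
        spacer_seq=spacer,
        donor_genome=donor,
        seed=rng_seed,
        n_reads=n_reads,
        **params,
    )


# ---------------------------------------------------------------------------
# event builders


def _draw(rng: np.random.Generator, probs: dict):
    keys = list(probs)
    p = np.asarray([probs[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


def _draw_del_size(rng: np.random.Generator, cfg: SimulationConfig, cap: int) -> int:
    if rng.random() < cfg.del_long_weight:
        lo, hi = cfg.del_long_range
        size = int(rng.integers(lo, hi + 1))
    else:
        size = int(rng.geometric(1.0 / cfg.del_short_mean))
    return max(1, min(size, cap))


def _draw_ins_len(rng: np.random.Generator, cfg: SimulationConfig) -> int:
    if rng.random() < cfg.ins_long_weight:
        lo, hi = cfg.ins_long_range
        return int(rng.integers(lo, hi + 1))
    return max(1, int(rng.geometric(1.0 / cfg.ins_short_mean)))


def _pick_duplication(rng: np.random.Generator, cfg: SimulationConfig, length: int):
    """Copy a segment adjacent (5' or 3') to one of the two cut sites of the
    full reporter."""
    reporter, cuts = reporter_sequence(cfg.substrate, cfg.spacer_seq)
    cut = cuts[int(rng.integers(0, 2))]
    side = "5'" if rng.integers(0, 2) == 0 else "3'"
    window = min(cfg.duplication_window, len(reporter))
    length = min(length, window)
    if side == "5'":
        hi = cut - length
        lo = max(0, cut - window)
    else:
        lo = cut
        hi = min(len(reporter), cut + window) - length
    if hi < lo:
        lo, hi = 0, len(reporter) - length
    start = int(rng.integers(lo, hi + 1))
    return reporter[start : start + length], "reporter", start, start + length


def _pick_ecs(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    flank5: str,
    flank3: str,
    length: int,
    mh5: int,
    mh3: int,
    max_tries: int = 50,
):
    """Donor interval whose flanks share the drawn microhomologies with the
    recipient flanks (the template-switching annealing signature).

    The copied segment starts right after a donor occurrence of the last
    ``mh5`` recipient bases and ends right before a donor occurrence of the
    first ``mh3`` recipient bases; the interval length is allowed to flex
    around ``length`` to satisfy the 3' constraint.  After bounded retries
    the constraint falls back to MH = 0 (noted in truth).
    """
    donor = cfg.donor_genome
    target5 = flank5[-mh5:] if mh5 > 0 else ""
    target3 = flank3[:mh3] if mh3 > 0 else ""
    lo_len = max(1, int(length * 0.8))
    hi_len = int(length * 1.2) + mh3 + 1

    starts = []
    if target5:
        i = donor.find(target5)
        while i >= 0 and len(starts) < 500:
            starts.append(i + mh5)
            i = donor.find(target5, i + 1)
    if not starts:
        starts = [int(rng.integers(0, max(1, len(donor) - hi_len)))]
        if target5:
            # no donor occurrence of the 5' microhomology at all
            mh5 = 0
    order = rng.permutation(len(starts))
    for idx in order[:max_tries]:
        d0 = starts[idx]
        if d0 + hi_len >= len(donor):
            continue
        if not target3:
            return donor[d0 : d0 + length], d0, d0 + length, mh5, 0, False
        j = donor.find(target3, d0 + lo_len, d0 + hi_len)
        if j > d0:
            return donor[d0:j], d0, j, mh5, mh3, False
    # fallback: unconstrained interval, MH = 0
    d0 = int(rng.integers(0, len(donor) - length))
    return donor[d0 : d0 + length], d0, d0 + length, 0, 0, True


def _maximal_border_mh(donor: str, d0: int, d1: int, flank5: str, flank3: str):
    """Canonical (maximal) exact border matches around a copied interval."""
    mh5 = 0
    while mh5 < min(d0, len(flank5)) and donor[d0 - mh5 - 1] == flank5[-mh5 - 1]:
        mh5 += 1
    mh3 = 0
    while d1 + mh3 < len(donor) and mh3 < len(flank3) and donor[d1 + mh3] == flank3[mh3]:
        mh3 += 1
    return mh5, mh3


# ---------------------------------------------------------------------------
# canonical reparse (independent of the classifier module)


def _leftmost_parse(seq: str, sub: ReporterSubstrate) -> dict:
    """Leftmost-maximal canonical coordinates of a junction read.

    This is the coordinate convention the per-read reports use: the left
    anchor is extended as far as it exactly matches ``left_arm + overhang``,
    the right anchor symmetrically, overlap assigned to the left arm, and at
    most four joint bases counted as retained overhang.
    """
    left_ref = sub.left_arm + sub.overhang
    right_ref = sub.overhang + sub.right_arm
    la, ra = len(sub.left_arm), len(sub.right_arm)
    a = 0
    while a < min(len(seq), len(left_ref)) and seq[a] == left_ref[a]:
        a += 1
    b = 0
    while b < min(len(seq), len(right_ref)) and seq[len(seq) - 1 - b] == right_ref[len(right_ref) - 1 - b]:
        b += 1
    overlap = max(0, a + b - len(seq))
    b_adj = b - overlap
    del_left = max(0, la - a)
    del_right = max(0, ra - b_adj)
    k_l = max(0, a - la)
    k_r = max(0, b_adj - ra)
    if k_l + k_r > OVERHANG_LEN:
        k_r = OVERHANG_LEN - k_l
    k = k_l + k_r
    right_keep = min(b_adj, ra) + k_r
    ins = seq[a : len(seq) - right_keep]
    if not ins and del_left == 0 and del_right == 0 and k >= 1:
        event = "HiFi"
    elif ins and del_left == 0 and del_right == 0 and k >= 1:
        event = "Insertion"
    elif not ins:
        event = "Deletion"
    else:
        event = "DeletionWithInsertion"
    return {
        "event_class": event,
        "k": k,
        "del_left": del_left,
        "del_right": del_right,
        "ins_seq": ins,
        "mh_len": overlap,
    }


# ---------------------------------------------------------------------------
# main generator


def _build_insertion_seq(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    flank5: str,
    flank3: str,
):
    """Inserted segment per the origin model; returns (ins, truth fields)."""
    origin = _draw(rng, cfg.ins_origin_probs)
    length = _draw_ins_len(rng, cfg)
    fields = dict(origin=origin, donor_label=None, donor_start=-1, donor_end=-1,
                  border_mh5=None, border_mh3=None, n_add5=0, n_add3=0, mh_fallback=False)
    if origin == "untemplated":
        return _random_seq(rng, length), fields

    if origin == "partial_duplication":
        core, label, d0, d1 = _pick_duplication(rng, cfg, length)
        donor_seq, _ = reporter_sequence(cfg.substrate, cfg.spacer_seq)
        fallback = False
    else:  # ECS capture via microhomology-mediated template switching
        mh5 = _draw(rng, cfg.mh_probs)
        mh3 = _draw(rng, cfg.mh_probs)
        core, d0, d1, mh5, mh3, fallback = _pick_ecs(
            rng, cfg, flank5, flank3, length, mh5, mh3
        )
        label = "genome"
        donor_seq = cfg.donor_genome

    # canonical maximal border matches for the raw interval
    mh5_true, mh3_true = _maximal_border_mh(donor_seq, d0, d1, flank5, flank3)
    fields.update(donor_label=label, donor_start=d0, donor_end=d1,
                  border_mh5=mh5_true, border_mh3=mh3_true, mh_fallback=fallback)

    # non-templated N-additions; an N-added border is no longer assessable
    ins = core
    if rng.random() < cfg.n_add_prob:
        n5 = int(rng.integers(cfg.n_add_range[0], cfg.n_add_range[1] + 1))
        ins = _random_seq(rng, n5) + ins
        fields.update(n_add5=n5, border_mh5=None)
    if rng.random() < cfg.n_add_prob:
        n3 = int(rng.integers(cfg.n_add_range[0], cfg.n_add_range[1] + 1))
        ins = ins + _random_seq(rng, n3)
        fields.update(n_add3=n3, border_mh3=None)
    return ins, fields


def simulate_junctions(cfg: SimulationConfig) -> list[SimulatedJunction]:
    """Generate ``cfg.n_reads`` junction reads with ground truth.

    Deterministic under a fixed seed.  The empirical class mix converges to
    ``class_probs``; ECS capture intervals are chosen so their donor flanks
    share the drawn microhomology with the recipient flanks.
    """
    # domain-separated seed sequence: keeps the read stream independent of
    # the fixture-genome stream even when the same integer seeds both
    rng = np.random.default_rng([cfg.seed, 0x6E6A])
    sub = cfg.substrate
    la, ra = len(sub.left_arm), len(sub.right_arm)
    O = sub.overhang
    cap_l = la - cfg.min_anchor_margin
    cap_r = ra - cfg.min_anchor_margin
    sims: list[SimulatedJunction] = []
    for i in range(cfg.n_reads):
        event = _draw(rng, cfg.class_probs)
        dl = dr = k_l = k_r = 0
        ins = ""
        extra = dict()
        if event == "HiFi":
            k_r = _draw(rng, cfg.k_probs)
        elif event == "Insertion":
            k_l = _draw(rng, cfg.k_probs)
            flank5 = sub.left_arm + O[:k_l]
            flank3 = sub.right_arm
            ins, extra = _build_insertion_seq(rng, cfg, flank5, flank3)
        elif event == "Deletion":
            mode = _draw(
                rng,
                {"left_only": 0.3, "right_only": 0.3, "both": 0.3, "overhang_only": 0.1},
            )
            if mode in ("left_only", "both"):
                dl = _draw_del_size(rng, cfg, cap_l)
            if mode in ("right_only", "both"):
                dr = _draw_del_size(rng, cfg, cap_r)
            # the un-resected side may keep protruding nucleotides
            if mode == "left_only" and rng.random() < 0.5:
                k_r = _draw(rng, cfg.k_probs)
            elif mode == "right_only" and rng.random() < 0.5:
                k_l = _draw(rng, cfg.k_probs)
        else:  # DeletionWithInsertion
            mode = _draw(rng, {"left_only": 0.25, "right_only": 0.25, "both": 0.5})
            if mode in ("left_only", "both"):
                dl = _draw_del_size(rng, cfg, cap_l)
            if mode in ("right_only", "both"):
                dr = _draw_del_size(rng, cfg, cap_r)
            flank5 = sub.left_arm[: la - dl]
            flank3 = sub.right_arm[dr:]
            ins, extra = _build_insertion_seq(rng, cfg, flank5, flank3)

        seq = (
            sub.left_arm[: la - dl]
            + O[:k_l]
            + ins
            + (O[OVERHANG_LEN - k_r :] if k_r else "")
            + sub.right_arm[dr:]
        )
        canon = _leftmost_parse(seq, sub)
        raw_matches = (
            canon["event_class"] == event
            and canon["k"] == k_l + k_r
            and canon["del_left"] == dl
            and canon["del_right"] == dr
            and canon["ins_seq"] == ins
        )
        truth = JunctionTruth(
            event_class=event,
            del_left=dl,
            del_right=dr,
            k_left=k_l,
            k_right=k_r,
            ins_seq=ins,
            c_event_class=canon["event_class"],
            c_k=canon["k"],
            c_del_left=canon["del_left"],
            c_del_right=canon["del_right"],
            c_ins_seq=canon["ins_seq"],
            c_mh_len=canon["mh_len"],
            boundary_ambiguous=not raw_matches,
            **extra,
        )
        sims.append(SimulatedJunction(read=JunctionRead(id=f"sim{i:05d}", sequence=seq), truth=truth))
    return sims


def reconstruct_read(truth: JunctionTruth, sub: ReporterSubstrate) -> str:
    """Rebuild the read from its raw truth record (lossless grammar)."""
    la, ra = len(sub.left_arm), len(sub.right_arm)
    return (
        sub.left_arm[: la - truth.del_left]
        + sub.overhang[: truth.k_left]
        + truth.ins_seq
        + (sub.overhang[OVERHANG_LEN - truth.k_right :] if truth.k_right else "")
        + sub.right_arm[truth.del_right :]
    )


# ---------------------------------------------------------------------------
# I/O

_TRUTH_COLUMNS = [
    "read_id",
    "event_class",
    "del_left",
    "del_right",
    "k_left",
    "k_right",
    "ins_seq",
    "origin",
    "donor_label",
    "donor_start",
    "donor_end",
    "border_mh5",
    "border_mh3",
    "n_add5",
    "n_add3",
    "mh_fallback",
    "c_event_class",
    "c_k",
    "c_del_left",
    "c_del_right",
    "c_ins_seq",
    "c_mh_len",
    "boundary_ambiguous",
]


def write_truth(sims: Sequence[SimulatedJunction], path: str | Path) -> None:
    """Lossless truth table (TSV) paired with the reads FASTA."""
    rows = []
    for s in sims:
        t = s.truth
        rows.append(
            {
                "read_id": s.read.id,
                "event_class": t.event_class,
                "del_left": t.del_left,
                "del_right": t.del_right,
                "k_left": t.k_left,
                "k_right": t.k_right,
                "ins_seq": t.ins_seq,
                "origin": t.origin or "",
                "donor_label": t.donor_label or "",
                "donor_start": t.donor_start,
                "donor_end": t.donor_end,
                "border_mh5": "NA" if t.border_mh5 is None else t.border_mh5,
                "border_mh3": "NA" if t.border_mh3 is None else t.border_mh3,
                "n_add5": t.n_add5,
                "n_add3": t.n_add3,
                "mh_fallback": t.mh_fallback,
                "c_event_class": t.c_event_class,
                "c_k": t.c_k,
                "c_del_left": t.c_del_left,
                "c_del_right": t.c_del_right,
                "c_ins_seq": t.c_ins_seq,
                "c_mh_len": t.c_mh_len,
                "boundary_ambiguous": t.boundary_ambiguous,
            }
        )
    pd.DataFrame(rows, columns=_TRUTH_COLUMNS).to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", keep_default_na=False,
        dtype={"ins_seq": str, "c_ins_seq": str, "border_mh5": str, "border_mh3": str},
    )


def write_reads_fasta(sims: Sequence[SimulatedJunction], path: str | Path) -> None:
    records = [SeqRecord(Seq(s.read.sequence), id=s.read.id, description="") for s in sims]
    SeqIO.write(records, str(path), "fasta")
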