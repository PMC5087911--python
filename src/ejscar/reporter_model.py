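"""Two-cut end-joining reporter substrates.

A reporter carries two meganuclease (I-SceI-style) cleavage sites separated by a
spacer of ``spacer_len`` bp.  Cleavage excises the spacer and leaves two
double-strand ends (DSEs), each with a 4-nt 3'-protruding overhang.  Rejoining
of the two retained arms is read out by sequencing across the repair junction.
This module represents the substrate and derives the reference junction
sequences against which every read is interpreted.

Coordinates are 0-based, half-open, on the k=4 reference junction
(``left_arm + overhang + right_arm``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SubstrateConfigError",
    "ReporterSubstrate",
    "ReferenceJunction",
    "DoubleStrandEnd",
    "build_substrate",
    "reference_junctions",
    "excise",
    "junctions_to_fasta",
]

_ACGT = re.compile(r"^[ACGT]+$")

OVERHANG_LEN = 4
#: canonical I-SceI preset: 18-bp recognition site leaving 4-nt 3' overhangs
ISCEI_OVERHANG = "ATAA"


class SubstrateConfigError(ValueError):
    """Malformed substrate configuration; names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"substrate config field '{field}': {message}")


def _check_seq(field: str, seq: str) -> str:
    if not isinstance(seq, str) or not seq:
        raise SubstrateConfigError(field, "must be a non-empty string")
    seq = seq.upper()
    if not _ACGT.match(seq):
        raise SubstrateConfigError(field, "contains characters outside ACGT")
    return seq


@dataclass(frozen=True)
class ReporterSubstrate:
    """The two retained arms of a two-cut reporter plus its cut geometry.

    ``left_arm`` ends at the left cut's double-strand boundary; ``right_arm``
    begins at the right cut's double-strand boundary; ``overhang`` is the 4-nt
    3'-protruding segment a perfect rejoin restores once; ``spacer_len`` is the
    excised distance between the two cuts (34 bp for "close" ends, 3200 bp for
    "distant" ends in the assays this models); ``orientation`` records whether
    the two ends' overhangs are mutually annealable.
    """

    name: str
    left_arm: str
    right_arm: str
    overhang: str
    spacer_len: int
    orientation: str = "compatible"

    def __post_init__(self):
        object.__setattr__(self, "left_arm", _check_seq("left_arm", self.left_arm))
        object.__setattr__(self, "right_arm", _check_seq("right_arm", self.right_arm))
        object.__setattr__(self, "overhang", _check_seq("overhang", self.overhang))
        if len(self.overhang) != OVERHANG_LEN:
            raise SubstrateConfigError(
                "overhang", f"must be exactly {OVERHANG_LEN} nt, got {len(self.overhang)}"
            )
        if not isinstance(self.spacer_len, int) or isinstance(self.spacer_len, bool):
            raise SubstrateConfigError("spacer_len", "must be an integer")
        if self.spacer_len < OVERHANG_LEN:
            raise SubstrateConfigError(
                "spacer_len", f"must be >= overhang length ({OVERHANG_LEN})"
            )
        if self.orientation not in ("compatible", "incompatible"):
            raise SubstrateConfigError(
                "orientation", "must be 'compatible' or 'incompatible'"
            )

    @property
    def junction_pos(self) -> int:
        """Offset of the first base after left_arm on the k=4 reference."""
        return len(self.left_arm)

    @property
    def k4_sequence(self) -> str:
        return self.left_arm + self.overhang + self.right_arm


@dataclass(frozen=True)
class ReferenceJunction:
    """Reference sequence for direct ligation retaining k protruding nucleotides.

    k=4 is the error-free rejoin with one full overhang copy between the arms;
    k<4 sequences have 4-k overhang bases removed at ``junction_pos``, i.e.
    they retain the overhang suffix.
    """

    k: int
    sequence: str
    junction_pos: int


@dataclass(frozen=True)
class DoubleStrandEnd:
    """One end presented for joining: its arm and the 3'-protruding segment."""

    side: str  # "left" | "right"
    arm: str
    protruding: str


def build_substrate(config: Mapping | str | Path) -> ReporterSubstrate:
    """Build and validate a :class:`ReporterSubstrate` from a config.

    ``config`` is either a mapping or a path to a YAML file with keys
    ``name``, ``left_arm``, ``right_arm``, ``overhang``, ``spacer_len`` and
    optional ``orientation``.  Arms may instead be supplied as a 2-record
    FASTA referenced by ``arms_fasta`` (record ids ``left_arm``/``right_arm``).
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, Mapping):
        raise SubstrateConfigError("<root>", "config must be a mapping or YAML path")
    cfg = dict(config)
    fasta = cfg.pop("arms_fasta", None)
    if fasta is not None:
        records = {r.id: str(r.seq) for r in SeqIO.parse(str(fasta), "fasta")}
        for arm in ("left_arm", "right_arm"):
            if arm not in records:
                raise SubstrateConfigError("arms_fasta", f"missing record '{arm}'")
            cfg.setdefault(arm, records[arm])
    required = ("left_arm", "right_arm", "overhang", "spacer_len")
    for field in required:
        if field not in cfg:
            raise SubstrateConfigError(field, "missing")
    return ReporterSubstrate(
        name=str(cfg.get("name", "reporter")),
        left_arm=cfg["left_arm"],
        right_arm=cfg["right_arm"],
        overhang=cfg["overhang"],
        spacer_len=cfg["spacer_len"],
        orientation=cfg.get("orientation", "compatible"),
    )


def reference_junctions(sub: ReporterSubstrate) -> list[ReferenceJunction]:
    """Reference junctions for direct ligation of k = 4, 3, 2, 1 overhang bases.

    Pure and deterministic: byte-identical output for identical substrates.
    """
    out = []
    for k in (4, 3, 2, 1):
        seq = sub.left_arm + sub.overhang[OVERHANG_LEN - k:] + sub.right_arm
        out.append(ReferenceJunction(k=k, sequence=seq, junction_pos=sub.junction_pos))
    return out


def excise(sub: ReporterSubstrate) -> tuple[DoubleStrandEnd, DoubleStrandEnd]:
    """The two double-strand ends left after cleavage at both sites.

    For ``compatible`` orientation the two protruding segments are mutually
    annealable and a k=4 rejoin reconstructs an intact cut-site region; for
    ``incompatible`` orientation the right end presents the reverse of the
    overhang and no full annealing exists (k then counts total overhang bases
    retained at the joint, however they got there).
    """
    left = DoubleStrandEnd(side="left", arm=sub.left_arm, protruding=sub.overhang)
    right_prot = sub.overhang if sub.orientation == "compatible" else sub.overhang[::-1]
    right = DoubleStrandEnd(side="right", arm=sub.right_arm, protruding=right_prot)
    return left, right


def junctions_to_fasta(juncs: Iterable[ReferenceJunction], path: str | Path) -> None:
    """Export reference junctions as FASTA, k encoded in each record id."""
    records = [
        SeqRecord(Seq(j.sequence), id=f"ref_junction_k{j.k}", description="")
        for j in juncs
    ]
    SeqIO.write(records, str(path), "fasta")
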