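"""Summary tables and statistics over junction calls.

Produces the per-condition event-class frequency tables, insertion-size
summaries and the nonparametric comparisons used to contrast repair of close
vs. distant double-strand ends: Mann-Whitney U for size distributions (exact
enumeration at small n, tie-corrected normal approximation otherwise) and an
exact conditional (hypergeometric / Fisher) test for pooled proportions.

Note on proportion tests: the original assays tested per-experiment replicate
fractions with t-tests; replicate-level fractions are not part of this
package's inputs, so pooled-count exact tests are provided instead and are
not numerically comparable to replicate-level p-values.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats as sps

from .junction_classifier import JunctionCall
from .stats_util import pct_half_up

__all__ = [
    "ClassCountTable",
    "EVENT_CLASSES",
    "tabulate",
    "class_table",
    "compare_sizes",
    "compare_proportions",
    "insertion_size_summary",
    "EXACT_MIN_N",
    "EXACT_MAX_TOTAL",
]

logger = logging.getLogger(__name__)

EVENT_CLASSES = ("HiFi", "Insertion", "Deletion", "DeletionWithInsertion")

#: exact Mann-Whitney enumeration is used when min(n_a, n_b) <= EXACT_MIN_N
#: and n_a + n_b <= EXACT_MAX_TOTAL; otherwise the tie-corrected normal
#: approximation
EXACT_MIN_N = 8
EXACT_MAX_TOTAL = 25


@dataclass(frozen=True)
class ClassCountTable:
    """Event-class counts and printed-precision percentages for one condition.

    Percentages are computed on ``n_total`` (classified junctions only,
    Unalignable excluded upstream) and rounded half-up to ``digits`` decimals
    (0 for class tables).  ``conservative`` counts junctions using at least
    one protruding nucleotide: HiFi + Insertion.
    """

    condition: str
    counts: dict
    digits: int = 0

    @property
    def n_total(self) -> int:
        return sum(self.counts[c] for c in EVENT_CLASSES)

    def pct(self, event_class: str) -> float:
        return pct_half_up(self.counts[event_class], self.n_total, self.digits)

    @property
    def n_conservative(self) -> int:
        return self.counts["HiFi"] + self.counts["Insertion"]

    @property
    def pct_conservative(self) -> float:
        return pct_half_up(self.n_conservative, self.n_total, self.digits)

    def to_row(self) -> dict:
        row = {"condition": self.condition, "n_total": self.n_total}
        for c in EVENT_CLASSES:
            row[f"n_{c}"] = self.counts[c]
            row[f"pct_{c}"] = self.pct(c)
        row["n_conservative"] = self.n_conservative
        row["pct_conservative"] = self.pct_conservative
        return row


def tabulate(calls: Sequence[JunctionCall], condition: str, digits: int = 0) -> ClassCountTable:
    """Event-class count table for one condition's calls.

    Unalignable calls are excluded from the denominator, mirroring
    sequenced-junction denominators.  Empty input yields undefined (NaN)
    percentages.
    """
    counts = {c: 0 for c in EVENT_CLASSES}
    for call in calls:
        if call.event_class == "Unalignable":
            continue
        counts[call.event_class] += 1
    if sum(counts.values()) == 0:
        logger.warning("tabulate(%s): no classified calls; percentages undefined", condition)
    return ClassCountTable(condition=condition, counts=counts, digits=digits)


def class_table(tables: Sequence[ClassCountTable]) -> pd.DataFrame:
    """Stack per-condition class tables into one DataFrame."""
    return pd.DataFrame([t.to_row() for t in tables])


def from_counts(condition: str, counts: Mapping[str, int], digits: int = 0) -> ClassCountTable:
    """Build a table directly from published per-class counts."""
    missing = set(EVENT_CLASSES) - set(counts)
    if missing:
        raise ValueError(f"missing class counts: {sorted(missing)}")
    return ClassCountTable(condition=condition, counts=dict(counts), digits=digits)


def _u_statistic(a: Sequence[float], b: Sequence[float]) -> float:
    """U for sample a: #(a_i > b_j) + 0.5 * #(a_i == b_j)."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def compare_sizes(sizes_a: Sequence[float], sizes_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney comparison of two size samples.

    Exact branch (min(n) <= 8 and combined n <= 25): the permutation null is
    enumerated over all assignments of the pooled values, and the p-value is
    the fraction of assignments with |U - n_a*n_b/2| at least as large as
    observed (ties contribute 0.5 to U, so the enumeration is tie-exact).
    Larger samples use the tie-corrected normal approximation.  When every
    value is tied across both samples, p = 1 with a warning.

    Returns ``(U, p)`` with U the statistic of the first sample.
    """
    a, b = list(sizes_a), list(sizes_b)
    if not a or not b:
        raise ValueError("each sample must contain at least one value")
    if len(set(a) | set(b)) == 1:
        logger.warning("compare_sizes: all values tied across both samples; p = 1")
        return _u_statistic(a, b), 1.0
    n_a, n_b = len(a), len(b)
    u_obs = _u_statistic(a, b)
    if min(n_a, n_b) <= EXACT_MIN_N and n_a + n_b <= EXACT_MAX_TOTAL:
        pooled = a + b
        center = n_a * n_b / 2.0
        dev_obs = abs(u_obs - center)
        n_extreme = 0
        n_all = 0
        idx = range(len(pooled))
        for combo in itertools.combinations(idx, n_a):
            sel = set(combo)
            aa = [pooled[i] for i in combo]
            bb = [pooled[i] for i in idx if i not in sel]
            u = _u_statistic(aa, bb)
            n_all += 1
            if abs(u - center) >= dev_obs - 1e-12:
                n_extreme += 1
        return u_obs, n_extreme / n_all
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def compare_proportions(x1: int, n1: int, x2: int, n2: int) -> dict:
    """Exact conditional two-sided test of two pooled proportions.

    Fisher's exact test on the 2x2 table (hypergeometric two-sided p), plus
    the proportion difference and ratio.  Not comparable to replicate-level
    t-tests.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0:
            raise ValueError("sample sizes must be positive")
        if not 0 <= x <= n:
            raise ValueError(f"count {x} outside [0, {n}]")
    _, p = sps.fisher_exact([[x1, n1 - x1], [x2, n2 - x2]], alternative="two-sided")
    p1, p2 = x1 / n1, x2 / n2
    return {
        "p_value": float(p),
        "prop1": p1,
        "prop2": p2,
        "difference": p1 - p2,
        "ratio": p1 / p2 if p2 > 0 else math.inf,
    }


def insertion_size_summary(
    calls: Sequence[JunctionCall],
    threshold: int = 45,
    long_deletion: int = 100,
    inclusive: bool = True,
) -> dict:
    """Insertion sizes and large-insertion frequencies for one condition.

    ``threshold`` (default 45 bp, the origin-search cut-off) selects "long"
    insertions, compared with ``>=`` by default (``inclusive=False`` switches
    to strict ``>``).  Frequencies are over all classified junctions;
    stratification distinguishes insertions coupled to a deletion
    (del_total > 0) and to a long deletion (del_total > ``long_deletion``).
    """
    classified = [c for c in calls if c.event_class != "Unalignable"]
    n_total = len(classified)
    with_ins = [c for c in classified if c.ins_len > 0]
    sizes = [c.ins_len for c in with_ins]
    if inclusive:
        long_ins = [c for c in with_ins if c.ins_len >= threshold]
    else:
        long_ins = [c for c in with_ins if c.ins_len > threshold]
    n_long = len(long_ins)
    n_long_coupled = sum(c.del_total > 0 for c in long_ins)
    n_long_del_gt = sum(c.del_total > long_deletion for c in long_ins)
    return {
        "n_total": n_total,
        "sizes": sizes,
        "n_insertions": len(sizes),
        "median_size": float(pd.Series(sizes).median()) if sizes else math.nan,
        "n_long": n_long,
        "pct_long": pct_half_up(n_long, n_total, 1),
        "n_long_coupled": n_long_coupled,
        "n_long_uncoupled": n_long - n_long_coupled,
        "n_long_coupled_del_gt100": n_long_del_gt,
        "pct_long_coupled_del_gt100": pct_half_up(n_long_del_gt, n_total, 1),
    }


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")


def run_pipeline(
    reads_fasta,
    substrate_config,
    refs_manifest,
    out_dir,
    condition: str = "sample",
    min_insertion: int = 45,
    long_deletion: int = 100,
    min_anchor: int = 15,
    inclusive_threshold: bool = True,
) -> dict:
    """End-to-end run: classify reads, assign insertion origins, summarize.

    Writes into ``out_dir``: ``calls.tsv`` (per read), ``class_table.tsv``,
    ``origins.tsv`` (per large insertion), ``origin_table.tsv``,
    ``insertion_summary.tsv`` and ``run_log.json``.  Deterministic given the
    inputs.  On any stage failure the partially written outputs are removed
    and a stage-named :class:`PipelineError` is raised.
    """
    import json
    from pathlib import Path

    from . import __version__
    from .insertion_origin import (
        ReferenceCollection,
        categorize_insertion,
        origin_table,
        origins_to_frame,
    )
    from .junction_classifier import (
        calls_to_frame,
        classify_batch,
        read_junction_fasta,
    )
    from .reporter_model import build_substrate

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _emit(name: str, frame: pd.DataFrame) -> Path:
        path = out_dir / name
        frame.to_csv(path, sep="\t", index=False)
        written.append(path)
        return path

    try:
        stage = "load_inputs"
        sub = build_substrate(substrate_config)
        reads = read_junction_fasta(reads_fasta)
        refs = ReferenceCollection.from_manifest(refs_manifest) if refs_manifest else None

        stage = "classify"
        calls, log = classify_batch(reads, sub, min_anchor=min_anchor)
        _emit("calls.tsv", calls_to_frame(calls))

        stage = "tabulate"
        table = tabulate(calls, condition)
        _emit("class_table.tsv", class_table([table]))

        stage = "origins"
        origins = []
        if refs is not None:
            for call in calls:
                if call.event_class in ("Insertion", "DeletionWithInsertion") and (
                    call.ins_len >= min_insertion
                    if inclusive_threshold
                    else call.ins_len > min_insertion
                ):
                    origins.append(categorize_insertion(call, refs, sub))
            _emit("origins.tsv", origins_to_frame(origins))
            _emit("origin_table.tsv", origin_table({condition: (origins, table.n_total)}))

        stage = "summarize"
        summary = insertion_size_summary(
            calls,
            threshold=min_insertion,
            long_deletion=long_deletion,
            inclusive=inclusive_threshold,
        )
        summary_row = {k: v for k, v in summary.items() if k != "sizes"}
        summary_row["condition"] = condition
        _emit("insertion_summary.tsv", pd.DataFrame([summary_row]))

        stage = "run_log"
        log_path = out_dir / "run_log.json"
        log_path.write_text(
            json.dumps(
                {
                    "tool": "ejscar",
                    "version": __version__,
                    "condition": condition,
                    "inputs": {
                        "reads_fasta": str(reads_fasta),
                        "substrate_config": str(substrate_config),
                        "refs_manifest": str(refs_manifest) if refs_manifest else None,
                    },
                    "params": {
                        "min_insertion": min_insertion,
                        "long_deletion": long_deletion,
                        "min_anchor": min_anchor,
                        "inclusive_threshold": inclusive_threshold,
                    },
                    "classify_log": log,
                },
                indent=2,
            )
        )
        written.append(log_path)
    except Exception as exc:  # noqa: BLE001 - abort semantics
        for path in written:
            path.unlink(missing_ok=True)
        raise PipelineError(stage, exc) from exc
    return {
        "calls": calls,
        "table": table,
        "origins": origins,
        "summary": summary,
        "outputs": [str(p) for p in written],
    }
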