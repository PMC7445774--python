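"""qTerm-Seq quantification core.

Reads are quality-filtered, anchored to the constant amplicon flanks,
assigned to terminator variants when a complete hairpin is present, and
classified by the offset of their 3' end relative to the hairpin's last
nucleotide (coordinate 0; the first downstream nucleotide is +1):

* ``terminated``        offset in [+1, +8] (through the poly(U) tract)
* ``readthrough``       offset >= +9 (beyond the poly(U) tract)
* ``truncated_discard`` offset <= 0 (3' end inside the hairpin; the complete
  hairpin cannot be confirmed, so these reads are excluded from TE)

Per-variant termination efficiency is TE_TS = 100 * terminated / (terminated
+ read-through); abundances are normalized to transcripts-per-million within
each sample.  Variants do not need to be known in advance: a complete
hairpin in a read identifies its variant by the 5'-arm sequence (de novo
mode), or an explicit library can be supplied for lookup.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .design import TerminatorDesign, TerminatorVariant, reverse_complement

__all__ = [
    "QCReport",
    "ReadAssignment",
    "qc_filter",
    "match_variant",
    "classify_read",
    "assign_reads",
    "quantify",
    "quantify_replicates",
    "assign_variant_ids",
    "end_position_histogram",
]

TERMINATED_WINDOW = (1, 8)

CLASS_LABELS = (
    "terminated",
    "readthrough",
    "truncated_discard",
    "qc_fail",
    "unassigned",
)


# ---------------------------------------------------------------------------
# QC


@dataclass
class QCReport:
    n_in: int = 0
    n_pass: int = 0
    n_dropped_quality: int = 0
    n_trimmed: int = 0


def _mean_quality(qual: str) -> float:
    return float(np.frombuffer(qual.encode(), dtype=np.uint8).mean()) - 33.0


def _trim_adapter(seq: str, qual: str, adapter: str, min_identity: float,
                  min_overlap: int = 3) -> tuple[str, str, bool]:
    """3'-adapter trimming: find the leftmost occurrence (full or running off
    the read 3' end) matching at >= ``min_identity``; trim from there."""
    L, A = len(seq), len(adapter)
    for start in range(max(0, L - A - 32), L - min_overlap + 1):
        n = min(A, L - start)
        matches = sum(1 for a, b in zip(seq[start : start + n], adapter[:n]) if a == b)
        if matches / n >= min_identity:
            return seq[:start], qual[:start], True
    return seq, qual, False


def qc_filter(
    reads: Iterable[tuple[str, str, str]],
    min_q: float = 30.0,
    adapters: Sequence[str] | None = None,
    adapter_identity: float = 0.90,
    per_base: bool = False,
) -> tuple[list[tuple[str, str, str]], QCReport]:
    """Drop low-quality reads and trim 3' adapter sequence.

    A read passes if its mean Phred score is >= ``min_q`` (or, with
    ``per_base``, if every base is); adapter suffixes matching one of
    ``adapters`` at >= ``adapter_identity`` are removed before the quality
    check.  Returns the surviving reads and a stage report.
    """
    report = QCReport()
    out = []
    for idx, rec in enumerate(reads):
        try:
            read_id, seq, qual = rec
        except Exception as exc:  # malformed record from a hand-built stream
            raise ValueError(f"malformed read record at index {idx}") from exc
        if len(seq) != len(qual):
            raise ValueError(
                f"record {idx} ({read_id}): sequence and quality lengths differ"
            )
        report.n_in += 1
        if adapters:
            for adapter in adapters:
                seq, qual, trimmed = _trim_adapter(seq, qual, adapter, adapter_identity)
                if trimmed:
                    report.n_trimmed += 1
                    break
        if not seq:
            report.n_dropped_quality += 1
            continue
        q = np.frombuffer(qual.encode(), dtype=np.uint8).astype(float) - 33.0
        ok = bool(q.min() >= min_q) if per_base else bool(q.mean() >= min_q)
        if ok:
            report.n_pass += 1
            out.append((read_id, seq, qual))
        else:
            report.n_dropped_quality += 1
    return out, report


# ---------------------------------------------------------------------------
# variant matching and classification


@dataclass
class ReadAssignment:
    read_id: str
    variant_id: str | None
    orientation: str | None  # "forward" / "reverse"
    offset_3prime: int | None  # relative to hairpin last nucleotide (0)
    class_label: str
    stem_5arm: str | None = None


class LibraryAnchors:
    """Constant-flank anchors plus (optionally) a known stem->variant map.

    With ``variants`` given, only known stems are assigned; without, every
    complete hairpin defines a variant keyed by its 5'-arm sequence (de novo
    discovery, the normal qTerm-Seq situation).
    """

    def __init__(
        self,
        design: TerminatorDesign,
        variants: Sequence[TerminatorVariant] | None = None,
        prefix_mismatch_budget: int = 0,
    ):
        self.design = design
        self.prefix_mismatch_budget = int(prefix_mismatch_budget)
        self.anchor = design.prefix + "A" * design.polya_len
        self.stem_to_id: dict[str, str] | None = None
        if variants is not None:
            self.stem_to_id = {v.stem_5arm: v.variant_id for v in variants}

    def lookup(self, stem: str) -> str | None:
        if self.stem_to_id is None:
            return stem  # de novo: the stem sequence is the variant key
        return self.stem_to_id.get(stem)


def _hamming_within(a: str, b: str, budget: int) -> bool:
    if len(a) != len(b):
        return False
    if budget <= 0:
        return a == b
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > budget:
                return False
    return True


def match_variant(
    read: tuple[str, str, str] | str, anchors: LibraryAnchors
) -> ReadAssignment:
    """Anchor one QC-passed read and, if its complete hairpin is present,
    assign its variant, orientation (loop GAAA = forward, TTTC = reverse)
    and 3'-end offset.

    Reads that anchor but end before the hairpin's last nucleotide carry an
    incomplete hairpin: they get offset <= 0 and no variant assignment
    (class ``truncated_discard`` downstream).  Reads that do not anchor at
    the constant flank are ``unassigned``.
    """
    if isinstance(read, str):
        read_id, seq = "read", read
    else:
        read_id, seq = read[0], read[1]
    d = anchors.design
    anchor_len = len(anchors.anchor)
    if len(seq) < anchor_len or not _hamming_within(
        seq[:anchor_len], anchors.anchor, anchors.prefix_mismatch_budget
    ):
        return ReadAssignment(read_id, None, None, None, "unassigned")

    offset = (len(seq) - 1) - d.hairpin_end
    body = seq[anchor_len:]
    k, loop_len = d.stem_len, len(d.loop_forward)
    if len(body) >= 2 * k + loop_len:
        arm1 = body[:k]
        loop = body[k : k + loop_len]
        arm2 = body[k + loop_len : 2 * k + loop_len]
        if arm2 == reverse_complement(arm1):
            orientation = None
            if loop == d.loop_forward:
                orientation = "forward"
            elif loop == d.loop_reverse:
                orientation = "reverse"
            if orientation is not None:
                vid = anchors.lookup(arm1)
                if vid is not None:
                    return ReadAssignment(
                        read_id, vid, orientation, offset, "", stem_5arm=arm1
                    )
                return ReadAssignment(read_id, None, orientation, offset, "unassigned")
        # anchored but the hairpin region does not reconstruct: treat as
        # unassignable rather than guessing a variant
        return ReadAssignment(read_id, None, None, offset, "unassigned")
    # complete hairpin absent: 3'-truncated within the hairpin
    return ReadAssignment(read_id, None, None, offset, "")


def classify_read(
    assignment: ReadAssignment, window: tuple[int, int] = TERMINATED_WINDOW
) -> ReadAssignment:
    """Fill in the class label from the 3'-end offset.

    ``terminated`` iff offset in [window_low, window_high] (default [1, 8]),
    ``readthrough`` iff beyond, ``truncated_discard`` iff <= window_low - 1
    ... i.e. at or before the hairpin's last nucleotide.
    """
    if assignment.class_label in ("qc_fail", "unassigned"):
        return assignment
    off = assignment.offset_3prime
    if off is None:
        assignment.class_label = "unassigned"
    elif off < window[0]:
        assignment.class_label = "truncated_discard"
    elif off <= window[1]:
        assignment.class_label = "terminated"
    else:
        assignment.class_label = "readthrough"
    return assignment


def assign_reads(
    reads: Iterable[tuple[str, str, str]],
    anchors: LibraryAnchors,
    window: tuple[int, int] = TERMINATED_WINDOW,
) -> pd.DataFrame:
    """Match and classify a stream of QC-passed reads into a tidy table."""
    rows = []
    for read in reads:
        a = classify_read(match_variant(read, anchors), window)
        rows.append(
            (a.read_id, a.variant_id, a.orientation, a.offset_3prime,
             a.class_label, a.stem_5arm)
        )
    return pd.DataFrame(
        rows,
        columns=["read_id", "variant_id", "orientation", "offset_3prime",
                 "class_label", "stem_5arm"],
    )


# ---------------------------------------------------------------------------
# quantification


def quantify(
    assignments: pd.DataFrame,
    min_reads: int = 200,
    top_k: int | None = 2000,
    keep_all: bool = False,
) -> pd.DataFrame:
    """Aggregate classified assignments into per-variant terminator calls.

    TE_TS = 100 * n_terminated / (n_terminated + n_readthrough).  TPM is
    computed over *all* observed variants before any filtering (so TPM sums
    to 1e6 across the unfiltered table); the read-count filter
    (``n_total >= min_reads``) and the ``top_k`` total-reads cap then select
    the reported variants.  ``keep_all`` returns the unfiltered table with a
    ``pass_filter`` column instead.
    """
    if len(assignments) == 0:
        import warnings

        warnings.warn("no assignments supplied; returning empty call table")
        return pd.DataFrame(
            columns=["variant_id", "stem_5arm", "n_terminated", "n_readthrough",
                     "n_total", "te_ts", "tpm", "pass_filter"]
        )
    usable = assignments[assignments["class_label"].isin(["terminated", "readthrough"])]
    if len(usable) == 0:
        import warnings

        warnings.warn("no terminated/read-through assignments; empty call table")
        return pd.DataFrame(
            columns=["variant_id", "stem_5arm", "n_terminated", "n_readthrough",
                     "n_total", "te_ts", "tpm", "pass_filter"]
        )
    grouped = (
        usable.groupby("variant_id")
        .agg(
            stem_5arm=("stem_5arm", "first"),
            n_terminated=("class_label", lambda s: int((s == "terminated").sum())),
            n_readthrough=("class_label", lambda s: int((s == "readthrough").sum())),
        )
        .reset_index()
    )
    grouped["n_total"] = grouped["n_terminated"] + grouped["n_readthrough"]
    grouped["te_ts"] = 100.0 * grouped["n_terminated"] / grouped["n_total"]
    grouped["tpm"] = 1e6 * grouped["n_total"] / grouped["n_total"].sum()
    grouped = grouped.sort_values(
        ["n_total", "stem_5arm"], ascending=[False, True]
    ).reset_index(drop=True)
    passed = grouped["n_total"] >= min_reads
    if top_k is not None:
        passed &= grouped.index < top_k  # rows already sorted by total reads
    grouped["pass_filter"] = passed
    if keep_all:
        return grouped
    return grouped[grouped["pass_filter"]].reset_index(drop=True)


def quantify_replicates(
    assignment_tables: Sequence[pd.DataFrame],
    min_reads: int = 200,
    top_k: int | None = 2000,
) -> pd.DataFrame:
    """Per-variant calls across replicates: replicate TE list, mean and SD.

    A variant is reported if it passes the read filter in every replicate.
    """
    per_rep = [
        quantify(a, min_reads=min_reads, top_k=top_k, keep_all=True)
        for a in assignment_tables
    ]
    common = None
    for tbl in per_rep:
        ids = set(tbl.loc[tbl["pass_filter"], "variant_id"])
        common = ids if common is None else (common & ids)
    common = common or set()
    rows = []
    for vid in sorted(common):
        tes = [float(t.loc[t["variant_id"] == vid, "te_ts"].iloc[0]) for t in per_rep]
        stem = per_rep[0].loc[per_rep[0]["variant_id"] == vid, "stem_5arm"].iloc[0]
        n_total = int(
            sum(t.loc[t["variant_id"] == vid, "n_total"].iloc[0] for t in per_rep)
        )
        rows.append(
            {
                "variant_id": vid,
                "stem_5arm": stem,
                "n_total": n_total,
                "te_replicates": tes,
                "te_mean": float(np.mean(tes)),
                "te_sd": float(np.std(tes, ddof=1)) if len(tes) >= 2 else np.nan,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["variant_id", "stem_5arm", "n_total", "te_replicates",
                 "te_mean", "te_sd"],
    )


def assign_variant_ids(calls: pd.DataFrame, count_col: str = "n_total"):
    """Rename variants T1, T2, ... in descending order of total read
    abundance across all supplied calls (ties broken lexicographically by
    stem sequence).

    ``calls`` may be a concatenation over samples; counts are summed per
    variant first.  Returns ``(renamed_calls, mapping)`` where ``mapping``
    has columns (variant_id, stem_5arm, total_reads, terminator_id).
    """
    totals = (
        calls.groupby("variant_id")
        .agg(total_reads=(count_col, "sum"), stem_5arm=("stem_5arm", "first"))
        .reset_index()
    )
    totals["stem_key"] = totals["stem_5arm"].fillna(totals["variant_id"])
    totals = totals.sort_values(
        ["total_reads", "stem_key"], ascending=[False, True]
    ).reset_index(drop=True)
    totals["terminator_id"] = [f"T{i + 1}" for i in range(len(totals))]
    mapping = totals[["variant_id", "stem_5arm", "total_reads", "terminator_id"]]
    renamed = calls.merge(mapping[["variant_id", "terminator_id"]], on="variant_id")
    renamed = renamed.drop(columns=["variant_id"]).rename(
        columns={"terminator_id": "variant_id"}
    )
    cols = ["variant_id"] + [c for c in renamed.columns if c != "variant_id"]
    return renamed[cols], mapping


def end_position_histogram(assignments: pd.DataFrame) -> pd.Series:
    """Read counts per 3'-end offset over all anchored reads (hairpin
    internal, terminated and read-through positions alike)."""
    offs = assignments["offset_3prime"].dropna().astype(int)
    return offs.value_counts().sort_index()
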