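"""Sequence/structure features relating terminator composition to TE.

Covers hairpin folding free energy (external RNAfold backend or a built-in
nearest-neighbor stack-sum approximation), stem G/C content, TE pool
partitioning, basal closing-pair motif counting and position-frequency
matrices for sequence logos.

Free energies always carry a unit tag ("kcal/mol" for both backends'
native output); threshold queries must state the unit they mean and are
refused on mismatch — no silent conversion between kcal and kJ.
"""

from __future__ import annotations

import math
import shutil
import subprocess
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .design import TerminatorVariant, reverse_complement

__all__ = [
    "HairpinFeatures",
    "TEPoolPartition",
    "TE_POOL_LABELS",
    "fold_hairpin",
    "te_feature_table",
    "assign_te_pools",
    "closing_pair_motif_count",
    "position_frequency_matrix",
    "gc_fraction",
]

KCAL_PER_MOL = "kcal/mol"

# Watson-Crick nearest-neighbor stacking free energies at 37 degC
# (kcal/mol).  Key: (outer pair, inner pair) for stacked pairs i.j and
# (i+1).(j-1), each pair written 5'-arm base then its partner.  Values are
# the standard Turner-style RNA Watson-Crick parameters, completed by the
# strand-flip symmetry dG(p1, p2) = dG(rev(p2), rev(p1)); stacks involving
# G-U wobbles are approximated by a single constant.
_STACK = {
    ("AU", "AU"): -0.93,
    ("AU", "UA"): -1.10,
    ("AU", "GC"): -2.08,
    ("AU", "CG"): -2.24,
    ("UA", "AU"): -1.33,
    ("UA", "UA"): -0.93,
    ("UA", "GC"): -2.11,
    ("UA", "CG"): -2.35,
    ("CG", "AU"): -2.11,
    ("CG", "UA"): -2.08,
    ("CG", "GC"): -2.36,
    ("CG", "CG"): -3.26,
    ("GC", "AU"): -2.35,
    ("GC", "UA"): -2.24,
    ("GC", "GC"): -3.26,
    ("GC", "CG"): -3.42,
}
_WOBBLE_STACK = -1.0  # crude stand-in for stacks involving G-U pairs
_PAIRS = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}
#: Hairpin loop initiation penalties (kcal/mol) by loop size; the tetraloop
#: value anchors the Jacobson-Stockmayer extrapolation used for other sizes.
_LOOP4 = 5.6


def _loop_penalty(n: int) -> float:
    if n < 3:
        return math.inf
    return _LOOP4 + (1.75 * 0.616 * math.log(n / 4.0) if n != 4 else 0.0)


def _to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def gc_fraction(seq: str) -> float:
    from Bio.SeqUtils import gc_fraction as _gc

    return float(_gc(seq))


@dataclass(frozen=True)
class HairpinFeatures:
    variant_id: str
    hairpin_seq: str  # RNA alphabet
    gc_fraction: float  # of the stem (5' arm)
    delta_g: float
    delta_g_unit: str
    closing_pairs: tuple[str, str]  # the two basal stem pairs, e.g. ("G-C", "G-C")
    predicted_structure: str  # dot-bracket
    backend: str


def _hairpin_seq(variant: TerminatorVariant) -> tuple[str, str]:
    d = variant.design
    hp = variant.forward_seq[d.hairpin_start : d.hairpin_end + 1]
    return _to_rna(hp), variant.stem_5arm


def _builtin_fold(rna: str) -> tuple[float, str]:
    """Best single outer-anchored perfect helix, scored as the sum of
    nearest-neighbor stacks plus a loop initiation penalty.

    A deliberately simple model: adequate for the designed hairpins (one
    contiguous perfect stem) and for asserting energy orderings; it is not a
    general secondary-structure predictor.
    """
    L = len(rna)
    best = (0.0, "." * L)
    max_trim = 3
    for a in range(min(max_trim, L) + 1):
        for b in range(min(max_trim, L - a) + 1):
            i, j = a, L - 1 - b
            k = 0
            while i + k < j - k - 2 and (rna[i + k], rna[j - k]) in _PAIRS:
                k += 1
            # require at least 2 pairs and a >= 3 nt loop
            while k >= 2 and (j - k + 1) - (i + k) < 3:
                k -= 1
            if k < 2:
                continue
            dg = _loop_penalty((j - k + 1) - (i + k))
            for s in range(k - 1):
                outer = rna[i + s] + rna[j - s]
                inner = rna[i + s + 1] + rna[j - s - 1]
                dg += _STACK.get((outer, inner), _WOBBLE_STACK)
            if dg < best[0]:
                struct = (
                    "." * i + "(" * k + "." * ((j - k + 1) - (i + k)) + ")" * k
                    + "." * (L - 1 - j)
                )
                best = (dg, struct)
    return best


def _vienna_fold(rna: str, temperature: float = 37.0) -> tuple[float, str]:
    exe = shutil.which("RNAfold")
    if exe is None:
        raise RuntimeError(
            "RNAfold executable not found; install the ViennaRNA package or "
            "use backend='builtin'"
        )
    proc = subprocess.run(
        [exe, "--noLP", "-d2", "-p", "-T", str(temperature), "--noPS"],
        input=rna + "\n",
        text=True,
        capture_output=True,
        check=True,
    )
    lines = [ln for ln in proc.stdout.splitlines() if ln.strip()]
    # line 2: "((((...)))) ( -12.30)"
    struct_line = lines[1]
    struct = struct_line.split(" ", 1)[0]
    dg = float(struct_line.rsplit("(", 1)[1].rstrip(")").strip())
    return dg, struct


def fold_hairpin(
    variant: TerminatorVariant | str,
    backend: str = "builtin",
    temperature: float = 37.0,
    variant_id: str | None = None,
) -> HairpinFeatures:
    """Fold a variant's hairpin (or an explicit hairpin sequence).

    ``backend="vienna"`` shells out to RNAfold (37 degC, ``-p -d2 --noLP``);
    ``backend="builtin"`` uses the dependency-free stack-sum approximation.
    Both report free energy in kcal/mol, tagged on the result.
    """
    if isinstance(variant, TerminatorVariant):
        rna, stem = _hairpin_seq(variant)
        vid = variant_id or variant.variant_id
    else:
        rna, stem = _to_rna(variant), None
        vid = variant_id or "hairpin"
    if backend == "builtin":
        dg, struct = _builtin_fold(rna)
    elif backend == "vienna":
        dg, struct = _vienna_fold(rna, temperature)
    else:
        raise ValueError(f"unknown backend {backend!r}")
    if struct.count("(") != struct.count(")"):
        raise RuntimeError("unbalanced dot-bracket structure from backend")
    if stem is None:
        # basal pairs from the folded structure's outermost pairs, if any
        stem = rna.replace("U", "T")
    basal = tuple(
        f"{stem[i]}-{reverse_complement(stem[i])}" for i in range(min(2, len(stem)))
    )
    return HairpinFeatures(
        variant_id=vid,
        hairpin_seq=rna,
        gc_fraction=gc_fraction(stem),
        delta_g=dg,
        delta_g_unit=KCAL_PER_MOL,
        closing_pairs=basal,  # type: ignore[arg-type]
        predicted_structure=struct,
        backend=backend,
    )


# ---------------------------------------------------------------------------
# feature/TE joins and pools


def te_feature_table(
    calls: pd.DataFrame, features: Iterable[HairpinFeatures]
) -> pd.DataFrame:
    """Join terminator calls with hairpin features on variant_id.

    One row per variant in the intersection, carrying TE, delta G (with
    unit), stem G/C fraction and the basal closing pairs.
    """
    feat = pd.DataFrame(
        [
            {
                "variant_id": f.variant_id,
                "delta_g": f.delta_g,
                "delta_g_unit": f.delta_g_unit,
                "gc_fraction": f.gc_fraction,
                "closing_pairs": "/".join(f.closing_pairs),
                "predicted_structure": f.predicted_structure,
            }
            for f in features
        ]
    )
    if feat.empty:
        return pd.DataFrame(
            columns=["variant_id", "te", "delta_g", "delta_g_unit",
                     "gc_fraction", "closing_pairs", "predicted_structure"]
        )
    te_col = "te_mean" if "te_mean" in calls.columns else "te_ts"
    left = calls[["variant_id", te_col]].rename(columns={te_col: "te"})
    return left.merge(feat, on="variant_id", how="inner")


def fraction_strong_below_dg(
    table: pd.DataFrame,
    dg_threshold: float,
    unit: str,
    te_threshold: float = 90.0,
) -> float:
    """Fraction of variants with delta G below ``dg_threshold`` whose TE
    exceeds ``te_threshold``.  ``unit`` must match the table's unit tag —
    thresholds are never converted silently."""
    units = set(table["delta_g_unit"].unique())
    if units != {unit}:
        raise ValueError(
            f"threshold unit {unit!r} does not match table units {sorted(units)}"
        )
    sel = table[table["delta_g"] < dg_threshold]
    if sel.empty:
        return float("nan")
    return float((sel["te"] > te_threshold).mean())


#: Pool labels with their half-open TE intervals (percent); as printed the
#: cutoffs overlap, so partitioning intervals are used: [0,90), [90,99),
#: [99,99.9), [99.9,100].
TE_POOL_LABELS = ("<90", ">=90", ">=99", ">=99.9")
_POOL_EDGES = (0.0, 90.0, 99.0, 99.9, 100.0 + 1e-9)


@dataclass
class TEPoolPartition:
    label: str
    members: pd.DataFrame  # variant_id, te, stem_5arm
    pfm: pd.DataFrame | None  # position-frequency matrix over stem positions


def assign_te_pools(calls: pd.DataFrame, te_col: str | None = None) -> list[TEPoolPartition]:
    """Partition called variants into the four 10-fold TE pools and build a
    PFM per pool (when stems are available and non-empty)."""
    if te_col is None:
        te_col = "te_mean" if "te_mean" in calls.columns else "te_ts"
    pools = []
    te = calls[te_col].to_numpy(dtype=float)
    if np.any((te < 0) | (te > 100)):
        raise ValueError("TE values must be percentages in [0, 100]")
    idx = np.digitize(te, _POOL_EDGES[1:-1], right=False)
    for k, label in enumerate(TE_POOL_LABELS):
        members = calls.loc[idx == k, ["variant_id", te_col] + (
            ["stem_5arm"] if "stem_5arm" in calls.columns else []
        )].rename(columns={te_col: "te"}).reset_index(drop=True)
        pfm = None
        if "stem_5arm" in members.columns and len(members) > 0:
            pfm = position_frequency_matrix(members["stem_5arm"].tolist())
        pools.append(TEPoolPartition(label=label, members=members, pfm=pfm))
    return pools


def closing_pair_motif_count(pools: Sequence[TEPoolPartition]) -> pd.DataFrame:
    """Count 5'-GG...CC-3' basal closures per pool.

    The motif requires both basal stem pairs to be G on the 5' arm pairing C
    on the 3' arm, i.e. the stem's first two letters are GG (a GC start is a
    G-C then C-G closure and does not count).
    """
    rows = []
    for pool in pools:
        stems = pool.members["stem_5arm"] if "stem_5arm" in pool.members else []
        n_total = len(pool.members)
        n_motif = int(sum(1 for s in stems if s[:2] == "GG"))
        rows.append({"pool": pool.label, "n_with_motif": n_motif, "n_total": n_total})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# position-frequency matrices / logos


def position_frequency_matrix(
    sequences: Sequence[str], mode: str = "frequency"
) -> pd.DataFrame:
    """Column-stochastic base-frequency matrix over stem positions.

    Rows A,C,G,T; one column per position.  ``mode="frequency"`` returns raw
    frequencies (the default logo height here); ``mode="information"``
    scales each column by its information content in bits (2 - entropy).
    """
    seqs = list(sequences)
    if not seqs:
        raise ValueError("no sequences supplied")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("sequences must have equal length")
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), L)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    counts = np.stack([(arr == b).sum(axis=0) for b in bases]).astype(float)
    freq = counts / counts.sum(axis=0, keepdims=True)
    pfm = pd.DataFrame(freq, index=list("ACGT"), columns=range(L))
    if mode == "frequency":
        return pfm
    if mode == "information":
        logf = np.log2(np.where(freq > 0, freq, 1.0))
        ent = -(freq * logf).sum(axis=0)
        return pfm * (2.0 - ent)
    raise ValueError(f"unknown mode {mode!r}")
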