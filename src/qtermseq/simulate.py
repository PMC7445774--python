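"""Synthetic Term-Seq read generator with ground truth.

Emulates, at desk scale, the 3'-end sequencing libraries the quantification
pipeline consumes.  Each read is a transcript fragment of one library
variant, anchored at the amplicon 5' end, whose 3' end encodes its fate:

* terminated reads end +1..+8 nt downstream of the hairpin's last
  nucleotide, with the offset distribution peaked at +1..+3 as observed in
  real libraries;
* read-through reads acquire a proximal 3' end ~30 nt downstream of the
  terminator site (the RNase H cleavage strategy), modelled as a truncated
  discrete normal;
* a configurable fraction of reads is 3'-truncated uniformly inside the
  hairpin (degradation/termination-like artifacts that preclude analysis).

Base-call substitution errors and per-read mean Phred levels are applied on
top.  Everything is reproducible from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import TerminatorVariant
from .flow import DEFAULT_GATES, Gate, facs_gate_assignment, validate_gates

__all__ = [
    "DOWNSTREAM_CONTEXT",
    "DEFAULT_OFFSET_WEIGHTS",
    "SimulationConfig",
    "TruthTable",
    "simulate_sample",
    "simulate_facs_bins",
    "simulate_temperature_series",
    "simulate_te_table",
]

#: Constant reporter context downstream of the cloning suffix (5' portion of
#: the eGFP CDS), giving read-through 3' ends a template to land on.
DOWNSTREAM_CONTEXT = (
    "ATGGTGAGCAAGGGCGAGGAGCTGTTCACCGGGGTGGTGCCCATCCTGGTCGAGCTGGAC"
)

#: Default terminated 3'-end offset weights over +1..+8, peaked at +1..+3
#: (the empirically dominant positions) with residual mass out to the
#: canonical +6..+8 sites.
DEFAULT_OFFSET_WEIGHTS = (0.30, 0.25, 0.20, 0.05, 0.04, 0.04, 0.06, 0.06)

TERMINATED_WINDOW = (1, 8)


@dataclass
class SimulationConfig:
    """Everything needed to draw one Term-Seq sample.

    ``true_te`` and ``abundance`` are aligned with ``variants``; abundance
    weights are relative (normalized internally).  ``quality_mean``/``sd``
    describe the per-read mean Phred level; defaults emulate a run in which
    roughly three quarters of reads clear Q30.
    """

    variants: Sequence[TerminatorVariant]
    true_te: Sequence[float]
    n_reads: int = 100_000
    abundance: Sequence[float] | None = None
    terminated_offset_dist: Sequence[float] = DEFAULT_OFFSET_WEIGHTS
    readthrough_cut_mean: float = 30.0
    readthrough_cut_sd: float = 3.0
    truncation_rate: float = 0.15
    base_error_rate: float = 0.001
    quality_mean: float = 32.0
    quality_sd: float = 3.3
    downstream_context: str = DOWNSTREAM_CONTEXT
    seed: int | Sequence[int] = 0

    def __post_init__(self) -> None:
        if len(self.variants) == 0:
            raise ValueError("no variants supplied")
        if len(self.true_te) != len(self.variants):
            raise ValueError("true_te must align with variants")
        te = np.asarray(self.true_te, dtype=float)
        if np.any((te < 0) | (te > 1)):
            raise ValueError("true_te values must be in [0, 1]")
        if self.abundance is None:
            self.abundance = np.ones(len(self.variants))
        ab = np.asarray(self.abundance, dtype=float)
        if len(ab) != len(self.variants) or np.any(ab < 0) or ab.sum() <= 0:
            raise ValueError("abundance must be non-negative weights, not all zero")
        w = np.asarray(self.terminated_offset_dist, dtype=float)
        lo, hi = TERMINATED_WINDOW
        if len(w) != hi - lo + 1 or np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError(
                f"terminated_offset_dist must be {hi - lo + 1} non-negative "
                "weights summing to 1"
            )
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        if not 0.0 <= self.truncation_rate <= 1.0:
            raise ValueError("truncation_rate must be in [0, 1]")
        designs = {
            (
                v.design.prefix,
                v.design.polya_len,
                v.design.stem_len,
                len(v.design.loop_forward),
                v.design.polyu_len,
                v.design.suffix,
            )
            for v in self.variants
        }
        if len(designs) > 1:
            raise ValueError("all variants must share one design geometry")


@dataclass
class TruthTable:
    """Ground truth for one simulated sample."""

    per_read: pd.DataFrame  # read_id, variant_id, class, offset
    per_variant: pd.DataFrame  # variant_id, true_te, reads_* counts


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.zeros(256, dtype=np.uint8)
for _k, _b in enumerate(_BASES):
    _BASE_INDEX[_b] = _k


def simulate_sample(config: SimulationConfig):
    """Draw one sample; returns ``(reads, truth)`` where ``reads`` is a list
    of ``(read_id, sequence, quality)`` tuples (Sanger Phred+33)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_reads
    variants = list(config.variants)
    nv = len(variants)
    design = variants[0].design
    hp_end = design.hairpin_end
    hp_len = design.hairpin_len
    templates = [v.forward_seq + config.downstream_context for v in variants]
    tmax = len(templates[0])

    ab = np.asarray(config.abundance, dtype=float)
    vidx = rng.choice(nv, size=n, p=ab / ab.sum())
    te = np.asarray(config.true_te, dtype=float)[vidx]

    truncated = rng.random(n) < config.truncation_rate
    terminated = (~truncated) & (rng.random(n) < te)
    readthrough = ~(truncated | terminated)

    offset = np.zeros(n, dtype=int)
    lo, hi = TERMINATED_WINDOW
    offset[terminated] = rng.choice(
        np.arange(lo, hi + 1),
        size=int(terminated.sum()),
        p=np.asarray(config.terminated_offset_dist, dtype=float),
    )
    # hairpin-internal truncation: uniform over the hairpin positions,
    # offsets -(hp_len-1)..0 relative to the hairpin's last nucleotide
    offset[truncated] = rng.integers(
        -(hp_len - 1), 1, size=int(truncated.sum())
    )
    rt = rng.normal(
        design.polyu_len + config.readthrough_cut_mean,
        config.readthrough_cut_sd,
        size=int(readthrough.sum()),
    )
    offset[readthrough] = np.clip(
        np.rint(rt).astype(int), hi + 1, tmax - 1 - hp_end
    )

    end = hp_end + offset
    mean_q = np.clip(
        np.rint(rng.normal(config.quality_mean, config.quality_sd, n)), 2, 40
    ).astype(int)
    n_err = (
        rng.binomial(end + 1, config.base_error_rate)
        if config.base_error_rate > 0
        else np.zeros(n, dtype=int)
    )

    classes = np.where(
        truncated, "truncated", np.where(terminated, "terminated", "readthrough")
    )
    reads = []
    for i in range(n):
        seq = templates[vidx[i]][: end[i] + 1]
        if n_err[i]:
            arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
            pos = rng.integers(0, arr.size, size=n_err[i])
            shift = rng.integers(1, 4, size=n_err[i])  # substitution, never identity
            arr[pos] = _BASES[(_BASE_INDEX[arr[pos]] + shift) % 4]
            seq = arr.tobytes().decode()
        reads.append((f"r{i:07d}", seq, chr(mean_q[i] + 33) * len(seq)))

    per_read = pd.DataFrame(
        {
            "read_id": [r[0] for r in reads],
            "variant_id": [variants[j].variant_id for j in vidx],
            "class": classes,
            "offset": offset,
        }
    )
    counts = (
        per_read.groupby(["variant_id", "class"]).size().unstack(fill_value=0)
    )
    per_variant = pd.DataFrame(
        {
            "variant_id": [v.variant_id for v in variants],
            "true_te": np.asarray(config.true_te, dtype=float),
        }
    ).set_index("variant_id")
    for cls in ("terminated", "readthrough", "truncated"):
        col = counts[cls] if cls in counts else pd.Series(0, index=counts.index)
        per_variant[f"reads_{cls}"] = col.reindex(per_variant.index).fillna(0).astype(int)
    per_variant["reads_emitted"] = (
        per_variant[["reads_terminated", "reads_readthrough", "reads_truncated"]].sum(axis=1)
    )
    return reads, TruthTable(per_read=per_read, per_variant=per_variant.reset_index())


def _child_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] & 0x7FFFFFFF)


def _master_entropy(seed) -> int:
    if isinstance(seed, (list, tuple)):
        return _child_seed(*seed)
    return int(seed)


@dataclass
class FacsBinSimulation:
    """Per-(bin, replicate) samples plus the variant routing table."""

    samples: dict  # (bin_label, replicate) -> (reads, TruthTable)
    routing: pd.DataFrame  # replicate, variant_id, true_te, bin
    gates: tuple[Gate, ...]


def simulate_facs_bins(
    config: SimulationConfig,
    gates: Sequence[Gate] = DEFAULT_GATES,
    sort_noise_sd: float = 5.0,
    replicates: int = 3,
) -> FacsBinSimulation:
    """Sort the library into TE gates and sequence each fraction.

    Each replicate re-routes every variant to the gate containing
    ``true_te*100 + Normal(0, sort_noise_sd)`` (clipped to [0, 100];
    left-closed/right-open gates, last gate closed) and re-simulates each
    gate fraction at the configured depth.  Empty gates yield empty samples.
    """
    validate_gates(gates)
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    master = _master_entropy(config.seed)
    rng = np.random.default_rng([master, 7_001])
    te = np.asarray(config.true_te, dtype=float)
    ab = np.asarray(config.abundance, dtype=float)

    samples: dict = {}
    routing_rows = []
    for rep in range(replicates):
        apparent = np.clip(te * 100.0 + rng.normal(0.0, sort_noise_sd, te.size), 0, 100)
        labels = [facs_gate_assignment(a, gates) for a in apparent]
        for v, lab in zip(config.variants, labels):
            routing_rows.append(
                {"replicate": rep, "variant_id": v.variant_id, "bin": lab}
            )
        for gi, gate in enumerate(gates):
            members = [i for i, lab in enumerate(labels) if lab == gate.label]
            if not members:
                samples[(gate.label, rep)] = (
                    [],
                    TruthTable(
                        per_read=pd.DataFrame(
                            columns=["read_id", "variant_id", "class", "offset"]
                        ),
                        per_variant=pd.DataFrame(
                            columns=[
                                "variant_id",
                                "true_te",
                                "reads_terminated",
                                "reads_readthrough",
                                "reads_truncated",
                                "reads_emitted",
                            ]
                        ),
                    ),
                )
                continue
            sub = replace(
                config,
                variants=[config.variants[i] for i in members],
                true_te=te[members],
                abundance=ab[members],
                seed=_child_seed(master, rep, gi),
            )
            samples[(gate.label, rep)] = simulate_sample(sub)
    routing = pd.DataFrame(routing_rows).merge(
        pd.DataFrame(
            {
                "variant_id": [v.variant_id for v in config.variants],
                "true_te": te,
            }
        ),
        on="variant_id",
    )
    return FacsBinSimulation(samples=samples, routing=routing, gates=tuple(gates))


def simulate_temperature_series(
    config: SimulationConfig,
    temps: Sequence[float],
    te_by_temp: Mapping[str, Mapping[float, float]] | pd.DataFrame,
    replicates: int = 3,
) -> dict:
    """Independent samples per (temperature, replicate).

    ``te_by_temp`` maps ``variant_id -> {temp: te}`` (or is a DataFrame
    indexed by variant_id with one column per temperature).  Seeds derive
    deterministically from (master seed, temperature index, replicate).
    Returns ``{(temp, replicate): (reads, TruthTable)}``.
    """
    if isinstance(te_by_temp, pd.DataFrame):
        te_by_temp = {
            vid: {t: float(te_by_temp.loc[vid, t]) for t in te_by_temp.columns}
            for vid in te_by_temp.index
        }
    for v in config.variants:
        if v.variant_id not in te_by_temp:
            raise ValueError(f"missing TE entries for variant {v.variant_id}")
        for t in temps:
            if t not in te_by_temp[v.variant_id]:
                raise ValueError(
                    f"missing TE for variant {v.variant_id} at {t} degC"
                )
    master = _master_entropy(config.seed)
    out = {}
    for ti, temp in enumerate(temps):
        te = [te_by_temp[v.variant_id][temp] for v in config.variants]
        for rep in range(replicates):
            sub = replace(
                config, true_te=te, seed=_child_seed(master, 9_000 + ti, rep)
            )
            out[(temp, rep)] = simulate_sample(sub)
    return out


def simulate_te_table(
    true_te: Sequence[float],
    reads_per_variant: int,
    conditions: Sequence,
    replicates: int = 3,
    seed: int = 0,
    variant_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Replicate TE measurements under the read-classification sampling law.

    Each measured TE is ``100 * Binomial(n, te) / n`` — exactly the
    distribution of the read-counting estimator for a variant with ``n``
    classified (terminated + read-through) reads — without the sequence
    overhead of full read simulation.  Intended for calibration studies
    (type-I error, power) at large variant counts.

    Returns a long table (variant_id, condition, replicate, te) with TE in
    percent.
    """
    te = np.asarray(true_te, dtype=float)
    if np.any((te < 0) | (te > 1)):
        raise ValueError("true_te values must be in [0, 1]")
    if reads_per_variant < 1:
        raise ValueError("reads_per_variant must be >= 1")
    rng = np.random.default_rng(seed)
    if variant_ids is None:
        variant_ids = [f"V{i + 1}" for i in range(te.size)]
    rows = []
    for cond in conditions:
        for rep in range(replicates):
            meas = 100.0 * rng.binomial(reads_per_variant, te) / reads_per_variant
            rows.append(
                pd.DataFrame(
                    {
                        "variant_id": variant_ids,
                        "condition": cond,
                        "replicate": rep,
                        "te": meas,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)
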