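"""Bidirectional intrinsic-terminator library design.

An intrinsic terminator is modelled here as a perfectly paired RNA hairpin
(T_hp) flanked by an upstream poly(A) tract and a downstream poly(U) tract,
embedded between constant cloning flanks.  The hairpin 5' arm is given as a
degenerate DNA pattern over ``{A,C,G,T,N,S}`` where ``S`` resolves to C/G and
``N`` to any base; the 3' arm is always the reverse complement of the 5' arm,
so the combinatorial space of a design is ``2^#S * 4^#N``.

All sequences are DNA (U encoded as T); rendering as RNA is left to callers.
Coordinates of degenerate positions are 0-based within the stem pattern.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

__all__ = [
    "BIOBRICK_PREFIX",
    "BIOBRICK_SUFFIX",
    "DEFAULT_STEM_PATTERN",
    "TerminatorDesign",
    "TerminatorVariant",
    "OligoPair",
    "DesignError",
    "reverse_complement",
    "enumerate_library",
    "sample_library",
    "reverse_orientation",
    "design_half_oligos",
    "assemble_in_silico",
]

#: BioBrick RFC10 standard prefix/suffix used as constant cloning flanks.
BIOBRICK_PREFIX = "GAATTCGCGGCCGCTTCTAGAG"
BIOBRICK_SUFFIX = "TACTAGTAGCGGCCGCTGCAG"

#: Default 14 nt hairpin 5' arm: a basal randomized 8-mer closed by two
#: strong (S=C/G) pairs, then a fixed distal hexamer.  The distal hexamer is
#: a documented placeholder (the published oligos are not in the open text);
#: it does not change the design combinatorics (2^2 * 4^6 = 16384).
DEFAULT_STEM_PATTERN = "SSNNNNNNGCCGCC"

_COMPLEMENT = str.maketrans("ACGTNS", "TGCANS")

#: Resolutions of each degenerate code, in alphabetical order.
DEGENERATE_CODES = {"N": "ACGT", "S": "CG"}
_VALID_CHARS = frozenset("ACGTNS")


class DesignError(ValueError):
    """Raised for invalid designs, patterns or assembly inputs."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (degenerate codes N/S are
    self-complementary as classes and map to themselves)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _validate_pattern(pattern: str, name: str = "pattern") -> None:
    bad = set(pattern) - _VALID_CHARS
    if bad:
        raise DesignError(
            f"{name} contains invalid characters {sorted(bad)}; "
            f"allowed: A,C,G,T,N,S"
        )
    if not pattern:
        raise DesignError(f"{name} must be non-empty")


@dataclass(frozen=True)
class TerminatorDesign:
    """A degenerate bidirectional terminator template.

    Parameters
    ----------
    stem_pattern_5arm
        Hairpin 5' arm pattern, 5'->3', basal (stem-base) positions first.
    loop_forward
        Hairpin loop in the forward orientation (default GAAA tetraloop);
        the reverse orientation shows its reverse complement (TTTC).
    polya_len, polyu_len
        Lengths of the upstream poly(A) and downstream poly(U) tracts
        (poly(U) encoded as T in DNA).
    prefix, suffix
        Constant flanks (default BioBrick RFC10).
    """

    stem_pattern_5arm: str = DEFAULT_STEM_PATTERN
    loop_forward: str = "GAAA"
    polya_len: int = 8
    polyu_len: int = 8
    prefix: str = BIOBRICK_PREFIX
    suffix: str = BIOBRICK_SUFFIX

    def __post_init__(self) -> None:
        _validate_pattern(self.stem_pattern_5arm, "stem_pattern_5arm")
        _validate_pattern(self.loop_forward, "loop_forward")
        for attr in ("prefix", "suffix"):
            seq = getattr(self, attr)
            if set(seq) - set("ACGT"):
                raise DesignError(f"{attr} must be concrete DNA (A/C/G/T)")
        if self.polya_len < 0 or self.polyu_len < 0:
            raise DesignError("tract lengths must be >= 0")

    # -- derived geometry ---------------------------------------------------

    @property
    def loop_reverse(self) -> str:
        """Loop as seen in the reverse orientation (revcomp of forward)."""
        return reverse_complement(self.loop_forward)

    @property
    def stem_len(self) -> int:
        return len(self.stem_pattern_5arm)

    @property
    def hairpin_len(self) -> int:
        return 2 * self.stem_len + len(self.loop_forward)

    @property
    def hairpin_start(self) -> int:
        """0-based index of the hairpin's first nucleotide in the full
        forward sequence."""
        return len(self.prefix) + self.polya_len

    @property
    def hairpin_end(self) -> int:
        """0-based index of the hairpin's last (3'-arm-final) nucleotide —
        the origin for 3'-end offsets."""
        return self.hairpin_start + self.hairpin_len - 1

    @property
    def template_len(self) -> int:
        return (
            len(self.prefix)
            + self.polya_len
            + self.hairpin_len
            + self.polyu_len
            + len(self.suffix)
        )

    def degenerate_positions(self) -> list[int]:
        """0-based stem-pattern positions holding a degenerate code."""
        return [
            i for i, c in enumerate(self.stem_pattern_5arm) if c in DEGENERATE_CODES
        ]

    @property
    def n_equivalents(self) -> float:
        """Degeneracy expressed in N-position equivalents (log4 space size)."""
        n_s = self.stem_pattern_5arm.count("S")
        n_n = self.stem_pattern_5arm.count("N")
        return n_n + n_s / 2.0

    @property
    def space_size(self) -> int:
        return 2 ** self.stem_pattern_5arm.count("S") * (
            4 ** self.stem_pattern_5arm.count("N")
        )

    # -- sequence construction ----------------------------------------------

    def insert_for_stem(self, stem_5arm: str) -> str:
        """Variable insert: polyA + 5' arm + loop + 3' arm + polyU."""
        return (
            "A" * self.polya_len
            + stem_5arm
            + self.loop_forward
            + reverse_complement(stem_5arm)
            + "T" * self.polyu_len
        )

    def forward_seq_for_stem(self, stem_5arm: str) -> str:
        return self.prefix + self.insert_for_stem(stem_5arm) + self.suffix

    def stem_for_index(self, index: int) -> str:
        """Decode a lexicographic rank into a concrete 5'-arm sequence."""
        if not 0 <= index < self.space_size:
            raise DesignError(f"index {index} outside design space")
        digits = []
        rem = index
        radices = [
            len(DEGENERATE_CODES.get(c, c)) for c in self.stem_pattern_5arm
        ]
        for radix in reversed(radices):
            digits.append(rem % radix)
            rem //= radix
        digits.reverse()
        return "".join(
            DEGENERATE_CODES.get(c, c)[d]
            for c, d in zip(self.stem_pattern_5arm, digits)
        )

    def matches_pattern(self, stem_5arm: str) -> bool:
        if len(stem_5arm) != self.stem_len:
            return False
        return all(
            b in DEGENERATE_CODES.get(c, c)
            for c, b in zip(self.stem_pattern_5arm, stem_5arm)
        )


@dataclass(frozen=True)
class TerminatorVariant:
    """One concrete library member.

    ``forward_seq``/``reverse_seq`` are full templates including the constant
    flanks; the reverse insert is the reverse complement of the forward
    insert framed by the same flanks, so the two differ only in the hairpin
    loop (GAAA vs TTTC).
    """

    variant_id: str
    stem_5arm: str
    forward_seq: str
    reverse_seq: str
    orientation_loop: str = "GAAA"
    design: TerminatorDesign = field(default_factory=TerminatorDesign, repr=False)

    @classmethod
    def from_stem(
        cls,
        design: TerminatorDesign,
        stem_5arm: str,
        variant_id: str,
    ) -> "TerminatorVariant":
        if not design.matches_pattern(stem_5arm):
            raise DesignError(
                f"stem {stem_5arm!r} does not match pattern "
                f"{design.stem_pattern_5arm!r}"
            )
        insert = design.insert_for_stem(stem_5arm)
        return cls(
            variant_id=variant_id,
            stem_5arm=stem_5arm,
            forward_seq=design.prefix + insert + design.suffix,
            reverse_seq=design.prefix + reverse_complement(insert) + design.suffix,
            orientation_loop=design.loop_forward,
            design=design,
        )

    @property
    def insert(self) -> str:
        p, s = len(self.design.prefix), len(self.design.suffix)
        return self.forward_seq[p : len(self.forward_seq) - s]


@dataclass(frozen=True)
class OligoPair:
    """The two half-oligos of the single-pot assembly, modelled at sequence
    level.

    ``half5`` is the top-strand 5' half; ``half3`` is the bottom-strand 3'
    half (written 5'->3') carrying a 5'-monophosphate for ligation.  The two
    anneal through ``anneal_overlap`` (the constant loop, top-strand
    rendering); mutual 3' extension across the single-stranded degenerate
    tails then reconstructs the full double-stranded template.
    """

    half5: str
    half3: str
    anneal_overlap: str
    half3_phosphorylated: bool = True
    # pattern coordinates inside each oligo, for resolving degenerate codes
    pattern_start_half5: int = 0
    pattern_start_half3: int = 0
    pattern: str = ""


def enumerate_library(
    design: TerminatorDesign, max_n_equivalents: float = 12.0
) -> list[TerminatorVariant]:
    """Enumerate every variant of the design space.

    Variants are returned in deterministic lexicographic order of the
    resolved 5'-arm sequence, with ids ``V1..Vn`` in that order (abundance
    based T-numbering happens downstream, after quantification).

    Raises
    ------
    DesignError
        If the design degeneracy exceeds ``max_n_equivalents`` N-position
        equivalents (use :func:`sample_library` instead).
    """
    if design.n_equivalents > max_n_equivalents:
        raise DesignError(
            f"design space of 4^{design.n_equivalents:g} sequences is too "
            f"large to enumerate (guard: {max_n_equivalents:g} N-equivalents);"
            " use sample_library instead"
        )
    choices = [DEGENERATE_CODES.get(c, c) for c in design.stem_pattern_5arm]
    variants = []
    for i, bases in enumerate(itertools.product(*choices)):
        stem = "".join(bases)
        variants.append(TerminatorVariant.from_stem(design, stem, f"V{i + 1}"))
    return variants


def sample_library(
    design: TerminatorDesign, n: int, seed: int
) -> list[TerminatorVariant]:
    """Draw ``n`` distinct variants uniformly without replacement.

    A desk-scale stand-in for a cloned library (~10,000 clones out of the
    16,384-sequence default space).  Reproducible under ``seed``; variants
    are returned in lexicographic order with ids matching their rank in the
    full enumeration.
    """
    import numpy as np

    if n < 1:
        raise DesignError("n must be >= 1")
    size = design.space_size
    if n > size:
        raise DesignError(f"cannot draw {n} distinct variants from a space of {size}")
    rng = np.random.default_rng(seed)
    idx = sorted(rng.choice(size, size=n, replace=False).tolist())
    return [
        TerminatorVariant.from_stem(design, design.stem_for_index(i), f"V{i + 1}")
        for i in idx
    ]


def reverse_orientation(v: TerminatorVariant) -> TerminatorVariant:
    """Flip a variant between forward and reverse orientations.

    The insert is reverse complemented within the same constant flanks; the
    GAAA<->TTTC loop swap falls out of reverse complementation (the 5' arm
    sequence itself is preserved).  Applying twice returns the original.
    """
    other_loop = reverse_complement(v.orientation_loop)
    return replace(
        v,
        forward_seq=v.reverse_seq,
        reverse_seq=v.forward_seq,
        orientation_loop=other_loop,
    )


def design_half_oligos(design: TerminatorDesign) -> OligoPair:
    """Emit the two half-oligos whose anneal->extend->ligate reconstruction
    yields the full template of every variant.

    half5 (top strand):    prefix + polyA + stem_pattern + loop
    half3 (bottom strand): revcomp(suffix) + polyA-mirror + stem_pattern
                           + revcomp(loop), 5'-monophosphorylated

    The two 3' termini pair across the constant loop; each degenerate stem
    block sits in a single-stranded 5' tail and is copied onto the opposite
    strand during extension, which is what makes the hairpin arms perfectly
    complementary by construction.  In the wet protocol complementarity of
    the two randomized blocks is enforced by hybridization selection during
    slow-cool annealing; in silico the same resolution is applied to both.
    """
    loop = design.loop_forward
    if set(loop) & set(DEGENERATE_CODES):
        raise DesignError(
            "degenerate positions fall inside the anneal overlap (loop); "
            "they must be confined to single-stranded oligo segments"
        )
    half5 = design.prefix + "A" * design.polya_len + design.stem_pattern_5arm + loop
    half3 = (
        reverse_complement(design.suffix)
        + "A" * design.polyu_len
        + design.stem_pattern_5arm
        + design.loop_reverse
    )
    return OligoPair(
        half5=half5,
        half3=half3,
        anneal_overlap=loop,
        half3_phosphorylated=True,
        pattern_start_half5=len(design.prefix) + design.polya_len,
        pattern_start_half3=len(design.suffix) + design.polyu_len,
        pattern=design.stem_pattern_5arm,
    )


def _resolve(pattern: str, start: int, oligo: str, resolution: Mapping[int, str]) -> str:
    out = list(oligo)
    for i, code in enumerate(pattern):
        if code in DEGENERATE_CODES:
            if i not in resolution:
                raise DesignError(f"resolution missing degenerate position {i}")
            base = resolution[i].upper()
            if base not in DEGENERATE_CODES[code]:
                raise DesignError(
                    f"base {base!r} not allowed at position {i} (code {code})"
                )
            out[start + i] = base
    return "".join(out)


def assemble_in_silico(pair: OligoPair, resolution: Mapping[int, str]) -> str:
    """Deterministic sequence-level model of anneal -> extend -> ligate.

    ``resolution`` maps 0-based degenerate stem-pattern positions to bases;
    it must cover exactly the degenerate positions.  Returns the top strand
    of the reconstructed double-stranded template (identical to the
    corresponding variant's ``forward_seq``).
    """
    degen = {
        i for i, c in enumerate(pair.pattern) if c in DEGENERATE_CODES
    }
    extra = set(resolution) - degen
    if extra:
        raise DesignError(
            f"resolution assigns bases at non-degenerate positions {sorted(extra)}"
        )
    top = _resolve(pair.pattern, pair.pattern_start_half5, pair.half5, resolution)
    bottom = _resolve(pair.pattern, pair.pattern_start_half3, pair.half3, resolution)
    k = len(pair.anneal_overlap)
    rc_bottom = reverse_complement(bottom)
    if k == 0 or not top.endswith(pair.anneal_overlap) or not rc_bottom.startswith(
        pair.anneal_overlap
    ):
        raise DesignError("oligo 3' ends share no complementary overlap")
    # mutual extension across each other's 5' tails, then (nick-free) ligation
    return top + rc_bottom[k:]


def iter_resolutions(design: TerminatorDesign) -> Iterator[dict[int, str]]:
    """Iterate all resolutions of the design's degenerate positions, in the
    same lexicographic order as :func:`enumerate_library`."""
    pos = design.degenerate_positions()
    choices = [DEGENERATE_CODES[design.stem_pattern_5arm[i]] for i in pos]
    for bases in itertools.product(*choices):
        yield dict(zip(pos, bases))
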