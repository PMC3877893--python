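"""Degenerate primer design from a nucleotide multiple alignment.

The design logic mirrors how "universal" cyanobactin A-gene primers are
obtained in practice: align known homologs, build a per-column consensus
that covers *every* observed base (not a majority call), then scan for
low-degeneracy, low-gap windows a suitable product length apart. The
published pair this package ships as a default is

    CBT_AF  5'-TTVGGYTAYGAYTTYGG-3'   (degeneracy 48)
    CBT_AR  5'-AGACCARGAACGRACTTC-3'  (degeneracy 4)

amplifying a nominal 804 bp region of the A-gene.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Sequence

from .seq_io import GAP, IUPAC_SETS, SETS_TO_CODE, Alignment, revcomp

__all__ = [
    "DegeneratePrimer", "PrimerPair", "ConservationProfile", "PrimerDesignParams",
    "degeneracy", "expansions", "melting_temp", "conservation_profile",
    "design_primer_pairs", "CBT_AF", "CBT_AR", "CBT_PAIR",
]


def degeneracy(sequence: str) -> int:
    """Number of distinct plain-ACGT strings an IUPAC pattern denotes."""
    d = 1
    for c in sequence:
        try:
            d *= len(IUPAC_SETS[c])
        except KeyError:
            raise ValueError(f"illegal IUPAC character {c!r} in primer") from None
    return d


def expansions(sequence: str) -> Iterator[str]:
    """Yield every plain-ACGT expansion of an IUPAC pattern (lexicographic)."""
    pools = [sorted(IUPAC_SETS[c]) for c in sequence]
    for combo in itertools.product(*pools):
        yield "".join(combo)


@dataclass(frozen=True)
class DegeneratePrimer:
    name: str
    sequence: str
    orientation: str  # "forward" | "reverse"
    degeneracy: int = field(init=False)

    def __post_init__(self):
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"orientation must be forward|reverse, got {self.orientation!r}")
        seq = self.sequence.upper().replace("U", "T")
        if GAP in seq:
            raise ValueError("primers may not contain gaps")
        if len(seq) < 10:
            raise ValueError(f"primer {self.name!r} shorter than 10 bases")
        object.__setattr__(self, "sequence", seq)
        object.__setattr__(self, "degeneracy", degeneracy(seq))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PrimerPair:
    forward: DegeneratePrimer
    reverse: DegeneratePrimer
    nominal_product_length: int
    design_window: tuple[tuple[int, int], tuple[int, int]] | None = None

    def __post_init__(self):
        if self.forward.orientation != "forward":
            raise ValueError("forward primer must have forward orientation")
        if self.reverse.orientation != "reverse":
            raise ValueError("reverse primer must have reverse orientation")
        if self.nominal_product_length < len(self.forward) + len(self.reverse):
            raise ValueError("nominal product length shorter than the two primer footprints")


#: The published A-gene screening pair (nominal 804 bp product).
CBT_AF = DegeneratePrimer("CBT_AF", "TTVGGYTAYGAYTTYGG", "forward")
CBT_AR = DegeneratePrimer("CBT_AR", "AGACCARGAACGRACTTC", "reverse")
CBT_PAIR = PrimerPair(CBT_AF, CBT_AR, nominal_product_length=804)


def melting_temp(primer: DegeneratePrimer | str) -> tuple[float, float]:
    """Wallace-rule Tm range over the degenerate family, in deg C.

    Tm = 2*(#A+#T) + 4*(#G+#C) per expansion. Because positions contribute
    independently, the (min, max) over the family equals the sum of
    per-position minima / maxima, so no enumeration is needed at any
    degeneracy.
    """
    seq = primer.sequence if isinstance(primer, DegeneratePrimer) else primer
    lo = hi = 0.0
    for c in seq:
        bases = IUPAC_SETS[c]
        contribs = [2.0 if b in "AT" else 4.0 for b in bases]
        lo += min(contribs)
        hi += max(contribs)
    return (lo, hi)


@dataclass(frozen=True)
class ColumnProfile:
    consensus: str          # minimal IUPAC code covering all observed bases
    degeneracy: int         # 1..4
    gap_fraction: float


@dataclass(frozen=True)
class ConservationProfile:
    columns: tuple[ColumnProfile, ...]

    def __len__(self) -> int:
        return len(self.columns)

    def __getitem__(self, j: int) -> ColumnProfile:
        return self.columns[j]


def conservation_profile(alignment: Alignment) -> ConservationProfile:
    """Per-column consensus over *all* observed bases (ambiguities expanded)."""
    cols = []
    n = len(alignment)
    for j in range(alignment.columns):
        observed: set[str] = set()
        gaps = 0
        for r in alignment.records:
            c = r.residues[j]
            if c == GAP:
                gaps += 1
            else:
                observed |= IUPAC_SETS[c]
        # Alignment invariant guarantees at least one non-gap residue.
        code = SETS_TO_CODE[frozenset(observed)]
        cols.append(ColumnProfile(code, len(observed), gaps / n))
    return ConservationProfile(tuple(cols))


@dataclass(frozen=True)
class PrimerDesignParams:
    min_length: int = 17
    max_length: int = 22
    max_degeneracy: int = 96
    max_gap_fraction: float = 0.10
    product_min: int = 400
    product_max: int = 1200
    tm_min: float = 40.0
    tm_max: float = 70.0
    max_3prime_degeneracy: int = 2   # per-position cap on the 3'-terminal 3 positions


def _windows(profile: ConservationProfile, params: PrimerDesignParams):
    """All (start, end, consensus, degeneracy, mean_gap) windows passing the
    per-column gap filter and the degeneracy cap."""
    ncol = len(profile)
    out = []
    for start in range(ncol):
        deg = 1
        gaps = 0.0
        for end in range(start + 1, min(ncol, start + params.max_length) + 1):
            col = profile[end - 1]
            if col.gap_fraction > params.max_gap_fraction:
                break
            deg *= col.degeneracy
            gaps += col.gap_fraction
            if deg > params.max_degeneracy:
                break
            length = end - start
            if length >= params.min_length:
                seq = "".join(profile[j].consensus for j in range(start, end))
                out.append((start, end, seq, deg, gaps / length))
    return out


def _three_prime_ok(profile: ConservationProfile, start: int, end: int,
                    terminal_at_end: bool, cap: int) -> bool:
    cols = range(end - 3, end) if terminal_at_end else range(start, start + 3)
    return all(profile[j].degeneracy <= cap for j in cols)


def design_primer_pairs(alignment: Alignment,
                        params: PrimerDesignParams = PrimerDesignParams(),
                        ) -> list[PrimerPair]:
    """Scan an alignment for degenerate primer pairs and rank them.

    Forward candidates read 5'->3' along the alignment; reverse candidates
    are reverse complements of downstream windows. Product length is
    measured on the consensus with majority-gap columns (> 50% gaps)
    dropped, the one nominal number a screen reports even though real
    amplicons vary. Ranking: total degeneracy, then mean gap fraction,
    then 3'-end degeneracy, then leftmost forward start.

    An empty result is a normal outcome, not an error.
    """
    if len(alignment) < 4:
        import warnings
        warnings.warn(f"designing on only {len(alignment)} sequences; "
                      "consensus degeneracy may be understated", stacklevel=2)
    profile = conservation_profile(alignment)
    windows = _windows(profile, params)

    # cumulative count of non-majority-gap columns, for product lengths
    keep = [1 if profile[j].gap_fraction <= 0.5 else 0 for j in range(len(profile))]
    cum = [0]
    for k in keep:
        cum.append(cum[-1] + k)

    fwd_ok = [w for w in windows
              if _three_prime_ok(profile, w[0], w[1], True, params.max_3prime_degeneracy)]
    rev_ok = [w for w in windows
              if _three_prime_ok(profile, w[0], w[1], False, params.max_3prime_degeneracy)]

    scored = []
    for fs, fe, fseq, fdeg, fgap in fwd_ok:
        flo, fhi = melting_temp(fseq)
        if flo < params.tm_min or fhi > params.tm_max:
            continue
        for rs, re_, rseq, rdeg, rgap in rev_ok:
            if rs < fe:
                continue
            product = cum[re_] - cum[fs]
            if not (params.product_min <= product <= params.product_max):
                continue
            rlo, rhi = melting_temp(rseq)
            if rlo < params.tm_min or rhi > params.tm_max:
                continue
            f3 = 1
            for j in range(fe - 3, fe):
                f3 *= profile[j].degeneracy
            r3 = 1
            for j in range(rs, rs + 3):
                r3 *= profile[j].degeneracy
            key = (fdeg * rdeg, (fgap + rgap) / 2.0, f3 * r3, fs, rs)
            scored.append((key, fs, fe, fseq, rs, re_, rseq, product))

    scored.sort(key=lambda t: t[0])
    pairs = []
    for i, (_, fs, fe, fseq, rs, re_, rseq, product) in enumerate(scored, start=1):
        fwd = DegeneratePrimer(f"F{i:03d}_{fs}", fseq, "forward")
        rev = DegeneratePrimer(f"R{i:03d}_{rs}", revcomp(rseq), "reverse")
        pairs.append(PrimerPair(fwd, rev, product, ((fs, fe), (rs, re_))))
    return pairs
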