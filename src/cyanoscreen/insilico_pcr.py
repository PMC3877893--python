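"""In-silico PCR: locate degenerate primer sites and excise amplicons.

The dry-lab analogue of the screening PCR. A primer "anneals" where its
IUPAC base set intersects the template's at every position (mismatches up
to a configurable maximum are tolerated; default 0, since degenerate codes
already encode the intended tolerance). Both template strands are scanned;
an amplicon is any forward-facing site of one primer paired with a
downstream reverse-facing site of the other within the product length
range. An empty result is the "PCR-negative strain" outcome, not an error.

Matching is bitmask-based: each IUPAC code is a 4-bit base set, a position
matches when the AND of primer and template masks is non-zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seq_io import IUPAC_SETS, SequenceRecord, revcomp
from .primer_design import DegeneratePrimer, PrimerPair

__all__ = ["AmpliconHit", "iupac_match", "find_sites", "pcr_products"]

_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
_CODE_MASK = {code: sum(_BIT[b] for b in bases) for code, bases in IUPAC_SETS.items()}


def iupac_match(code_a: str, code_b: str) -> bool:
    """True iff the two IUPAC codes' base sets intersect (N matches all)."""
    try:
        return bool(_CODE_MASK[code_a.upper()] & _CODE_MASK[code_b.upper()])
    except KeyError as exc:
        raise ValueError(f"illegal IUPAC code {exc.args[0]!r}") from None


def _mask_array(seq: str) -> np.ndarray:
    try:
        return np.array([_CODE_MASK[c] for c in seq], dtype=np.uint8)
    except KeyError as exc:
        raise ValueError(f"illegal IUPAC code {exc.args[0]!r}") from None


def _scan(primer_mask: np.ndarray, template_mask: np.ndarray, max_mismatch: int) -> list[tuple[int, int]]:
    """(start, mismatches) for every window where mismatches <= max."""
    n, m = len(template_mask), len(primer_mask)
    if n < m:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(template_mask, m)
    mism = np.count_nonzero((windows & primer_mask) == 0, axis=1)
    idx = np.nonzero(mism <= max_mismatch)[0]
    return [(int(i), int(mism[i])) for i in idx]


def find_sites(primer: DegeneratePrimer | str, template: SequenceRecord,
               max_mismatch: int = 0) -> list[tuple[int, str, int]]:
    """All annealing sites of a degenerate primer on both template strands.

    Returns (start, strand, mismatches) sorted by start, with reverse-strand
    hits reported in forward-strand coordinates (start = leftmost base of
    the footprint on the forward strand).
    """
    seq = primer.sequence if isinstance(primer, DegeneratePrimer) else primer
    if "-" in template.residues:
        raise ValueError("template must be ungapped")
    tmask = _mask_array(template.residues)
    hits = [(s, "+", mm) for s, mm in _scan(_mask_array(seq), tmask, max_mismatch)]
    hits += [(s, "-", mm) for s, mm in _scan(_mask_array(revcomp(seq)), tmask, max_mismatch)]
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


@dataclass(frozen=True)
class AmpliconHit:
    """One predicted PCR product on the forward strand of a template."""

    template_id: str
    start: int            # 0-based, half-open footprint incl. both primer sites
    end: int
    mismatches_fwd: int
    mismatches_rev: int
    product: SequenceRecord

    @property
    def product_length(self) -> int:
        return self.end - self.start


def pcr_products(pair: PrimerPair, template: SequenceRecord,
                 max_mismatch: int = 0,
                 product_length_range: tuple[int, int] = (50, 5000)) -> list[AmpliconHit]:
    """Predict amplicons for a primer pair on one template.

    Both pairings that a real PCR supports are enumerated: the forward
    primer facing right with the reverse primer facing left downstream, and
    the mirror arrangement (so the predicted product set is strand
    symmetric). Product sequences are excised verbatim from the forward
    strand. Self-pairing is reported like any other pair.
    """
    lo, hi = product_length_range
    fwd_sites = find_sites(pair.forward, template, max_mismatch)
    rev_sites = find_sites(pair.reverse, template, max_mismatch)
    flen, rlen = len(pair.forward), len(pair.reverse)

    hits: list[AmpliconHit] = []
    seen: set[tuple[int, int]] = set()

    def pair_up(left_sites, left_len, right_sites, right_len, swap: bool):
        for ls, lstrand, lmm in left_sites:
            if lstrand != "+":
                continue
            for rs, rstrand, rmm in right_sites:
                if rstrand != "-":
                    continue
                start, end = ls, rs + right_len
                if end <= ls + left_len or rs < ls + left_len:
                    continue  # must face each other, non-overlapping footprints
                if not (lo <= end - start <= hi) or (start, end) in seen:
                    continue
                seen.add((start, end))
                product = SequenceRecord(
                    f"{template.id}_amp_{start}_{end}",
                    template.residues[start:end],
                    f"amplicon {start}..{end} of {template.id}",
                )
                mmf, mmr = (rmm, lmm) if swap else (lmm, rmm)
                hits.append(AmpliconHit(template.id, start, end, mmf, mmr, product))

    # forward primer facing right, reverse primer facing left
    pair_up(fwd_sites, flen, rev_sites, rlen, swap=False)
    # mirror arrangement: reverse primer facing right, forward facing left
    pair_up(rev_sites, rlen, fwd_sites, flen, swap=True)

    hits.sort(key=lambda h: (h.start, h.end))
    return hits
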