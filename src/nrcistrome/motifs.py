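"""Nuclear-receptor response-element scoring and classification.

Nuclear receptors bind hexameric half-sites with the degenerate consensus
RGGTCA (A/GGGTCA).  A dimer site is two half-sites separated by a spacer of n
bases in one of three geometries:

* ``DRn`` — direct repeat, both hexamers read on the same strand;
* ``IRn`` — inverted repeat, head-to-head (``AGGTCA nnn TGACCT`` on the
  forward text: 5' hexamer on +, 3' hexamer on -);
* ``ERn`` — everted repeat, tail-to-tail (5' hexamer on -, 3' hexamer on +).

Half-sites are scored by a position-specific log-odds matrix (or matched
exactly in IUPAC-consensus mode); arrangements are enumerated exhaustively
over all hit pairs within the spacer range.  The spacer length is what links
an element to its preferred receptor dimer (the "1-2-3-4-5 rule": DR1 for
PPAR/RXR and RXR/RXR, DR3/ER6 for PXR, DR4 for LXR/TR, DR5 for RAR, IR1 for
FXR), so class and spacer together summarize likely dimer identity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .core import ValidationError

HALF_SITE_LEN = 6
HALF_SITE_CONSENSUS = "RGGTCA"
GC_BOX = "GGGCGG"

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTRYKMBVDHSWN", "TGCAYRMKVBHDSWN")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

CLASS_ORDER = {"DR": 0, "IR": 1, "ER": 2}


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class HalfSiteModel:
    """Length-6 position-specific scoring model for one half-site.

    ``matrix`` holds log-odds scores (6 positions x 4 bases, A/C/G/T order);
    ``threshold`` is the absolute acceptance score.  In consensus mode hits
    are exact IUPAC matches: the matrix encodes allowed bases as equiprobable
    and the threshold sits at the maximal score, so N never matches.
    """

    matrix: np.ndarray
    threshold: float
    consensus: Optional[str] = None

    def __post_init__(self) -> None:
        if self.matrix.shape != (HALF_SITE_LEN, 4):
            raise ValidationError(f"matrix must be {HALF_SITE_LEN} x 4, got {self.matrix.shape}")

    @property
    def consensus_mode(self) -> bool:
        return self.consensus is not None

    @property
    def max_score(self) -> float:
        return float(np.max(self.matrix, axis=1).sum())


@dataclass(frozen=True)
class HalfSiteHit:
    """A scoring hexamer: forward-text offset, strand and score."""

    position: int
    strand: str
    score: float


@dataclass(frozen=True)
class ArrangementCall:
    """One classified response element: class, spacer, and the two hits."""

    arrangement: str  # DR, IR or ER
    spacer: int
    positions: tuple[int, int]
    strands: tuple[str, str]
    score: float

    @property
    def label(self) -> str:
        return f"{self.arrangement}{self.spacer}"


def build_half_site_model(
    sites_or_consensus: Union[str, Sequence[str]],
    pseudocount: float = 1.0,
    background: Optional[Sequence[float]] = None,
    threshold_fraction: float = 0.8,
) -> HalfSiteModel:
    """Build a half-site model from aligned 6-mers or an IUPAC consensus.

    A single IUPAC string (e.g. ``"RGGTCA"``) gives consensus mode: allowed
    bases at each position score log(1/n_allowed / background) and the
    threshold equals the maximal score, so AGGTCA and GGGTCA tie at the top
    for RGGTCA and nothing else matches.  A list of ACGT sites gives a
    pseudocounted position frequency matrix converted to log-odds against the
    background, with the threshold at ``threshold_fraction`` of the maximal
    score.
    """
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    if bg.shape != (4,) or not math.isclose(bg.sum(), 1.0, abs_tol=1e-9):
        raise ValidationError("background must be 4 probabilities summing to 1")
    if not (0 < threshold_fraction <= 1):
        raise ValidationError("threshold fraction must lie in (0, 1]")

    if isinstance(sites_or_consensus, str):
        consensus = sites_or_consensus.upper()
        if len(consensus) != HALF_SITE_LEN:
            raise ValidationError(f"consensus must be length {HALF_SITE_LEN}")
        matrix = np.full((HALF_SITE_LEN, 4), -np.inf)
        for i, code in enumerate(consensus):
            allowed = IUPAC.get(code)
            if allowed is None:
                raise ValidationError(f"non-IUPAC character {code!r} in consensus")
            for b in allowed:
                matrix[i, _BASE_INDEX[b]] = math.log((1.0 / len(allowed)) / bg[_BASE_INDEX[b]])
        model = HalfSiteModel(matrix=matrix, threshold=float(np.max(matrix, axis=1).sum()),
                              consensus=consensus)
        return model

    sites = [s.upper() for s in sites_or_consensus]
    if not sites:
        raise ValidationError("empty training-site set")
    if any(len(s) != HALF_SITE_LEN for s in sites):
        raise ValidationError(f"all training sites must be length {HALF_SITE_LEN}")
    counts = np.zeros((HALF_SITE_LEN, 4))
    for s in sites:
        for i, b in enumerate(s):
            if b not in _BASE_INDEX:
                raise ValidationError(f"non-ACGT character {b!r} in training site {s}")
            counts[i, _BASE_INDEX[b]] += 1
    with np.errstate(divide="ignore"):
        freqs = (counts + pseudocount) / (len(sites) + 4 * pseudocount)
        matrix = np.log(freqs / bg)
    max_score = float(np.max(matrix, axis=1).sum())
    return HalfSiteModel(matrix=matrix, threshold=threshold_fraction * max_score)


def _encode(sequence: str) -> np.ndarray:
    seq = sequence.upper()
    codes = np.full(len(seq), 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        codes[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(b)] = i
    return codes


def _window_scores(codes: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Score every length-6 window; non-ACGT positions score -inf."""
    n = len(codes) - HALF_SITE_LEN + 1
    if n <= 0:
        return np.empty(0)
    padded = np.hstack([matrix, np.full((HALF_SITE_LEN, 1), -np.inf)])
    scores = np.zeros(n)
    for i in range(HALF_SITE_LEN):
        scores += padded[i, codes[i : i + n]]
    return scores


def scan_half_sites(sequence: str, model: HalfSiteModel) -> list[HalfSiteHit]:
    """All half-site hits on both strands scoring at or above the threshold.

    Positions are forward-text offsets of the hexamer start; a - strand hit
    means the reverse complement of that window matches the model.
    """
    seq = str(sequence)
    if len(seq) < HALF_SITE_LEN:
        return []
    codes = _encode(seq)
    fwd = _window_scores(codes, model.matrix)
    # a window's reverse complement is scored by the reversed, complemented matrix
    rc_matrix = model.matrix[::-1, ::-1]
    rev = _window_scores(codes, rc_matrix)
    eps = 1e-9
    hits = [
        HalfSiteHit(int(i), "+", float(s)) for i, s in enumerate(fwd) if s >= model.threshold - eps
    ] + [
        HalfSiteHit(int(i), "-", float(s)) for i, s in enumerate(rev) if s >= model.threshold - eps
    ]
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def classify_arrangements(
    hits: Iterable[HalfSiteHit], max_spacer: int = 8
) -> list[ArrangementCall]:
    """Enumerate every ordered hit pair with spacer in [0, max_spacer].

    For a left hit at p1 and right hit at p2 (spacer = p2 - p1 - 6): same
    strands give DRn; (+,-) gives IRn (head-to-head); (-,+) gives ERn
    (tail-to-tail).
    """
    ordered = sorted(hits, key=lambda h: (h.position, h.strand))
    calls = []
    for i, left in enumerate(ordered):
        for right in ordered[i + 1 :]:
            spacer = right.position - left.position - HALF_SITE_LEN
            if spacer < 0:
                continue
            if spacer > max_spacer:
                break
            if left.strand == right.strand:
                arrangement = "DR"
            elif left.strand == "+":
                arrangement = "IR"
            else:
                arrangement = "ER"
            calls.append(
                ArrangementCall(
                    arrangement=arrangement,
                    spacer=spacer,
                    positions=(left.position, right.position),
                    strands=(left.strand, right.strand),
                    score=left.score + right.score,
                )
            )
    return calls


def best_arrangement(
    sequence: str, model: HalfSiteModel, max_spacer: int = 8
) -> Optional[ArrangementCall]:
    """The maximal-scoring arrangement in a sequence, or None.

    Ties break deterministically: higher combined score, then smaller spacer,
    then class order DR < IR < ER, then leftmost position.
    """
    calls = classify_arrangements(scan_half_sites(sequence, model), max_spacer)
    if not calls:
        return None
    return min(
        calls,
        key=lambda c: (-c.score, c.spacer, CLASS_ORDER[c.arrangement], c.positions[0]),
    )


def arrangement_spectrum(
    sequences: Iterable[str], model: HalfSiteModel, max_spacer: int = 8
) -> dict[str, float]:
    """Fraction of sequences per best-call class-spacer label, plus ``none``.

    Each sequence contributes its single best arrangement; fractions sum to 1.
    """
    labels = []
    for seq in sequences:
        call = best_arrangement(str(getattr(seq, "seq", seq)), model, max_spacer)
        labels.append("none" if call is None else call.label)
    if not labels:
        raise ValidationError("arrangement spectrum of an empty sequence set")
    total = len(labels)
    spectrum: dict[str, float] = {}
    for lab in labels:
        spectrum[lab] = spectrum.get(lab, 0) + 1
    return {lab: count / total for lab, count in sorted(spectrum.items())}


def detect_overlapped_dr1(hits: Iterable[HalfSiteHit], spacer: int = 1) -> list[int]:
    """Start positions of three equally spaced same-strand half-sites.

    Three hexamers at p, p + (6+s), p + 2(6+s) form two overlapped DRs
    sharing the middle half-site (the dominant pattern among the strongest
    peaks' sequences for s = 1).
    """
    step = HALF_SITE_LEN + spacer
    positions: list[int] = []
    by_strand: dict[str, set[int]] = {"+": set(), "-": set()}
    for h in hits:
        by_strand[h.strand].add(h.position)
    for strand, pos_set in by_strand.items():
        for p in pos_set:
            if p + step in pos_set and p + 2 * step in pos_set:
                positions.append(p)
    return sorted(set(positions))


def detect_gc_box(sequence: str, core: str = GC_BOX) -> list[HalfSiteHit]:
    """All matches of the Sp1 GC-box core on either strand.

    The - strand match appears as the reverse complement of the core on the
    forward text (CCGCCC for GGGCGG).
    """
    seq = str(sequence).upper()
    rc = reverse_complement(core)
    hits = []
    for pattern, strand in ((core, "+"), (rc, "-")):
        start = seq.find(pattern)
        while start != -1:
            hits.append(HalfSiteHit(start, strand, float(len(pattern))))
            start = seq.find(pattern, start + 1)
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits
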