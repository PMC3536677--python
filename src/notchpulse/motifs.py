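"""PWM scanning for Su(H) and Hairy sites and SPS paired-site detection.

Su(H)/CSL binds a short consensus (YGTGGGAA-like); cooperative Notch
activation is promoted by Su(H) paired sites (SPS): two CSL motifs in
opposite orientation separated by a constrained spacer of 10 to 22
nucleotides.  Scanning uses additive log-odds scores (bits) against a stated
background; both strands are scanned and reverse-strand hits are reported on
the forward coordinate axis.

Spacing convention: the SPS spacer is the gap in nucleotides between the end
of the left site and the start of the right site, with inclusive bounds
[10, 22]; both head-to-head and tail-to-tail opposite-orientation patterns
qualify.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Inclusive bounds on the SPS inter-site gap, in nucleotides.
SPS_GAP_RANGE = (10, 22)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class WeightMatrix:
    """Position weight matrix in log-odds bits over {A, C, G, T}.

    Built from position frequencies with a pseudocount (default 0.5) against
    a background composition; ``threshold`` defaults to 60% of the maximal
    achievable score, since "high affinity" is a qualitative notion and the
    cut is meant to be tuned per matrix.
    """

    name: str
    weights: np.ndarray = field(repr=False)  # (length, 4) bits
    threshold: float
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[1] != 4:
            raise ValueError("weights must be (length, 4)")
        if self.threshold > self.max_score() + 1e-9:
            raise ValueError("threshold exceeds the maximal achievable score")

    def __len__(self) -> int:
        return self.weights.shape[0]

    def max_score(self) -> float:
        return float(self.weights.max(axis=1).sum())

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.weights.argmax(axis=1))

    @classmethod
    def from_counts(
        cls,
        name: str,
        counts: np.ndarray,
        pseudocount: float = 0.5,
        background: np.ndarray | None = None,
        threshold_fraction: float = 0.6,
    ) -> "WeightMatrix":
        counts = np.asarray(counts, dtype=float)
        if background is None:
            background = np.full(4, 0.25)
        background = np.asarray(background, dtype=float)
        if not np.isclose(background.sum(), 1.0):
            raise ValueError("background probabilities must sum to 1")
        probs = (counts + pseudocount) / (counts + pseudocount).sum(axis=1, keepdims=True)
        weights = np.log2(probs / background)
        wm = cls(name=name, weights=weights, threshold=0.0, background=background)
        wm.threshold = threshold_fraction * wm.max_score()
        return wm

    @classmethod
    def from_tsv(cls, path_or_buffer, name: str | None = None, **kwargs) -> "WeightMatrix":
        """Read a position-frequency table (columns A, C, G, T; one row per position)."""
        df = pd.read_csv(path_or_buffer, sep="\t", comment="#")
        counts = df[list(BASES)].to_numpy()
        return cls.from_counts(name or "matrix", counts, **kwargs)

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.weights, columns=list(BASES)).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class MotifMatch:
    """A scoring window on the forward coordinate axis (0-based start)."""

    chrom: str
    start: int
    strand: str
    score: float
    matrix: str

    def end(self, length: int) -> int:
        return self.start + length


def encode(seq: str) -> np.ndarray:
    """Sequence to integer codes; anything outside ACGT becomes 4 (N)."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(256, 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        codes[ord(b)] = i
    return codes[arr]


def scan_pwm(seq: str, wm: WeightMatrix, chrom: str = "chr") -> list[MotifMatch]:
    """Scan both strands for windows scoring at or above the matrix threshold.

    Windows containing N are skipped.  Reverse-strand matches are reported at
    the forward-axis start of the window they occupy.
    """
    L = len(wm)
    codes = encode(seq)
    n = len(codes) - L + 1
    if n <= 0:
        return []
    padded = np.vstack([wm.weights.T, np.full((1, L), -np.inf)])  # row 4 = N
    fwd = np.zeros(n)
    rev = np.zeros(n)
    # reverse-complement scoring on the forward axis: position j of the
    # window pairs with matrix position L-1-j, complemented base
    rc_weights = wm.weights[::-1, ::-1]
    rc_padded = np.vstack([rc_weights.T, np.full((1, L), -np.inf)])
    for j in range(L):
        col = codes[j : j + n]
        fwd += padded[col, j]
        rev += rc_padded[col, j]
    matches = [
        MotifMatch(chrom, int(i), "+", float(fwd[i]), wm.name)
        for i in np.flatnonzero(fwd >= wm.threshold)
    ]
    matches += [
        MotifMatch(chrom, int(i), "-", float(rev[i]), wm.name)
        for i in np.flatnonzero(rev >= wm.threshold)
    ]
    matches.sort(key=lambda m: (m.start, m.strand))
    return matches


@dataclass(frozen=True)
class SPSMatch:
    """Two opposite-strand matches with spacer gap in the allowed range."""

    left: MotifMatch
    right: MotifMatch
    gap: int
    orientation: str  # "head-to-head" (-/+ inward... see find_sps) or "tail-to-tail"


def find_sps(
    matches: list[MotifMatch],
    motif_length: int,
    gap_range: tuple[int, int] = SPS_GAP_RANGE,
) -> list[SPSMatch]:
    """All opposite-strand pairs with inter-site gap inside ``gap_range``.

    The gap is measured from the end of the left match to the start of the
    right match; bounds are inclusive.  Overlapping pairs are reported
    independently.
    """
    lo, hi = gap_range
    ms = sorted(matches, key=lambda m: m.start)
    out = []
    for i, a in enumerate(ms):
        for b in ms[i + 1 :]:
            gap = b.start - a.end(motif_length)
            if gap > hi:
                break
            if gap < lo or a.strand == b.strand:
                continue
            orientation = "head-to-head" if (a.strand, b.strand) == ("+", "-") else "tail-to-tail"
            out.append(SPSMatch(left=a, right=b, gap=gap, orientation=orientation))
    return out


def motif_gene_counts(
    genes: dict[str, tuple[int, int]],
    matches: list[MotifMatch],
    motif_length: int,
    window: int,
) -> pd.DataFrame:
    """Per-gene motif counts within ``window`` bp of the transcription unit.

    A match counts when the minimum distance between the match window and the
    gene extent is at most ``window`` (0 for overlap).  Returns a DataFrame
    with columns ``count`` and ``has_match``.
    """
    from .integrate import min_distance

    if not genes:
        raise ValueError("empty gene set")
    rows = {}
    for gid, (gstart, gend) in genes.items():
        c = sum(
            1
            for m in matches
            if min_distance((gstart, gend), (m.start, m.end(motif_length))) <= window
        )
        rows[gid] = c
    df = pd.DataFrame({"count": pd.Series(rows)})
    df["has_match"] = df["count"] >= 1
    return df


def fraction_with_match(counts: pd.DataFrame) -> int:
    """Percentage of genes with at least one match, rounded to nearest integer."""
    frac = counts["has_match"].mean()
    return int(round(100 * frac))


# ---------------------------------------------------------------------------
# Stand-in matrices.  The published alignment matrices are not reproduced
# here; these synthetic position-frequency tables encode the canonical
# consensus of each factor (Su(H)/CSL: CGTGGGAA; Hairy class-C box: CACGCG)
# with mild degeneracy, and exist so the scanner and the synthetic genome
# have concrete matrices to work with.

_SUH_SYNTHETIC_COUNTS = """\
A\tC\tG\tT
2\t14\t1\t3
1\t1\t17\t1
1\t1\t1\t17
1\t1\t17\t1
1\t1\t17\t1
1\t1\t17\t1
16\t1\t2\t1
16\t1\t2\t1
"""

_HAIRY_SYNTHETIC_COUNTS = """\
A\tC\tG\tT
1\t16\t2\t1
16\t1\t2\t1
1\t16\t2\t1
1\t1\t17\t1
1\t16\t2\t1
1\t1\t17\t1
"""


def suh_matrix(**kwargs) -> WeightMatrix:
    """Synthetic stand-in Su(H)/CSL weight matrix (consensus CGTGGGAA)."""
    return WeightMatrix.from_tsv(io.StringIO(_SUH_SYNTHETIC_COUNTS), name="SuH", **kwargs)


def hairy_matrix(**kwargs) -> WeightMatrix:
    """Synthetic stand-in Hairy weight matrix (consensus CACGCG)."""
    return WeightMatrix.from_tsv(io.StringIO(_HAIRY_SYNTHETIC_COUNTS), name="Hairy", **kwargs)
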