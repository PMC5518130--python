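"""Promoter PWM scanning and miRNA seed-match site prediction.

The PWM scorer is a transparent surrogate for commercial matrix scanners:
per-window log-odds against a background distribution, min-max normalized to
``[0, 1]`` using the matrix's own attainable extremes, with a default hit
threshold of 0.85.  Windows containing ``N`` score minus infinity and can
never be hits.

Seed matching follows the canonical site hierarchy.  With mature miRNA
positions numbered 1..n from the 5' end, the transcript-side site strings
(read 5'->3') are::

    6mer     = revcomp(positions 2-7)
    7mer-A1  = revcomp(positions 2-7) + "A"
    7mer-m8  = revcomp(positions 2-8)
    8mer     = revcomp(positions 2-8) + "A"

Each transcript offset reports at most one site per miRNA, typed by the
strongest match (8mer > 7mer-m8 > 7mer-A1 > 6mer).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np

from .errors import FormatError, InputError
from .formats_io import reverse_complement

ALPHABET = "ACGT"
SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")

__all__ = [
    "PWM",
    "MotifHit",
    "MiRNA",
    "SeedSite",
    "build_pwm",
    "pwm_scan",
    "seed_scan",
    "read_pwm",
    "write_pwm",
    "read_mirnas",
    "write_mirnas",
    "cebpa_example_sites",
    "cebpa_example_pwm",
    "SITE_TYPES",
]

_IDX = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(ALPHABET):
    _IDX[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    """DNA string -> indices 0..3; N (or anything else) -> -1."""
    return _IDX[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


class PWM:
    """Position probability matrix over (A, C, G, T) with a background model."""

    def __init__(self, matrix: np.ndarray, background: Optional[Sequence[float]] = None,
                 name: str = "motif"):
        matrix = np.asarray(matrix, dtype=float)
        if matrix.ndim != 2 or matrix.shape[0] != 4:
            raise InputError("PWM matrix must be 4 x L")
        if matrix.shape[1] < 1:
            raise InputError("PWM must have at least one position")
        sums = matrix.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise InputError("PWM columns must each sum to 1 (within 1e-9)")
        if np.any(matrix < 0):
            raise InputError("PWM probabilities must be non-negative")
        bg = np.asarray(
            background if background is not None else [0.25] * 4, dtype=float
        )
        if bg.shape != (4,) or abs(bg.sum() - 1.0) > 1e-9 or np.any(bg <= 0):
            raise InputError("background must be a positive distribution over ACGT")
        self.matrix = matrix
        self.background = bg
        self.name = name

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=0))

    def log_odds(self) -> np.ndarray:
        """log(p/q) per (base, position); zero probabilities map to -inf."""
        with np.errstate(divide="ignore"):
            return np.log(self.matrix) - np.log(self.background)[:, None]

    def score_range(self) -> tuple:
        lo = self.log_odds()
        return float(lo.min(axis=0).sum()), float(lo.max(axis=0).sum())


@dataclass(frozen=True)
class MotifHit:
    """One PWM hit on a promoter string (offset 0-based on that string)."""

    offset: int
    strand: str
    score: float
    promoter_id: str = ""


def build_pwm(
    sites: Sequence[str],
    pseudocount: float = 0.5,
    background: Optional[Sequence[float]] = None,
    name: str = "motif",
) -> PWM:
    """PWM from aligned equal-length binding sites.

    p(b, j) = (count(b, j) + pseudocount) / (n + 4 * pseudocount).
    """
    if len(sites) < 2:
        raise InputError("need at least 2 aligned sites to build a PWM")
    lengths = {len(s) for s in sites}
    if len(lengths) != 1:
        raise InputError(f"aligned sites have ragged lengths {sorted(lengths)}")
    L = lengths.pop()
    if pseudocount < 0:
        raise InputError("pseudocount must be >= 0")
    counts = np.zeros((4, L))
    for s in sites:
        idx = _encode(s)
        if np.any(idx < 0):
            raise InputError(f"site {s!r} contains non-ACGT characters")
        counts[idx, np.arange(L)] += 1
    matrix = (counts + pseudocount) / (len(sites) + 4 * pseudocount)
    return PWM(matrix, background=background, name=name)


def pwm_scan(
    seq: str,
    pwm: PWM,
    threshold: float = 0.85,
    both_strands: bool = True,
    promoter_id: str = "",
) -> List[MotifHit]:
    """All PWM hits on a sequence at or above a normalized-score threshold.

    The raw window score S = sum_j log(p(b_j, j)/q(b_j)) is normalized to
    (S - S_min)/(S_max - S_min) where S_min/S_max are the matrix's attainable
    extremes, so the consensus scores exactly 1.  Hits are sorted by offset
    ('+' before '-' at equal offsets).  A sequence shorter than the matrix
    yields an empty list.
    """
    if not (0.0 <= threshold <= 1.0):
        raise InputError("threshold must lie in [0, 1]")
    L = pwm.length
    n = len(seq)
    if n < L:
        return []
    lo = pwm.log_odds()
    if not np.all(np.isfinite(lo)):
        raise InputError(
            "PWM contains zero probabilities; rebuild with a positive pseudocount"
        )
    smin, smax = pwm.score_range()
    if smax <= smin:
        raise InputError("degenerate PWM: uniform score range")

    idx = _encode(seq)
    windows = np.lib.stride_tricks.sliding_window_view(idx, L)
    valid = (windows >= 0).all(axis=1)
    cols = np.arange(L)
    safe = np.where(windows >= 0, windows, 0)

    def norm_scores(matrix: np.ndarray) -> np.ndarray:
        raw = matrix[safe, cols].sum(axis=1)
        raw = np.where(valid, raw, -np.inf)
        return (raw - smin) / (smax - smin)

    hits: List[MotifHit] = []
    fwd = norm_scores(lo)
    strands_scores = [("+", fwd)]
    if both_strands:
        # scanning the reverse complement of each window == scanning forward
        # with the base-complemented, position-reversed matrix
        lo_rc = lo[::-1, ::-1]
        strands_scores.append(("-", norm_scores(lo_rc)))
    for strand, scores in strands_scores:
        for off in np.nonzero(scores >= threshold)[0]:
            hits.append(
                MotifHit(int(off), strand, float(scores[off]), promoter_id)
            )
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


# ---------------------------------------------------------------------------
# miRNA seed matching


@dataclass(frozen=True)
class MiRNA:
    """A mature miRNA: name and 5'->3' mature sequence (RNA or DNA alphabet)."""

    name: str
    mature: str

    def __post_init__(self):
        norm = self.mature.upper().replace("U", "T")
        if len(norm) < 8:
            raise InputError(f"{self.name}: mature sequence shorter than 8 nt")
        if set(norm) - set("ACGTN"):
            raise InputError(f"{self.name}: non-nucleotide characters in mature seq")
        object.__setattr__(self, "mature", norm)

    @property
    def seed(self) -> str:
        """Nucleotides 2-8 of the mature sequence (DNA alphabet)."""
        return self.mature[1:8]

    def site_strings(self) -> Dict[str, str]:
        """Transcript-side (5'->3') match strings for the four site types."""
        rc_2_8 = reverse_complement(self.mature[1:8])
        rc_2_7 = reverse_complement(self.mature[1:7])
        return {
            "8mer": rc_2_8 + "A",
            "7mer-m8": rc_2_8,
            "7mer-A1": rc_2_7 + "A",
            "6mer": rc_2_7,
        }


@dataclass(frozen=True)
class SeedSite:
    """One seed-match site on a transcript."""

    mirna: str
    offset: int
    site_type: str
    transcript_id: str = ""


def seed_scan(
    transcript_seq: str, mirnas: Iterable[MiRNA], transcript_id: str = ""
) -> List[SeedSite]:
    """Canonical seed-match sites of each miRNA on a transcript sequence.

    Each offset is reported once per miRNA with its strongest site type.
    Ordered by (miRNA order given, offset).
    """
    seq = transcript_seq.upper().replace("U", "T")
    n = len(seq)
    out: List[SeedSite] = []
    for mir in mirnas:
        sites = mir.site_strings()
        for off in range(n - 5):
            if seq[off : off + 8] == sites["8mer"]:
                stype = "8mer"
            elif seq[off : off + 7] == sites["7mer-m8"]:
                stype = "7mer-m8"
            elif seq[off : off + 7] == sites["7mer-A1"]:
                stype = "7mer-A1"
            elif seq[off : off + 6] == sites["6mer"]:
                stype = "6mer"
            else:
                continue
            out.append(SeedSite(mir.name, off, stype, transcript_id))
    return out


# ---------------------------------------------------------------------------
# text formats


def write_pwm(pwm: PWM, path) -> None:
    """One header line, then L whitespace-separated probability rows (A C G T)."""
    with open(path, "w") as fh:
        fh.write(f">{pwm.name} alphabet=ACGT background="
                 f"{' '.join(repr(float(b)) for b in pwm.background)}\n")
        for j in range(pwm.length):
            fh.write(" ".join(repr(float(v)) for v in pwm.matrix[:, j]) + "\n")


def read_pwm(path) -> PWM:
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines or not lines[0].startswith(">"):
        raise FormatError(f"{path}: line 1: PWM file must start with a '>' header")
    header = lines[0][1:].split()
    name = header[0] if header else "motif"
    background = None
    # background values follow "background=" and are whitespace-separated
    if "background=" in lines[0]:
        tail = lines[0].split("background=", 1)[1].split()
        background = [float(v) for v in tail[:4]]
    rows = []
    for i, ln in enumerate(lines[1:], start=2):
        parts = ln.split()
        if len(parts) != 4:
            raise FormatError(f"{path}: line {i}: expected 4 probabilities")
        rows.append([float(p) for p in parts])
    matrix = np.array(rows).T
    return PWM(matrix, background=background, name=name)


def write_mirnas(mirnas: Iterable[MiRNA], path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tmature_sequence\n")
        for m in mirnas:
            fh.write(f"{m.name}\t{m.mature}\n")


def read_mirnas(path) -> List[MiRNA]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}: line {lineno}: expected name<TAB>sequence")
            out.append(MiRNA(parts[0], parts[1]))
    return out


def cebpa_example_sites() -> List[str]:
    """Illustrative aligned C/EBPalpha-like binding sites (TTGCGCAA family).

    Synthetic example alignment for fixtures and demonstrations: variations
    around the palindromic CCAAT/enhancer-binding consensus, not a curated
    matrix from any database.
    """
    return [
        "TTGCGCAA",
        "TTGCGCAA",
        "TTGCGCAA",
        "TGGCGCAA",
        "TTGCGTAA",
        "ATGCGCAA",
        "TTGCACAA",
        "CTGCGCAA",
        "TTGCGCAT",
        "TTACGCAA",
    ]


def cebpa_example_pwm(pseudocount: float = 0.5) -> PWM:
    """PWM built from :func:`cebpa_example_sites` (consensus TTGCGCAA)."""
    return build_pwm(cebpa_example_sites(), pseudocount=pseudocount, name="CEBPA_like")
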