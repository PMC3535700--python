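"""Position-weight-matrix scanning and per-bin score pooling.

Motif count matrices (JASPAR flat-file format) are converted to log2-odds
matrices against a background base composition with a per-cell pseudocount,
scanned over both strands of the genome, and pooled to the per-bin maximum —
which becomes row 1 of the feature matrix.

Scoring conventions:

* ``log_odds[b, w] = log2((counts[b, w] + pc) / (col_total + 4 pc)) - log2(bg[b])``
  with pseudocount ``pc = 0.01`` and a uniform background by default;
* the score at position ``p`` is the strand-maximum of the additive log-odds
  of the W-mer *starting* at ``p`` (motifs may overhang the right bin edge);
* positions whose W-mer contains ``N`` and the last ``W - 1`` positions of a
  chromosome carry a ``-inf`` sentinel; a bin with no scorable position is
  floored to the chromosome-wide minimum finite score so no infinities reach
  the CRF.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .genome_prep import BinnedChromosome

SENTINEL = -np.inf
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
DEFAULT_PSEUDOCOUNT = 0.01


class JasparParseError(ValueError):
    """Malformed JASPAR flat file (message carries the offending line)."""


def to_log_odds(
    counts: np.ndarray,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    background: Sequence[float] | None = None,
) -> np.ndarray:
    """Convert a 4xW count matrix to log2 odds against ``background``."""
    counts = np.asarray(counts, dtype=np.float64)
    if counts.ndim != 2 or counts.shape[0] != 4:
        raise ValueError("counts must be a 4xW matrix (rows A, C, G, T)")
    if counts.shape[1] < 1:
        raise ValueError("motif width must be >= 1")
    if (counts < 0).any():
        raise ValueError("negative motif counts")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if background is None:
        background = np.full(4, 0.25)
    background = np.asarray(background, dtype=np.float64)
    if background.shape != (4,) or (background <= 0).any():
        raise ValueError("background must be 4 positive frequencies")
    if not np.isclose(background.sum(), 1.0):
        raise ValueError("background frequencies must sum to 1")
    totals = counts.sum(axis=0) + 4 * pseudocount
    probs = (counts + pseudocount) / totals
    return np.log2(probs) - np.log2(background)[:, None]


@dataclasses.dataclass
class MotifMatrix:
    """A motif: nucleotide counts plus the derived log2-odds scoring matrix."""

    name: str
    counts: np.ndarray
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        self.log_odds = to_log_odds(self.counts, self.pseudocount, self.background)

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "counts": self.counts.tolist(),
            "pseudocount": self.pseudocount,
            "background": list(self.background),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MotifMatrix":
        return cls(
            d["name"],
            np.asarray(d["counts"]),
            d.get("pseudocount", DEFAULT_PSEUDOCOUNT),
            tuple(d.get("background", (0.25, 0.25, 0.25, 0.25))),
        )


def read_jaspar(path) -> list[MotifMatrix]:
    """Read motifs from a JASPAR flat file.

    Expected layout per motif: a ``>ID NAME`` header followed by four rows
    ``A [ 4 0 ... ]`` (order A, C, G, T; brackets optional).  Order of motifs
    in the file is preserved.
    """
    motifs: list[MotifMatrix] = []
    header: str | None = None
    rows: list[np.ndarray] = []
    bases_seen: list[str] = []

    def flush(lineno: int) -> None:
        nonlocal header, rows, bases_seen
        if header is None:
            return
        if len(rows) != 4 or bases_seen != ["A", "C", "G", "T"]:
            raise JasparParseError(
                f"{path}:{lineno}: motif {header!r} has rows {bases_seen} "
                "(need exactly A, C, G, T)"
            )
        widths = {r.size for r in rows}
        if len(widths) != 1:
            raise JasparParseError(
                f"{path}:{lineno}: motif {header!r} rows have unequal widths"
            )
        motifs.append(MotifMatrix(header, np.vstack(rows)))
        header, rows, bases_seen = None, [], []

    lineno = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(lineno)
                header = line[1:].strip() or f"motif_{len(motifs) + 1}"
            else:
                if header is None:
                    raise JasparParseError(
                        f"{path}:{lineno}: count row before any '>' header"
                    )
                base, _, rest = line.partition(" ")
                base = base.upper()
                if base not in "ACGT" or len(base) != 1:
                    raise JasparParseError(
                        f"{path}:{lineno}: expected a nucleotide row, got {line!r}"
                    )
                rest = rest.replace("[", " ").replace("]", " ")
                try:
                    vals = np.array(rest.split(), dtype=np.float64)
                except ValueError:
                    raise JasparParseError(
                        f"{path}:{lineno}: non-numeric count in {line!r}"
                    ) from None
                if vals.size == 0:
                    raise JasparParseError(f"{path}:{lineno}: empty count row")
                rows.append(vals)
                bases_seen.append(base)
    flush(lineno + 1)
    return motifs


def _encode(sequence: str) -> np.ndarray:
    """Map a DNA string (case-insensitive; non-ACGT treated as N) to 0..4."""
    table = np.full(256, 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        table[ord(base)] = idx
        table[ord(base.lower())] = idx
    return table[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def _strand_scores(codes: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """Additive scores of W-mers starting at each position for one strand."""
    n, w = codes.size, lo.shape[1]
    out = np.full(n, SENTINEL)
    if n < w:
        return out
    # pad the lookup with a -inf row for N so any N-containing W-mer sinks
    lut = np.vstack([lo, np.full((1, w), -np.inf)])
    acc = np.zeros(n - w + 1)
    for offset in range(w):
        acc = acc + lut[codes[offset : offset + n - w + 1], offset]
    out[: n - w + 1] = acc
    return out


def scan_chromosome(sequence: str, motif: MotifMatrix) -> np.ndarray:
    """Strand-max per-position PWM scores over a chromosome.

    Returns one score per sequence position (the W-mer starting there);
    unscorable positions hold the ``-inf`` sentinel.
    """
    codes = _encode(sequence)
    fwd = _strand_scores(codes, motif.log_odds)
    # reverse-complement motif: complement rows (A<->T, C<->G), reverse columns
    rc = motif.log_odds[::-1, ::-1]
    rev = _strand_scores(codes, rc)
    with np.errstate(invalid="ignore"):
        return np.maximum(fwd, rev)


def max_score_per_bin(
    scores: np.ndarray, bins: BinnedChromosome, floor: float | None = None
) -> np.ndarray:
    """Pool per-position scores to the per-bin maximum (row 1 of the matrix).

    A bin whose positions are all sentinel receives ``floor`` (default: the
    chromosome-wide minimum finite score, or 0 if none exists).
    """
    scores = np.asarray(scores, dtype=np.float64)
    if scores.size != bins.chrom_length:
        raise ValueError(
            f"scores length {scores.size} != chromosome length {bins.chrom_length}"
        )
    out = np.empty(bins.n_bins)
    for j in range(bins.n_bins):
        start, end = bins.bin_span(j)
        out[j] = scores[start:end].max()
    if floor is None:
        finite = scores[np.isfinite(scores)]
        floor = float(finite.min()) if finite.size else 0.0
    return np.where(np.isfinite(out), out, floor)


def read_fasta(path) -> dict[str, str]:
    """Read all sequences from a FASTA file via an indexed reader."""
    from pyfaidx import Fasta

    with Fasta(str(path), as_raw=True, sequence_always_upper=True) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}
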