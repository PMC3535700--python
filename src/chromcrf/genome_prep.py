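"""Genome binning and per-bin feature construction.

The model operates on a genome tiled into fixed-width bins (200 bp by
default).  This module turns the raw annotation inputs — chromosome sizes,
peak calls in BED, transcription start sites — into the two per-chromosome
objects the CRF consumes:

* a :class:`LabelSequence` of 0/1 bin labels, positive where a binding-site
  peak *center* falls inside the bin ("peak-centric" labelling), and
* binary feature rows: 1 where a bin overlaps a histone-modification peak,
  or lies within the promoter window (default ±2000 bp) around a TSS.

All coordinates are 0-based half-open, as in BED.  A position ``p`` belongs
to bin ``p // bin_size``; bins tile the chromosome exactly and only the last
bin may be short.
"""

from __future__ import annotations

import dataclasses
import gzip
import json
import math
from typing import Iterable, Mapping, Sequence

import numpy as np

DEFAULT_BIN_SIZE = 200
DEFAULT_PROMOTER_HALF_WIDTH = 2000
PWM_ROW_NAME = "PWM"


@dataclasses.dataclass(frozen=True)
class BinnedChromosome:
    """A chromosome tiled into fixed-width bins (0-based half-open spans)."""

    chrom_name: str
    chrom_length: int
    bin_size: int = DEFAULT_BIN_SIZE

    def __post_init__(self) -> None:
        if self.chrom_length <= 0:
            raise ValueError(
                f"chromosome {self.chrom_name!r} has non-positive length "
                f"{self.chrom_length}"
            )
        if self.bin_size <= 0:
            raise ValueError(
                f"chromosome {self.chrom_name!r}: non-positive bin size {self.bin_size}"
            )

    @property
    def n_bins(self) -> int:
        return -(-self.chrom_length // self.bin_size)

    def bin_span(self, j: int) -> tuple[int, int]:
        """Half-open genomic span ``[start, end)`` of bin ``j``."""
        if not 0 <= j < self.n_bins:
            raise IndexError(f"bin {j} out of range for {self.chrom_name}")
        start = j * self.bin_size
        return start, min(start + self.bin_size, self.chrom_length)

    def bin_of(self, position: int) -> int:
        """Index of the bin containing ``position`` (half-open membership)."""
        if not 0 <= position < self.chrom_length:
            raise ValueError(
                f"position {position} outside {self.chrom_name} "
                f"[0, {self.chrom_length})"
            )
        return position // self.bin_size

    def bin_starts(self) -> np.ndarray:
        return np.arange(self.n_bins, dtype=np.int64) * self.bin_size

    def bin_ends(self) -> np.ndarray:
        return np.minimum(self.bin_starts() + self.bin_size, self.chrom_length)


@dataclasses.dataclass(frozen=True)
class Interval:
    """A 0-based half-open genomic interval (carrier for BED records)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"interval start {self.start} < 0 on {self.chrom}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval [{self.start}, {self.end}) on {self.chrom}"
            )

    @property
    def center(self) -> int:
        # floor((start + end) / 2); a center on a bin boundary belongs to the
        # right-hand bin via half-open membership.
        return (self.start + self.end) // 2


@dataclasses.dataclass
class LabelSequence:
    """Per-bin 0/1 annotation of one chromosome (1 = binding site)."""

    chrom_name: str
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.ndim != 1:
            raise ValueError("labels must be a 1-D vector")
        bad = ~np.isin(self.labels, (0, 1))
        if bad.any():
            raise ValueError(
                f"labels on {self.chrom_name} contain values other than 0/1"
            )

    def __len__(self) -> int:
        return self.labels.size


@dataclasses.dataclass
class FeatureMatrix:
    """Per-chromosome observation matrix: rows = features, columns = bins.

    Row 1 (``values[0]``) is the real-valued per-bin max PWM score; every
    other row is binary (peak overlap / promoter membership).  Row indices
    quoted elsewhere (feature templates) are 1-based to match this "row 1 is
    PWM" convention.
    """

    bins: BinnedChromosome
    values: np.ndarray
    row_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.row_names = tuple(self.row_names)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if self.values.shape[0] != len(self.row_names):
            raise ValueError("row_names length does not match matrix rows")
        if self.values.shape[1] != self.bins.n_bins:
            raise ValueError(
                f"matrix has {self.values.shape[1]} columns but "
                f"{self.bins.chrom_name} has {self.bins.n_bins} bins"
            )
        if len(set(self.row_names)) != len(self.row_names):
            raise ValueError("duplicate feature row names")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def chrom_name(self) -> str:
        return self.bins.chrom_name

    def row_index(self, name: str) -> int:
        """1-based index of a named row (row 1 = PWM)."""
        try:
            return self.row_names.index(name) + 1
        except ValueError:
            raise KeyError(f"no feature row named {name!r}") from None

    def row(self, name: str) -> np.ndarray:
        return self.values[self.row_index(name) - 1]

    def select_rows(self, names: Sequence[str]) -> "FeatureMatrix":
        """Sub-matrix restricted to ``names``; the PWM row must stay first."""
        if not names or names[0] != self.row_names[0]:
            raise ValueError(
                f"row selection must start with the PWM row {self.row_names[0]!r}"
            )
        idx = [self.row_index(n) - 1 for n in names]
        return FeatureMatrix(self.bins, self.values[idx], tuple(names))


# ---------------------------------------------------------------------------
# Binning and labelling operations


def make_bins(
    chrom_sizes: Mapping[str, int], bin_size: int = DEFAULT_BIN_SIZE
) -> list[BinnedChromosome]:
    """Tile every chromosome into ``bin_size`` bins (last bin may be short)."""
    return [
        BinnedChromosome(name, length, bin_size)
        for name, length in chrom_sizes.items()
    ]


def _check_chrom(bins: BinnedChromosome, intervals: Iterable[Interval]) -> None:
    for iv in intervals:
        if iv.chrom != bins.chrom_name:
            raise ValueError(
                f"interval on {iv.chrom!r} passed with bins for {bins.chrom_name!r}"
            )


def label_bins_peak_centric(
    bins: BinnedChromosome, peaks: Sequence[Interval]
) -> LabelSequence:
    """Peak-centric gold standard: bin j is positive iff a peak center is in it."""
    _check_chrom(bins, peaks)
    labels = np.zeros(bins.n_bins, dtype=np.int8)
    for peak in peaks:
        c = peak.center
        if c >= bins.chrom_length:
            raise ValueError(
                f"peak center {c} beyond end of {bins.chrom_name} "
                f"({bins.chrom_length})"
            )
        labels[bins.bin_of(c)] = 1
    return LabelSequence(bins.chrom_name, labels)


def binarize_peak_overlap(
    bins: BinnedChromosome, peaks: Sequence[Interval]
) -> np.ndarray:
    """Binary row: element j is 1 iff bin j intersects any peak interval."""
    _check_chrom(bins, peaks)
    out = np.zeros(bins.n_bins, dtype=np.int8)
    for peak in peaks:
        start = peak.start
        end = min(peak.end, bins.chrom_length)
        if start >= end:  # peak entirely beyond the chromosome end
            continue
        j0 = start // bins.bin_size
        j1 = (end - 1) // bins.bin_size
        out[j0 : j1 + 1] = 1
    return out


def tss_proximity(
    bins: BinnedChromosome,
    tss_positions: Sequence[int],
    promoter_half_width: int = DEFAULT_PROMOTER_HALF_WIDTH,
) -> np.ndarray:
    """Binary row: bin overlaps the promoter window around any TSS.

    The promoter is the ``2 * promoter_half_width`` bp interval centred at
    the TSS (default 4000 bp), clipped at chromosome ends, not strand-aware.
    """
    windows = []
    for t in tss_positions:
        if not 0 <= t < bins.chrom_length:
            raise ValueError(
                f"TSS {t} outside {bins.chrom_name} [0, {bins.chrom_length})"
            )
        start = max(0, t - promoter_half_width)
        end = min(bins.chrom_length, t + promoter_half_width)
        if start < end:
            windows.append(Interval(bins.chrom_name, start, end))
    return binarize_peak_overlap(bins, windows)


def assemble_feature_matrix(
    bins: BinnedChromosome,
    pwm_row: np.ndarray,
    binary_rows: Mapping[str, np.ndarray],
    pwm_name: str = PWM_ROW_NAME,
) -> FeatureMatrix:
    """Stack the PWM row (row 1) and the named binary rows into a matrix."""
    pwm_row = np.asarray(pwm_row, dtype=np.float64)
    if pwm_row.shape != (bins.n_bins,):
        raise ValueError(
            f"row {pwm_name!r}: expected length {bins.n_bins}, got {pwm_row.shape}"
        )
    rows = [pwm_row]
    names = [pwm_name]
    for name, vec in binary_rows.items():
        vec = np.asarray(vec)
        if vec.shape != (bins.n_bins,):
            raise ValueError(
                f"row {name!r}: expected length {bins.n_bins}, got {vec.shape}"
            )
        if not np.isin(vec, (0, 1)).all():
            raise ValueError(f"row {name!r} is not binary")
        rows.append(vec.astype(np.float64))
        names.append(name)
    return FeatureMatrix(bins, np.vstack(rows), tuple(names))


# ---------------------------------------------------------------------------
# I/O: chrom.sizes, BED, TSS tables, feature-matrix tables


def read_chrom_sizes(path) -> dict[str, int]:
    """Read a two-column ``chrom<TAB>length`` file."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'chrom length'")
            try:
                sizes[parts[0]] = int(parts[1])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-integer length {parts[1]!r}"
                ) from None
    return sizes


def read_bed(path, with_scores: bool = False):
    """Read BED3+ records.

    Returns a list of :class:`Interval`, or ``(Interval, score)`` pairs when
    ``with_scores`` is true (score taken from BED column 5).
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected at least 3 BED columns")
            try:
                iv = Interval(parts[0], int(parts[1]), int(parts[2]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if with_scores:
                if len(parts) < 5:
                    raise ValueError(f"{path}:{lineno}: no score column (BED5 needed)")
                out.append((iv, float(parts[4])))
            else:
                out.append(iv)
    return out


def read_tss_table(
    path,
    chrom_col: int = 0,
    pos_col: int = 1,
    one_based: bool = False,
) -> dict[str, list[int]]:
    """Read TSS positions from a tab-separated table with a configurable
    column mapping (covers both BED and refGene-like layouts).

    ``one_based=True`` converts 1-based coordinates to the internal 0-based
    convention on read.
    """
    tss: dict[str, list[int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            try:
                chrom = parts[chrom_col]
                pos = int(parts[pos_col]) - (1 if one_based else 0)
            except (IndexError, ValueError):
                raise ValueError(
                    f"{path}:{lineno}: cannot read chrom/position from columns "
                    f"{chrom_col}/{pos_col}"
                ) from None
            tss.setdefault(chrom, []).append(pos)
    return tss


def write_labels_bed(
    labels: LabelSequence, bins: BinnedChromosome, path, append: bool = False
) -> None:
    """One BED record per positive bin."""
    with open(path, "a" if append else "w") as fh:
        for j in np.flatnonzero(labels.labels):
            start, end = bins.bin_span(int(j))
            fh.write(f"{bins.chrom_name}\t{start}\t{end}\n")


def read_labels_bed(bins: BinnedChromosome, path) -> LabelSequence:
    """Re-label bins from a labels BED (inverse of :func:`write_labels_bed`)."""
    peaks = [iv for iv in read_bed(path) if iv.chrom == bins.chrom_name]
    return label_bins_peak_centric(bins, peaks)


def write_feature_matrix(matrix: FeatureMatrix, path) -> None:
    """Write the matrix as a gzipped TSV (rows = features, columns = bins)
    with a JSON sidecar (``<path>.json``) of row names and bin coordinates."""
    path = str(path)
    with gzip.open(path, "wt") as fh:
        for name, row in zip(matrix.row_names, matrix.values):
            fh.write(name + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    sidecar = {
        "chrom_name": matrix.bins.chrom_name,
        "chrom_length": matrix.bins.chrom_length,
        "bin_size": matrix.bins.bin_size,
        "row_names": list(matrix.row_names),
    }
    with open(path + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)


def read_feature_matrix(path) -> FeatureMatrix:
    path = str(path)
    with open(path + ".json") as fh:
        meta = json.load(fh)
    bins = BinnedChromosome(meta["chrom_name"], meta["chrom_length"], meta["bin_size"])
    names, rows = [], []
    with gzip.open(path, "rt") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            names.append(parts[0])
            rows.append(np.array(parts[1:], dtype=np.float64))
    if names != meta["row_names"]:
        raise ValueError(f"{path}: row names disagree with sidecar")
    return FeatureMatrix(bins, np.vstack(rows), tuple(names))
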