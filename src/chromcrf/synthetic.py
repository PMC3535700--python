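"""Synthetic multi-chromosome benchmark data.

Generates small genomes with the statistical structure the binding-site CRF
assumes, so training, prediction, feature ablation and cross-validation are
exercisable without any downloads:

* background sequence i.i.d. uniform over ACGT, with motif instances sampled
  from the motif's column distributions planted at non-overlapping positions
  (a configurable fraction inside promoter windows around generated TSSs,
  emulating the promoter enrichment of some factors' sites);
* a "binding-site peak" interval of configurable width centred on each
  instance (peak centers define the gold-standard bin labels);
* binary histone-mark tracks whose per-bin occurrence rates differ between
  site-containing and background bins — the marks differ in how separated
  the two rates are, mirroring the observation that H3K4me2/3 discriminate
  binding sites best while marks like H3K9me3 carry little signal — with one
  designated pair additionally co-occurring in site bins (bivalent-like);
  "on" bins are merged into BED-style peak intervals;
* TSS positions, which also feed the TSS-proximity feature row.

Everything is reproducible from the config seed.
"""

from __future__ import annotations

import dataclasses
import os
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import crf_core, evaluation, pwm_scan
from .feature_templates import FeatureSet, build_default_feature_set
from .genome_prep import (
    BinnedChromosome,
    FeatureMatrix,
    Interval,
    LabelSequence,
    assemble_feature_matrix,
    binarize_peak_overlap,
    label_bins_peak_centric,
    make_bins,
    tss_proximity,
    write_labels_bed,
)
from .pwm_scan import MotifMatrix

#: Default planted motif: 10 columns, counts out of 100, mixing strongly and
#: weakly constrained positions the way real factor motifs do.
_DEFAULT_MOTIF_COUNTS = np.array(
    [
        # A    C    G    T  per column (transposed below)
        [85, 5, 5, 5],
        [5, 85, 5, 5],
        [55, 25, 10, 10],
        [5, 5, 85, 5],
        [40, 30, 20, 10],
        [10, 55, 10, 25],
        [5, 5, 5, 85],
        [25, 10, 55, 10],
        [85, 5, 5, 5],
        [30, 40, 20, 10],
    ]
).T

#: Marker occurrence rates (p_on_given_site_bin, p_on_given_background_bin),
#: ordered from most to least discriminative, echoing the known ordering of
#: histone marks around binding sites (H3K4me2/3 strongest, H3K4me1 weaker,
#: repressive/background marks near-uninformative).
DEFAULT_MARKER_RATES: dict[str, tuple[float, float]] = {
    "H3K4me2": (0.45, 0.12),
    "H3K4me3": (0.44, 0.12),
    "H3K4me1": (0.42, 0.14),
    "H3K27me3": (0.25, 0.10),
    "H3K36me3": (0.25, 0.20),
    "H3K9me3": (0.08, 0.10),
    "H3": (0.50, 0.45),
    "H4K20me3": (0.05, 0.06),
}

TSS_ROW_NAME = "TSS"


def default_motif() -> MotifMatrix:
    return MotifMatrix("synthetic_tf", _DEFAULT_MOTIF_COUNTS)


@dataclasses.dataclass
class SyntheticConfig:
    """Study conditions for one generated dataset."""

    n_chroms: int = 4
    chrom_length: int = 200_000
    bin_size: int = 200
    motif: MotifMatrix = dataclasses.field(default_factory=default_motif)
    n_sites_per_chrom: int = 50
    marker_rates: Mapping[str, tuple[float, float]] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_MARKER_RATES)
    )
    cooccurrence_pair: tuple[str, str] = ("H3K4me3", "H3K27me3")
    cooccurrence_boost: float = 0.20
    tss_enrichment: float = 0.30
    n_tss_per_chrom: int = 10
    promoter_half_width: int = 2000
    site_peak_width: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for name, (p1, p0) in self.marker_rates.items():
            if not (0 <= p1 <= 1 and 0 <= p0 <= 1):
                raise ValueError(f"marker {name!r}: rates must lie in [0, 1]")
        if not 0 <= self.tss_enrichment <= 1:
            raise ValueError("tss_enrichment must lie in [0, 1]")
        if not 0 <= self.cooccurrence_boost <= 1:
            raise ValueError("cooccurrence_boost must lie in [0, 1]")
        if self.n_sites_per_chrom * self.bin_size > 0.5 * self.chrom_length:
            raise ValueError("sites are not sparse relative to the chromosome")

    @classmethod
    def benchmark(cls, seed: int = 0) -> "SyntheticConfig":
        """Benchmark variant sized for 10-fold chromosome-holdout CV:
        20 chromosomes (two per fold) so fold-level AUC estimates are stable
        enough to resolve the feature-ablation ordering."""
        return cls(
            n_chroms=20,
            chrom_length=150_000,
            n_sites_per_chrom=40,
            n_tss_per_chrom=8,
            seed=seed,
        )


@dataclasses.dataclass
class SyntheticDataset:
    """One generated genome with its annotations and ground truth."""

    config: SyntheticConfig
    sequences: dict[str, str]
    chrom_sizes: dict[str, int]
    site_peaks: list[Interval]
    marker_peaks: dict[str, list[Interval]]
    tss: dict[str, list[int]]
    labels: dict[str, LabelSequence]

    @property
    def bins(self) -> list[BinnedChromosome]:
        return make_bins(self.chrom_sizes, self.config.bin_size)


def _plant_sites(
    rng: np.random.Generator,
    chrom: str,
    length: int,
    motif: MotifMatrix,
    n_sites: int,
    tss_positions: Sequence[int],
    tss_enrichment: float,
    promoter_half_width: int,
    max_retries: int = 200,
) -> list[int]:
    """Choose non-overlapping motif start positions; a ``tss_enrichment``
    fraction falls inside promoter windows."""
    w = motif.width
    taken: list[tuple[int, int]] = []
    starts: list[int] = []
    n_promoter = int(round(tss_enrichment * n_sites)) if tss_positions else 0
    for site_idx in range(n_sites):
        in_promoter = site_idx < n_promoter
        for attempt in range(max_retries):
            if in_promoter:
                t = int(tss_positions[rng.integers(len(tss_positions))])
                lo = max(0, t - promoter_half_width)
                hi = min(length - w, t + promoter_half_width - w)
                if hi < lo:
                    continue
                start = int(rng.integers(lo, hi + 1))
            else:
                start = int(rng.integers(0, length - w + 1))
            if all(start + w <= s or start >= e for s, e in taken):
                taken.append((start, start + w))
                starts.append(start)
                break
        else:
            raise RuntimeError(
                f"could not place site {site_idx} on {chrom} after "
                f"{max_retries} retries"
            )
    return sorted(starts)


def _merge_on_bins(
    chrom: str, on: np.ndarray, bins: BinnedChromosome
) -> list[Interval]:
    """Merge runs of consecutive 'on' bins into peak intervals."""
    out: list[Interval] = []
    idx = np.flatnonzero(on)
    if idx.size == 0:
        return out
    run_start = idx[0]
    prev = idx[0]
    for j in list(idx[1:]) + [None]:
        if j is not None and j == prev + 1:
            prev = j
            continue
        start, _ = bins.bin_span(int(run_start))
        _, end = bins.bin_span(int(prev))
        out.append(Interval(chrom, start, end))
        if j is not None:
            run_start = prev = j
    return out


def generate_dataset(cfg: SyntheticConfig) -> SyntheticDataset:
    """Generate one dataset; byte-identical across runs for a fixed seed."""
    rng = np.random.default_rng(cfg.seed)
    motif = cfg.motif
    col_probs = motif.counts / motif.counts.sum(axis=0, keepdims=True)
    bases = np.array(list("ACGT"))

    sequences: dict[str, str] = {}
    chrom_sizes: dict[str, int] = {}
    site_peaks: list[Interval] = []
    tss: dict[str, list[int]] = {}
    labels: dict[str, LabelSequence] = {}
    marker_peaks: dict[str, list[Interval]] = {
        name: [] for name in cfg.marker_rates
    }

    for c in range(cfg.n_chroms):
        chrom = f"chr{c + 1}"
        length = cfg.chrom_length
        chrom_sizes[chrom] = length
        seq = rng.integers(0, 4, size=length)

        tss_positions = sorted(
            int(p) for p in rng.integers(0, length, size=cfg.n_tss_per_chrom)
        )
        tss[chrom] = tss_positions

        starts = _plant_sites(
            rng,
            chrom,
            length,
            motif,
            cfg.n_sites_per_chrom,
            tss_positions,
            cfg.tss_enrichment,
            cfg.promoter_half_width,
        )
        chrom_peaks: list[Interval] = []
        for start in starts:
            for offset in range(motif.width):
                seq[start + offset] = rng.choice(4, p=col_probs[:, offset])
            center = start + motif.width // 2
            half = cfg.site_peak_width // 2
            p_start = max(0, center - half)
            p_end = min(length, center + (cfg.site_peak_width - half))
            chrom_peaks.append(Interval(chrom, p_start, p_end))
        site_peaks.extend(chrom_peaks)
        sequences[chrom] = "".join(bases[seq])

        bins = BinnedChromosome(chrom, length, cfg.bin_size)
        lab = label_bins_peak_centric(bins, chrom_peaks)
        labels[chrom] = lab

        is_site = lab.labels.astype(bool)
        marker_on: dict[str, np.ndarray] = {}
        for name, (p_site, p_bg) in cfg.marker_rates.items():
            p = np.where(is_site, p_site, p_bg)
            marker_on[name] = rng.random(bins.n_bins) < p
        m1, m2 = cfg.cooccurrence_pair
        if cfg.cooccurrence_boost > 0 and m1 in marker_on and m2 in marker_on:
            force = is_site & (rng.random(bins.n_bins) < cfg.cooccurrence_boost)
            marker_on[m1] |= force
            marker_on[m2] |= force
        for name, on in marker_on.items():
            marker_peaks[name].extend(_merge_on_bins(chrom, on, bins))

    return SyntheticDataset(
        cfg, sequences, chrom_sizes, site_peaks, marker_peaks, tss, labels
    )


def build_chains(
    dataset: SyntheticDataset,
    pseudocount: float = pwm_scan.DEFAULT_PSEUDOCOUNT,
) -> list[crf_core.Chain]:
    """Run the data-preparation pipeline on a generated dataset.

    Returns one (feature matrix, label sequence) chain per chromosome with
    rows: PWM, the configured histone marks, then TSS proximity.
    """
    cfg = dataset.config
    motif = cfg.motif
    chains: list[crf_core.Chain] = []
    for bins in dataset.bins:
        chrom = bins.chrom_name
        scores = pwm_scan.scan_chromosome(dataset.sequences[chrom], motif)
        pwm_row = pwm_scan.max_score_per_bin(scores, bins)
        binary_rows: dict[str, np.ndarray] = {}
        for name in cfg.marker_rates:
            peaks = [iv for iv in dataset.marker_peaks[name] if iv.chrom == chrom]
            binary_rows[name] = binarize_peak_overlap(bins, peaks)
        binary_rows[TSS_ROW_NAME] = tss_proximity(
            bins, dataset.tss[chrom], cfg.promoter_half_width
        )
        chains.append(
            (assemble_feature_matrix(bins, pwm_row, binary_rows), dataset.labels[chrom])
        )
    return chains


def subset_chains(
    chains: Sequence[crf_core.Chain], row_names: Sequence[str]
) -> list[crf_core.Chain]:
    """Restrict every chain's matrix to ``row_names`` (PWM first)."""
    return [(X.select_rows(row_names), y) for X, y in chains]


def ablation_benchmark(
    cfg: SyntheticConfig,
    feature_subsets: Sequence[Sequence[str] | str],
    cv_k: int = 10,
    cv_seed: int = 0,
    sigma2: float = crf_core.DEFAULT_SIGMA2,
    **train_kwargs,
) -> pd.DataFrame:
    """Cross-validated AUC per feature subset on one generated dataset.

    Each subset is either ``"all"`` or a list of row names starting with
    ``"PWM"`` (e.g. ``["PWM", "H3K4me2"]``).  Returns a table of
    (subset, mean_auc, sd_auc, pooled_auc, pooled_auc10) preserving the
    requested order.
    """
    dataset = generate_dataset(cfg)
    chains = build_chains(dataset)
    all_rows = list(chains[0][0].row_names)
    plan = evaluation.make_cv_plan(
        [X.chrom_name for X, _ in chains], k=cv_k, seed=cv_seed
    )

    records = []
    for subset in feature_subsets:
        if subset == "all":
            names = all_rows
        else:
            names = list(subset)
            unknown = [n for n in names if n not in all_rows]
            if unknown:
                raise ValueError(f"unknown feature name(s): {unknown}")
        sub = subset_chains(chains, names)
        fs = build_default_feature_set(names)
        cv = evaluation.cross_validate(sub, fs, plan, sigma2=sigma2, **train_kwargs)
        records.append(
            {
                "subset": "all" if subset == "all" else "+".join(names),
                "mean_auc": cv.mean_auc,
                "sd_auc": cv.sd_auc,
                "pooled_auc": cv.pooled.auc,
                "pooled_auc10": cv.pooled.auc10,
            }
        )
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# On-disk form (standard FASTA/BED/chrom.sizes + YAML config)


def write_dataset(dataset: SyntheticDataset, outdir) -> None:
    os.makedirs(outdir, exist_ok=True)
    cfg = dataset.config

    with open(os.path.join(outdir, "genome.fa"), "w") as fh:
        for chrom, seq in dataset.sequences.items():
            fh.write(f">{chrom}\n")
            for pos in range(0, len(seq), 80):
                fh.write(seq[pos : pos + 80] + "\n")
    with open(os.path.join(outdir, "chrom.sizes"), "w") as fh:
        for chrom, length in dataset.chrom_sizes.items():
            fh.write(f"{chrom}\t{length}\n")
    with open(os.path.join(outdir, "site_peaks.bed"), "w") as fh:
        for iv in dataset.site_peaks:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
    with open(os.path.join(outdir, "tss.bed"), "w") as fh:
        for chrom, positions in dataset.tss.items():
            for t in positions:
                fh.write(f"{chrom}\t{t}\t{t + 1}\n")
    markers_dir = os.path.join(outdir, "markers")
    os.makedirs(markers_dir, exist_ok=True)
    for name, peaks in dataset.marker_peaks.items():
        with open(os.path.join(markers_dir, f"{name}.bed"), "w") as fh:
            for iv in peaks:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
    labels_path = os.path.join(outdir, "labels.bed")
    open(labels_path, "w").close()
    for bins in dataset.bins:
        write_labels_bed(dataset.labels[bins.chrom_name], bins, labels_path, append=True)
    with open(os.path.join(outdir, "motif.jaspar"), "w") as fh:
        fh.write(f">{cfg.motif.name} {cfg.motif.name}\n")
        for base, row in zip("ACGT", cfg.motif.counts):
            fh.write(f"{base} [ " + " ".join(f"{v:g}" for v in row) + " ]\n")
    cfg_doc = {
        "n_chroms": cfg.n_chroms,
        "chrom_length": cfg.chrom_length,
        "bin_size": cfg.bin_size,
        "n_sites_per_chrom": cfg.n_sites_per_chrom,
        "marker_rates": {k: list(v) for k, v in cfg.marker_rates.items()},
        "cooccurrence_pair": list(cfg.cooccurrence_pair),
        "cooccurrence_boost": cfg.cooccurrence_boost,
        "tss_enrichment": cfg.tss_enrichment,
        "n_tss_per_chrom": cfg.n_tss_per_chrom,
        "promoter_half_width": cfg.promoter_half_width,
        "site_peak_width": cfg.site_peak_width,
        "seed": cfg.seed,
    }
    with open(os.path.join(outdir, "config.yaml"), "w") as fh:
        yaml.safe_dump(cfg_doc, fh, sort_keys=True)
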