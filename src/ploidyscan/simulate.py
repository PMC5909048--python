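"""Synthetic VCF generator with known ploidy structure.

Emulates the VCF layer the allele-balance method consumes — not reads or
mapping.  Heterozygous sites are scattered uniformly along each chromosome
at a configurable density; at each site the total read depth is drawn from
a negative binomial around the mean (high-throughput coverage is
overdispersed, with long tails at both ends), and the reference-allele
depth is binomial at the site's true dosage ratio (2/3 for a triploid 2:1
site, 3/4 for a tetraploid 3:1 site, ...).  A configurable fraction of
sites is noise whose balance is uniform on (0, 1), mimicking the broad
histogram base real data show under mapping error and paralogy.  Ploidy is
piecewise-constant along each chromosome per sample, so sub-genomic copy
number changes (aneuploid segments) are representable and the per-window
truth is known by construction.

What the generator does not emulate: linkage between sites, genotyping
error in GT, reference bias, indels/multiallelic sites, and loss of
heterozygosity other than what the density implies.

Same seed, same config -> byte-identical VCF output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["PloidySegment", "SimulationConfig", "SimulatedTruth",
           "simulate_vcf", "simulate_populations"]

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class PloidySegment:
    """One constant-ploidy interval of a sample's genome.

    ``start``/``end`` are 1-based inclusive; ``copy_number`` in 2..5;
    ``dominant_dosage`` is how many of the copies carry the dominant
    allele (default copy_number - 1, putting the dominant balance at the
    canonical (c-1)/c peak; a tetraploid 2:2 segment uses dosage 2).
    """

    start: int
    end: int
    copy_number: int
    dominant_dosage: int | None = None

    @property
    def dosage(self) -> int:
        d = self.copy_number - 1 if self.dominant_dosage is None \
            else self.dominant_dosage
        return d

    @property
    def ratio(self) -> float:
        """True dominant-allele dosage ratio of the segment."""
        return self.dosage / self.copy_number

    def validate(self) -> None:
        if not 2 <= self.copy_number <= 5:
            raise ValueError("copy_number must be in 2..5")
        if not 1 <= self.dosage < self.copy_number:
            raise ValueError(
                "dominant_dosage must leave both alleles present")
        if self.end < self.start:
            raise ValueError("segment end before start")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic VCF.

    Defaults emulate a high-coverage fungal-scale dataset: ~100x depth at
    variable positions, about 5 heterozygous sites per kbp (real genomes
    show roughly 3-8), a 5% uniform-noise fraction, and moderate
    negative-binomial overdispersion (``depth_shape`` is the nbinom shape
    k; variance = m + m^2/k).
    """

    chrom_lengths: Mapping[str, int]
    ploidy_tracks: Mapping[str, Mapping[str, Sequence[PloidySegment]]]
    #: heterozygous sites per kbp
    het_density: float = 5.0
    mean_depth: float = 100.0
    depth_shape: float = 10.0
    noise_fraction: float = 0.05
    #: fraction of extra sites emitted as homozygous calls (exercises the
    #: heterozygote masking; the method discards them)
    homozygous_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not self.chrom_lengths:
            raise ValueError("no chromosomes configured")
        for c, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {c!r} has zero length")
        if self.het_density <= 0:
            raise ValueError("het_density must be > 0")
        if not 0.0 <= self.noise_fraction <= 1.0:
            raise ValueError("noise_fraction must be in [0, 1]")
        if not 0.0 <= self.homozygous_fraction <= 1.0:
            raise ValueError("homozygous_fraction must be in [0, 1]")
        for sample, tracks in self.ploidy_tracks.items():
            for c, segments in tracks.items():
                if c not in self.chrom_lengths:
                    raise ValueError(f"track for unknown chromosome {c!r}")
                pos = 1
                for seg in segments:
                    seg.validate()
                    if seg.start != pos:
                        raise ValueError(
                            f"{sample}/{c}: segments must tile the "
                            f"chromosome (gap/overlap at {seg.start})")
                    pos = seg.end + 1
                if pos != self.chrom_lengths[c] + 1:
                    raise ValueError(
                        f"{sample}/{c}: segments end at {pos - 1}, "
                        f"chromosome length is {self.chrom_lengths[c]}")

    @classmethod
    def uniform(cls, chrom_lengths: Mapping[str, int],
                samples: Sequence[str], copy_number: int = 2,
                **kwargs) -> "SimulationConfig":
        """Convenience: every sample at one copy number genome-wide."""
        tracks = {
            s: {c: [PloidySegment(1, L, copy_number)]
                for c, L in chrom_lengths.items()}
            for s in samples
        }
        return cls(chrom_lengths=chrom_lengths, ploidy_tracks=tracks,
                   **kwargs)


@dataclass
class SimulatedTruth:
    """Ground truth aligned to the emitted variants.

    ``variants`` has CHROM and POS; per sample there are aligned columns
    ``cn_<sample>`` (true copy number), ``ratio_<sample>`` (true dominant
    dosage ratio of the underlying segment) and ``noise_<sample>`` (True
    where the site's balance was drawn uniform instead).
    """

    table: pd.DataFrame
    config: SimulationConfig

    def window_truth(self, window_size: int) -> pd.DataFrame:
        """Majority true copy number per window and sample (rows per
        (CHROM, WINDOW) up to the last variant-bearing window)."""
        samples = list(self.config.ploidy_tracks)
        rows = []
        for c in dict.fromkeys(self.table["CHROM"]):
            sub = self.table[self.table["CHROM"] == c]
            widx = (sub["POS"].to_numpy() - 1) // window_size
            for k in range(int(widx.max()) + 1):
                sel = sub.loc[widx == k]
                row = {"CHROM": c, "WINDOW": k,
                       "START": k * window_size + 1,
                       "END": (k + 1) * window_size}
                for s in samples:
                    cn = sel[f"cn_{s}"]
                    row[f"cn_{s}"] = (
                        int(cn.mode().iloc[0]) if len(cn) else np.nan)
                rows.append(row)
        return pd.DataFrame(rows)

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _segment_at(segments: Sequence[PloidySegment], pos: int) -> PloidySegment:
    for seg in segments:
        if seg.start <= pos <= seg.end:
            return seg
    raise ValueError(f"position {pos} not covered by ploidy track")


def _gt_string(copy_number: int, dosage: int, ref_dominant: bool) -> str:
    """Unphased GT with `dosage` copies of the dominant allele."""
    dom, other = ("0", "1") if ref_dominant else ("1", "0")
    return "/".join([dom] * dosage + [other] * (copy_number - dosage))


def simulate_vcf(
    config: SimulationConfig,
    vcf_path: str,
    truth_path: str | None = None,
) -> SimulatedTruth:
    """Generate a VCF v4.2 with GT:AD genotypes and known ploidy truth.

    All samples are genotyped at every emitted site.  The dominant allele
    is the REF allele, so the AD string is ``dominant,secondary`` before
    sorting; downstream code must not rely on that order.  Optionally a
    fraction of additional homozygous sites is interleaved.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    samples = list(config.ploidy_tracks)

    chroms: list[str] = []
    positions: list[int] = []
    for c, length in config.chrom_lengths.items():
        n_sites = int(round(config.het_density * length / 1000.0))
        n_sites = max(n_sites, 1)
        pos = np.unique(rng.integers(1, length + 1, size=n_sites))
        chroms.extend([c] * pos.size)
        positions.extend(int(p) for p in pos)

    n_var = len(positions)
    nb_p = config.depth_shape / (config.depth_shape + config.mean_depth)

    gt_cells: dict[str, list[str]] = {s: [] for s in samples}
    ad_cells: dict[str, list[str]] = {s: [] for s in samples}
    truth_cols: dict[str, list] = {}
    for s in samples:
        truth_cols[f"cn_{s}"] = []
        truth_cols[f"ratio_{s}"] = []
        truth_cols[f"noise_{s}"] = []

    for c, p in zip(chroms, positions):
        for s in samples:
            seg = _segment_at(config.ploidy_tracks[s][c], p)
            total = int(rng.negative_binomial(config.depth_shape, nb_p))
            is_noise = rng.random() < config.noise_fraction
            is_hom = (config.homozygous_fraction > 0
                      and rng.random() < config.homozygous_fraction)
            if is_hom:
                gt_cells[s].append("/".join(["0"] * seg.copy_number))
                ad_cells[s].append(f"{total},0")
                truth_cols[f"cn_{s}"].append(seg.copy_number)
                truth_cols[f"ratio_{s}"].append(np.nan)
                truth_cols[f"noise_{s}"].append(False)
                continue
            ratio = float(rng.random()) if is_noise else seg.ratio
            d_ref = int(rng.binomial(total, ratio)) if total > 0 else 0
            gt_cells[s].append(_gt_string(seg.copy_number, seg.dosage, True))
            ad_cells[s].append(f"{d_ref},{total - d_ref}")
            truth_cols[f"cn_{s}"].append(seg.copy_number)
            truth_cols[f"ratio_{s}"].append(seg.ratio)
            truth_cols[f"noise_{s}"].append(bool(is_noise))

    ref = rng.choice(_BASES, size=n_var)
    alt = np.array([_BASES[((_BASES.index(r)) + 1 + int(k)) % 4]
                    for r, k in zip(ref, rng.integers(0, 3, size=n_var))])

    lines = [
        "##fileformat=VCFv4.2",
        "##source=ploidyscan-simulate",
    ]
    for c, length in config.chrom_lengths.items():
        lines.append(f"##contig=<ID={c},length={length}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Allelic depths for the ref and alt alleles">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples))
    for i in range(n_var):
        fields = [chroms[i], str(positions[i]), ".", str(ref[i]),
                  str(alt[i]), ".", "PASS", ".", "GT:AD"]
        fields.extend(f"{gt_cells[s][i]}:{ad_cells[s][i]}" for s in samples)
        lines.append("\t".join(fields))
    with open(vcf_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")

    table = pd.DataFrame({"CHROM": chroms,
                          "POS": np.asarray(positions, dtype=np.int64)})
    for k, v in truth_cols.items():
        table[k] = v
    truth = SimulatedTruth(table, config)
    if truth_path:
        truth.to_tsv(truth_path)
    logger.info("simulated %d variants x %d samples -> %s",
                n_var, len(samples), vcf_path)
    return truth


def simulate_populations(
    allele_freqs: Mapping[str, Sequence[float]],
    sample_sizes: Mapping[str, int],
    ploidies: Mapping[str, int],
    n_variants: int = 1,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, str], pd.DataFrame]:
    """Draw GT matrices for populations of (possibly different) ploidy.

    Each sample's genotype at each variant is ``ploidy`` alleles drawn
    independently from its population's allele-frequency vector.

    Returns (gt_matrix, sample->population map, truth frequencies).
    """
    rng = np.random.default_rng(seed)
    for p, f in allele_freqs.items():
        if abs(sum(f) - 1.0) > 1e-9:
            raise ValueError(f"frequencies for population {p!r} do not sum to 1")
    pops: dict[str, str] = {}
    columns: dict[str, list[str]] = {}
    for p in allele_freqs:
        f = np.asarray(allele_freqs[p], dtype=float)
        k = ploidies[p]
        for j in range(sample_sizes[p]):
            name = f"{p}_{j}"
            pops[name] = p
            draws = rng.choice(f.size, size=(n_variants, k), p=f)
            columns[name] = ["/".join(str(a) for a in sorted(row))
                             for row in draws]
    gt = pd.DataFrame(columns, dtype=object)
    truth = pd.DataFrame({p: np.asarray(allele_freqs[p], dtype=float)
                          for p in allele_freqs}).T
    return gt, pops, truth
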