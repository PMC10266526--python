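"""Readers and writers for the formats the pipeline touches, plus the
physical<->genetic coordinate transform every other stage relies on.

Conventions
-----------
Variants are 1-based inclusive (VCF convention) everywhere in memory; BED
output is 0-based half-open.  Summary-statistics tables are pandas
DataFrames with the canonical column set ``SUMSTAT_COLUMNS``.  p-values are
carried exclusively as -log10 values (column ``neg_log10_p``) so that
association signals far beyond float underflow survive round-trips.
"""

from __future__ import annotations

import io
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical summary-statistics column order (beta is on the ln-OR scale)
SUMSTAT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "beta", "se",
    "neg_log10_p", "af", "n_case", "n_control",
]

#: explicit missing-genotype code for archaic references (never 0)
MISSING = -1


class FormatError(ValueError):
    """A malformed input file; the message names the offending field."""


@dataclass(frozen=True)
class Variant:
    """A biallelic SNV identified by (chrom, pos, ref, alt).

    ``pos`` is 1-based.  ``id`` is an optional rsID label.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str | None = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)

    def __str__(self) -> str:  # chr7:37984972G/A
        return f"{self.chrom}:{self.pos}{self.ref}/{self.alt}"


class RecombinationMap:
    """Monotone piecewise-linear map from physical position (bp) to genetic
    position (cM).

    Beyond the first/last anchor the map extrapolates linearly at
    ``end_rate`` cM/Mb (default 1, the conventional genome-average rate used
    where map coverage runs out; at that rate 23 kb corresponds to
    0.023 cM).

    Parameters
    ----------
    chrom : chromosome label
    positions : ascending physical anchor positions, bp
    cum_cM : non-decreasing cumulative genetic positions, cM
    end_rate : extrapolation rate in cM/Mb, > 0
    """

    def __init__(self, chrom: str, positions: Sequence[int],
                 cum_cM: Sequence[float], end_rate: float = 1.0):
        pos = np.asarray(positions, dtype=float)
        cm = np.asarray(cum_cM, dtype=float)
        if pos.size == 0:
            raise FormatError("recombination map has no anchors")
        if pos.size != cm.size:
            raise FormatError("anchor position/cM lengths differ")
        if np.any(np.diff(pos) <= 0):
            raise FormatError("anchor positions must be strictly increasing")
        if np.any(np.diff(cm) < 0):
            raise FormatError("cumulative cM must be non-decreasing")
        if end_rate <= 0:
            raise ValueError("end_rate must be > 0")
        self.chrom = chrom
        self.positions = pos
        self.cum_cM = cm
        self.end_rate = float(end_rate)

    def genetic_position(self, pos_bp):
        """Map physical position(s) in bp to genetic position(s) in cM."""
        pos_bp = np.asarray(pos_bp, dtype=float)
        scalar = pos_bp.ndim == 0
        p = np.atleast_1d(pos_bp)
        out = np.interp(p, self.positions, self.cum_cM)
        rate_per_bp = self.end_rate * 1e-6
        lo, hi = self.positions[0], self.positions[-1]
        below = p < lo
        above = p > hi
        out[below] = self.cum_cM[0] - (lo - p[below]) * rate_per_bp
        out[above] = self.cum_cM[-1] + (p[above] - hi) * rate_per_bp
        return float(out[0]) if scalar else out

    def physical_position(self, cm):
        """Inverse transform: genetic position (cM) back to bp.

        Within flat (zero-rate) intervals the left endpoint is returned.
        """
        cm = np.asarray(cm, dtype=float)
        scalar = cm.ndim == 0
        c = np.atleast_1d(cm)
        out = np.interp(c, self.cum_cM, self.positions)
        rate_per_bp = self.end_rate * 1e-6
        lo, hi = self.cum_cM[0], self.cum_cM[-1]
        below = c < lo
        above = c > hi
        out[below] = self.positions[0] - (lo - c[below]) / rate_per_bp
        out[above] = self.positions[-1] + (c[above] - hi) / rate_per_bp
        return float(out[0]) if scalar else out

    def local_rates(self):
        """Per-interval recombination rates in cM/Mb between anchors.

        Returns (starts_bp, ends_bp, rates); used for hotspot detection.
        """
        d_bp = np.diff(self.positions)
        d_cm = np.diff(self.cum_cM)
        rates = d_cm / (d_bp * 1e-6)
        return self.positions[:-1], self.positions[1:], rates

    @classmethod
    def uniform(cls, chrom: str, length_bp: int, rate_cM_per_Mb: float = 1.0):
        """Constant-rate map covering [1, length_bp]."""
        return cls(chrom, [1, length_bp],
                   [0.0, (length_bp - 1) * rate_cM_per_Mb * 1e-6],
                   end_rate=rate_cM_per_Mb)


def genetic_position(rec_map: RecombinationMap, pos_bp):
    """Functional alias for :meth:`RecombinationMap.genetic_position`."""
    return rec_map.genetic_position(pos_bp)


@dataclass
class TruthTract:
    """Simulation ground truth for one archaic-origin segment on one
    haplotype; ``origin`` is ``"introgressed"`` or ``"ILS"``."""

    sample: str
    hap: int          # 0 or 1
    start_bp: int     # 1-based inclusive
    end_bp: int
    origin: str


@dataclass
class HaplotypePanel:
    """A modern genotype panel: samples x sites allele matrix.

    ``alleles`` has shape (2 * n_samples, n_sites) with entries in {0, 1};
    haplotypes 2i and 2i+1 belong to sample i.  When ``phased`` is False the
    within-individual order of the two rows is arbitrary and only dosages
    (0/1/2) are meaningful.  ``truth_tracts`` is populated only by the
    simulator.
    """

    samples: list
    sites: list
    alleles: np.ndarray
    phased: bool = True
    truth_tracts: list = field(default_factory=list)

    def __post_init__(self):
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.shape != (2 * len(self.samples), len(self.sites)):
            raise ValueError("allele matrix shape does not match samples/sites")
        if not np.isin(self.alleles, [0, 1]).all():
            raise ValueError("panel alleles must be 0/1")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.pos for v in self.sites])

    def dosages(self) -> np.ndarray:
        """Genotype dosage matrix, shape (n_samples, n_sites), values 0/1/2."""
        return (self.alleles[0::2] + self.alleles[1::2]).astype(np.int8)

    def site_index(self, variant: Variant) -> int:
        for i, v in enumerate(self.sites):
            if v.key == variant.key:
                return i
        raise KeyError(f"variant {variant} not in panel")


@dataclass
class ArchaicGenotypes:
    """Single archaic reference individual aligned to a panel's sites.

    ``gt`` holds alt-allele dosages in {0, 1, 2} with :data:`MISSING` (-1)
    marking unmapped sites — archaic genomes have roughly half their sites
    uncallable, so missing is an explicit state, never a 0.
    """

    sites: list
    gt: np.ndarray
    sample: str = "archaic"

    def __post_init__(self):
        self.gt = np.asarray(self.gt, dtype=np.int8)
        if self.gt.shape != (len(self.sites),):
            raise ValueError("gt length does not match sites")
        ok = np.isin(self.gt, [MISSING, 0, 1, 2])
        if not ok.all():
            raise ValueError("archaic dosages must be in {-1, 0, 1, 2}")

    @property
    def missing_fraction(self) -> float:
        return float(np.mean(self.gt == MISSING))


# ---------------------------------------------------------------------------
# summary statistics TSV


def _as_handle(stream, mode="r"):
    if isinstance(stream, (str, Path)):
        return open(stream, mode), True
    return stream, False


def read_summary_stats(stream, study_id: str) -> pd.DataFrame:
    """Read a per-study GWAS summary-statistics TSV.

    The header must contain every column in :data:`SUMSTAT_COLUMNS`; beta is
    on the ln-OR scale.  Rows with non-finite standard errors are dropped
    with a logged count.  Duplicate (chrom, pos, ref, alt) keys raise.

    Returns a DataFrame keyed by (chrom, pos, ref, alt) with a ``study``
    column attached.
    """
    handle, close = _as_handle(stream)
    try:
        df = pd.read_csv(handle, sep="\t", dtype={"chrom": str})
    finally:
        if close:
            handle.close()
    for col in SUMSTAT_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"summary statistics missing required column {col!r}")
    df = df[SUMSTAT_COLUMNS].copy()
    dup = df.duplicated(subset=["chrom", "pos", "ref", "alt"])
    if dup.any():
        first = df.loc[dup.idxmax(), ["chrom", "pos", "ref", "alt"]]
        raise FormatError(
            "duplicated variant key "
            f"{first.chrom}:{first.pos}:{first.ref}:{first.alt}"
        )
    bad_se = ~np.isfinite(df["se"].to_numpy(dtype=float))
    if bad_se.any():
        logger.warning("%s: dropped %d rows with non-finite se",
                       study_id, int(bad_se.sum()))
        df = df[~bad_se].reset_index(drop=True)
    df.insert(0, "study", study_id)
    return df


def write_summary_stats(df: pd.DataFrame, stream) -> None:
    """Write the canonical summary-statistics TSV (study column excluded)."""
    out = df[SUMSTAT_COLUMNS]
    handle, close = _as_handle(stream, "w")
    try:
        out.to_csv(handle, sep="\t", index=False, lineterminator="\n",
                   float_format="%.10g")
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# VCF (v4.2 subset: biallelic SNVs, GT only)


def _is_snv(ref: str, alts) -> bool:
    return (len(alts) == 1 and len(ref) == 1 and len(alts[0]) == 1
            and alts[0] in "ACGT" and ref in "ACGT")


def read_genotypes(path, kind: str = "panel"):
    """Read a VCF into a :class:`HaplotypePanel` or :class:`ArchaicGenotypes`.

    Parameters
    ----------
    path : VCF file path (plain text or bgzipped)
    kind : ``"panel"`` for a modern multi-sample panel (missing genotypes are
        a format error), ``"archaic"`` for a single-sample reference where
        ``./.`` becomes the explicit :data:`MISSING` state.

    Multiallelic records and indels are skipped with a logged count.  The
    panel ``phased`` flag is set only if every genotype is phased (``|``).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    sites, rows = [], []
    n_skipped = 0
    phased_all = True
    for rec in vcf:
        if not _is_snv(rec.REF, rec.ALT):
            n_skipped += 1
            continue
        sites.append(Variant(rec.CHROM, rec.POS, rec.REF, rec.ALT[0],
                             rec.ID if rec.ID not in (None, ".") else None))
        gts = rec.genotypes  # [[a0, a1, phased], ...]
        rows.append(gts)
        if not all(g[2] for g in gts):
            phased_all = False
    vcf.close()
    if n_skipped:
        logger.warning("%s: skipped %d multiallelic/indel records",
                       path, n_skipped)

    if kind == "archaic":
        if len(samples) != 1:
            raise FormatError(
                f"archaic VCF must have exactly 1 sample, found {len(samples)}")
        gt = np.empty(len(sites), dtype=np.int8)
        for j, gts in enumerate(rows):
            a0, a1 = gts[0][0], gts[0][1]
            gt[j] = MISSING if (a0 < 0 or a1 < 0) else a0 + a1
        return ArchaicGenotypes(sites, gt, sample=samples[0])

    if kind != "panel":
        raise ValueError(f"unknown kind {kind!r}")
    alleles = np.empty((2 * len(samples), len(sites)), dtype=np.int8)
    for j, gts in enumerate(rows):
        for i, g in enumerate(gts):
            a0, a1 = g[0], g[1]
            if a0 < 0 or a1 < 0:
                raise FormatError(
                    f"missing genotype for sample {samples[i]} at site "
                    f"{sites[j]} in panel VCF")
            alleles[2 * i, j] = a0
            alleles[2 * i + 1, j] = a1
    return HaplotypePanel(samples, sites, alleles, phased=phased_all)


def write_vcf(obj, stream) -> None:
    """Write a panel or archaic reference as a minimal VCF v4.2 (GT only)."""
    handle, close = _as_handle(stream, "w")
    try:
        handle.write("##fileformat=VCFv4.2\n")
        handle.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if isinstance(obj, ArchaicGenotypes):
            names = [obj.sample]
        else:
            names = list(obj.samples)
        handle.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\t"
                     "FORMAT\t" + "\t".join(names) + "\n")
        if isinstance(obj, ArchaicGenotypes):
            for v, d in zip(obj.sites, obj.gt):
                if d == MISSING:
                    g = "./."
                else:
                    g = ["0/0", "0/1", "1/1"][d]
                handle.write(f"{v.chrom}\t{v.pos}\t{v.id or '.'}\t{v.ref}\t"
                             f"{v.alt}\t.\t.\t.\tGT\t{g}\n")
        else:
            sep = "|" if obj.phased else "/"
            A = obj.alleles
            for j, v in enumerate(obj.sites):
                gs = "\t".join(f"{A[2 * i, j]}{sep}{A[2 * i + 1, j]}"
                               for i in range(obj.n_samples))
                handle.write(f"{v.chrom}\t{v.pos}\t{v.id or '.'}\t{v.ref}\t"
                             f"{v.alt}\t.\t.\t.\tGT\t{gs}\n")
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# tract BED (6+2: chrom start end sample score strand length_cM zygosity)

BED_HEADER = "#chrom\tstart\tend\tsample\tscore\tstrand\tlength_cM\tzygosity"


def write_tracts_bed(tracts: Iterable, stream) -> None:
    """Write detected archaic tracts as BED6+2.

    Coordinates convert from 1-based inclusive to BED 0-based half-open;
    name = sample, score = round(LOD); extra columns carry the genetic
    length (cM) and zygosity call.
    """
    rows = []
    for t in tracts:
        if t.end_bp <= t.start_bp - 1:
            raise ValueError(f"tract with end <= start: {t}")
        rows.append((t.chrom, t.start_bp - 1, t.end_bp, t.sample,
                     int(round(t.lod)), ".", t.length_cM, t.zygosity))
    rows.sort(key=lambda r: (r[0], r[1]))
    handle, close = _as_handle(stream, "w")
    try:
        handle.write(BED_HEADER + "\n")
        for r in rows:
            handle.write("\t".join(
                f"{x:.6g}" if isinstance(x, float) else str(x)
                for x in r) + "\n")
    finally:
        if close:
            handle.close()


def read_tracts_bed(stream) -> list:
    """Read tracts written by :func:`write_tracts_bed`."""
    from .introgression import ArchaicTract

    handle, close = _as_handle(stream)
    tracts = []
    try:
        for line in handle:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 8:
                raise FormatError(f"tract BED line has {len(f)} fields, need 8")
            tracts.append(ArchaicTract(
                sample=f[3], chrom=f[0], start_bp=int(f[1]) + 1,
                end_bp=int(f[2]), lod=float(f[4]),
                length_cM=float(f[6]), zygosity=f[7]))
    finally:
        if close:
            handle.close()
    return tracts


# ---------------------------------------------------------------------------
# HapMap-format recombination map


def read_recombination_map(stream, end_rate: float = 1.0) -> RecombinationMap:
    """Read a HapMap-style recombination map.

    Expected columns: chrom, pos (bp), rate (cM/Mb) and, optionally,
    cumulative map position (cM).  When the cumulative column is absent it
    is reconstructed by integrating the rate column from the first anchor.
    """
    handle, close = _as_handle(stream)
    try:
        df = pd.read_csv(handle, sep=r"\s+")
    finally:
        if close:
            handle.close()
    if df.shape[1] < 3:
        raise FormatError("recombination map needs >= 3 columns "
                          "(chrom, pos, rate[, map])")
    chroms = df.iloc[:, 0].astype(str)
    if chroms.nunique() != 1:
        raise FormatError("recombination map must cover a single chromosome")
    pos = df.iloc[:, 1].to_numpy(dtype=float)
    rate = df.iloc[:, 2].to_numpy(dtype=float)
    if df.shape[1] >= 4:
        cm = df.iloc[:, 3].to_numpy(dtype=float)
    else:
        # trapezoid-free integration: rate[i] applies over [pos[i], pos[i+1])
        cm = np.zeros_like(pos)
        cm[1:] = np.cumsum(rate[:-1] * np.diff(pos) * 1e-6)
    return RecombinationMap(chroms.iloc[0], pos, cm, end_rate=end_rate)


def write_recombination_map(rec_map: RecombinationMap, stream) -> None:
    """Write the 4-column HapMap-style map."""
    handle, close = _as_handle(stream, "w")
    try:
        handle.write("chrom\tpos\trate_cM_Mb\tmap_cM\n")
        starts, ends, rates = rec_map.local_rates()
        out_rates = np.append(rates, rec_map.end_rate)
        for p, r, c in zip(rec_map.positions, out_rates, rec_map.cum_cM):
            handle.write(f"{rec_map.chrom}\t{int(p)}\t{r:.8g}\t{c:.10g}\n")
    finally:
        if close:
            handle.close()
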