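"""Archaic tract detection and the incomplete-lineage-sorting length test.

The detector scores each site of a modern diploid genome with a log10
likelihood ratio (LOD) comparing two hypotheses: one of the individual's
haplotypes is identical by descent with the archaic reference genome,
versus the genotype being an ordinary Hardy-Weinberg draw at the panel
allele frequency.  All maximal-scoring runs of site LODs are extracted in
linear time (Ruzzo-Tompa) and runs with total LOD >= a threshold (default
4, a conservative choice for IBD tract detection) become tracts.

Archaic-looking sequence can also be ancestral: haplotypes shared through
incomplete lineage sorting (ILS) predate the modern-archaic population
split and are therefore old and short.  Conditional on being observed on
both branches, the genetic length of such a shared tract is the sum of two
exponential lengths with mean L = 100 / (total branch length in
generations) cM, i.e. Gamma(shape 2, rate 1/L).  Tracts longer than the
upper alpha/n_tests quantile of that distribution are too long to be ILS
and are accepted as gene flow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .io_formats import (MISSING, ArchaicGenotypes, HaplotypePanel,
                         RecombinationMap)

logger = logging.getLogger(__name__)


@dataclass
class TractCallerParams:
    """Tuning knobs of the IBD tract caller.

    lod_threshold : minimum summed segment LOD to call a tract (default 4)
    modern_error : modern genotype error rate epsilon_m; the flip
        probability of the copied allele in the IBD emission model
    archaic_error : archaic genotype error rate epsilon_a.  The emission
        takes the archaic call at face value (heterozygous calls are
        averaged over the two alleles); this knob is for sensitivity
        analyses that perturb archaic calls before tract calling
    min_minor_count : minimum panel minor-allele count for a site to be
        informative; rarer sites contribute LOD 0
    """

    lod_threshold: float = 4.0
    modern_error: float = 0.002
    archaic_error: float = 0.01
    min_minor_count: int = 1

    def __post_init__(self):
        if self.lod_threshold <= 0:
            raise ValueError("lod_threshold must be > 0")
        for e in (self.modern_error, self.archaic_error):
            if not 0 < e < 0.5:
                raise ValueError("error rates must lie in (0, 0.5)")


@dataclass
class ArchaicTract:
    """A detected IBD segment between one modern sample and the archaic
    reference; coordinates are 1-based inclusive."""

    sample: str
    chrom: str
    start_bp: int
    end_bp: int
    lod: float
    length_cM: float = np.nan
    zygosity: str = "het"

    def __post_init__(self):
        if self.start_bp > self.end_bp:
            raise ValueError("tract start > end")


@dataclass
class ILSParams:
    """Inputs of the ILS length test.

    alpha : family-wise error target (default 0.05)
    n_tests : number of loci tested (Bonferroni divisor)
    t_div_gen : generations since the modern-archaic common ancestor
    t_admix_gen : generations since archaic admixture
    """

    alpha: float = 0.05
    n_tests: int = 1
    t_div_gen: float = 21_500.0
    t_admix_gen: float = 2_000.0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_tests < 1:
            raise ValueError("n_tests must be >= 1")


@dataclass
class CosegregationResult:
    """Unphased r-squared between a risk variant and archaic-tract carriage."""

    r2: float
    n_carrier_haplotypes: int
    defined: bool = True
    archaic_source: str = "archaic"
    variant: object | None = None


# ---------------------------------------------------------------------------
# per-site LOD emission model


def _ibd_emission(copied_alt_prob: float, modern_gt: int, p: float) -> float:
    """P(modern genotype | one haplotype copies the archaic allele).

    The copied haplotype carries the alt allele with probability
    ``copied_alt_prob``; the other haplotype is an independent population
    draw at alt frequency p.
    """
    c = copied_alt_prob
    if modern_gt == 2:
        return c * p
    if modern_gt == 1:
        return c * (1.0 - p) + (1.0 - c) * p
    return (1.0 - c) * (1.0 - p)


def site_lod(archaic_gt: int, modern_gt: int, alt_freq: float,
             params: TractCallerParams) -> float:
    """log10 likelihood ratio of IBD-with-archaic versus Hardy-Weinberg.

    A missing archaic call is uninformative (LOD 0), as is a site fixed in
    the panel (alt_freq 0 or 1).  A heterozygous archaic genotype averages
    the IBD likelihood over the two archaic alleles.
    """
    if archaic_gt == MISSING:
        return 0.0
    p = float(alt_freq)
    if p <= 0.0 or p >= 1.0:
        return 0.0
    eps = params.modern_error                 # copy-flip probability
    q = archaic_gt / 2.0                      # alt fraction in archaic call
    c = q * (1.0 - eps) + (1.0 - q) * eps     # P(copied haplotype is alt)
    num = _ibd_emission(c, modern_gt, p)
    if modern_gt == 2:
        den = p * p
    elif modern_gt == 1:
        den = 2.0 * p * (1.0 - p)
    else:
        den = (1.0 - p) * (1.0 - p)
    return float(np.log10(num / den))


def _site_lod_matrix(panel: HaplotypePanel, archaic: ArchaicGenotypes,
                     params: TractCallerParams) -> np.ndarray:
    """LOD for every (sample, site), vectorized over samples.

    Uses panel alt-allele frequencies; sites that are archaic-missing,
    panel-fixed, or below ``min_minor_count`` contribute 0.
    """
    dos = panel.dosages()                       # (n, m)
    n2 = 2 * panel.n_samples
    ac = dos.sum(axis=0)
    p = ac / n2
    minor = np.minimum(ac, n2 - ac)
    informative = ((archaic.gt != MISSING) & (minor >= params.min_minor_count)
                   & (p > 0) & (p < 1))
    eps = params.modern_error
    q = np.where(archaic.gt == MISSING, 0, archaic.gt) / 2.0
    c = q * (1.0 - eps) + (1.0 - q) * eps
    ps = np.where(informative, p, 0.5)          # placeholder avoids /0
    # emission tables per site for modern gt 0/1/2
    num = np.stack([(1.0 - c) * (1.0 - ps),
                    c * (1.0 - ps) + (1.0 - c) * ps,
                    c * ps])
    den = np.stack([(1.0 - ps) ** 2, 2.0 * ps * (1.0 - ps), ps ** 2])
    lod_by_gt = np.log10(num / den)             # (3, m)
    lod = lod_by_gt[dos, np.arange(dos.shape[1])]
    lod[:, ~informative] = 0.0
    return lod


# ---------------------------------------------------------------------------
# maximal-scoring subsequences (Ruzzo-Tompa)


def maximal_scoring_segments(scores) -> list[tuple[int, int, float]]:
    """All maximal-scoring subsequences of a real-valued score sequence.

    Linear-time Ruzzo-Tompa algorithm; returns (start, end, score) with
    end inclusive, in left-to-right order.  Every returned segment has
    strictly positive score and cannot be extended or trimmed to a
    higher-scoring overlapping segment.
    """
    scores = np.asarray(scores, dtype=float)
    cum = np.concatenate([[0.0], np.cumsum(scores)])
    # list entries: [start, end, L, R]; L = cumulative score just before
    # start, R = cumulative score through end
    segs: list[list] = []
    for k, x in enumerate(scores):
        if x <= 0:
            continue
        start, end = k, k
        L, R = cum[k], cum[k + 1]
        while True:
            j = None
            for idx in range(len(segs) - 1, -1, -1):
                if segs[idx][2] < L:
                    j = idx
                    break
            if j is None or segs[j][3] >= R:
                segs.append([start, end, L, R])
                break
            # R_j < R: the candidate subsumes segment j and everything
            # after it; merge and re-test against earlier segments
            start, L = segs[j][0], segs[j][2]
            del segs[j:]
    return [(s, e, R - L) for s, e, L, R in segs]


def call_tracts(panel: HaplotypePanel, archaic: ArchaicGenotypes,
                rec_map: RecombinationMap,
                params: TractCallerParams | None = None) -> list[ArchaicTract]:
    """Detect archaic-IBD tracts in every sample of a modern panel.

    Per sample, site LODs are computed along the chromosome and all maximal
    scoring runs with total LOD >= ``params.lod_threshold`` become tracts.
    A tract's physical span runs from its first to its last contributing
    site; its genetic length comes from the recombination map and its
    zygosity from :func:`runs_of_homozygosity` over the span.
    """
    params = params or TractCallerParams()
    if len(panel.sites) == 0 or len(archaic.sites) != len(panel.sites):
        if len(panel.sites) == 0 or len(archaic.sites) == 0:
            logger.warning("no aligned sites between panel and archaic")
            return []
        raise ValueError("panel and archaic site lists are not aligned")
    positions = panel.positions
    chrom = panel.sites[0].chrom
    lod = _site_lod_matrix(panel, archaic, params)
    tracts = []
    for i, sample in enumerate(panel.samples):
        for s, e, score in maximal_scoring_segments(lod[i]):
            if score < params.lod_threshold:
                continue
            start_bp, end_bp = int(positions[s]), int(positions[e])
            length = (rec_map.genetic_position(end_bp)
                      - rec_map.genetic_position(start_bp))
            zyg, _ = runs_of_homozygosity(panel, sample, start_bp, end_bp)
            tracts.append(ArchaicTract(sample=sample, chrom=chrom,
                                       start_bp=start_bp, end_bp=end_bp,
                                       lod=float(score),
                                       length_cM=float(length),
                                       zygosity=zyg))
    return tracts


def runs_of_homozygosity(panel: HaplotypePanel, sample: str,
                         start_bp: int, end_bp: int,
                         min_sites: int = 10,
                         hom_fraction: float = 0.99) -> tuple[str, bool]:
    """Classify a region of one sample as homozygous or heterozygous.

    The call is ``"hom"`` iff the region holds at least ``min_sites``
    genotyped sites of which >= ``hom_fraction`` are homozygous; otherwise
    ``"het"``.  Returns (zygosity, confident); regions with fewer than
    ``min_sites`` sites are low-confidence ``"het"``.
    """
    i = panel.samples.index(sample)
    pos = panel.positions
    in_region = (pos >= start_bp) & (pos <= end_bp)
    dos = (panel.alleles[2 * i] + panel.alleles[2 * i + 1])[in_region]
    if dos.size < min_sites:
        return "het", False
    frac_hom = float(np.mean(dos != 1))
    return ("hom" if frac_hom >= hom_fraction else "het"), True


# ---------------------------------------------------------------------------
# ILS length test


def expected_shared_length(t_div_gen: float, t_admix_gen: float) -> float:
    """Expected genetic length (cM) of a tract shared through ILS.

    The tract survives recombination on both branches back to the common
    ancestor; the total branch length is 2*t_div - t_admix generations and
    the expected length is its inverse in Morgans, i.e.
    100 / (2*t_div - t_admix) cM.  Divergence 21,500 and admixture 2,000
    generations give L = 100/41,000 = 1/410 cM.
    """
    if not 0 <= t_admix_gen < t_div_gen:
        raise ValueError("need 0 <= t_admix_gen < t_div_gen")
    branch = 2.0 * t_div_gen - t_admix_gen
    if branch <= 0:
        raise ValueError("non-positive total branch length")
    return 100.0 / branch


def ils_length_threshold(alpha: float, n_tests: int, L: float) -> float:
    """Minimum genetic length m (cM) excluding ILS at family-wise level alpha.

    Conditional on appearing on both branches, an ILS tract's genetic
    length is Gamma(shape 2, rate 1/L) distributed; m solves the survival
    equation (1 + m/L) * exp(-m/L) = alpha / n_tests.  With alpha 0.05,
    61 tests and L = 1/410 cM this gives m = 0.023 cM.
    """
    if L <= 0:
        raise ValueError("L must be > 0")
    q = alpha / n_tests
    if q >= 1.0:
        return 0.0
    if not 0 < q:
        raise ValueError("alpha/n_tests must be positive")
    # inverse upper-tail of Gamma(2, 1) then rescale by the mean parameter
    return float(L * special.gammainccinv(2.0, q))


def ils_survival(m: float, L: float) -> float:
    """P(ILS tract length > m) under Gamma(2, rate 1/L): (1 + m/L) e^{-m/L}."""
    x = m / L
    return float((1.0 + x) * np.exp(-x))


def filter_significant_tracts(tracts: list[ArchaicTract],
                              m_cM: float) -> list[ArchaicTract]:
    """Keep tracts strictly longer than the ILS threshold m (cM)."""
    return [t for t in tracts if t.length_cM > m_cM]


# ---------------------------------------------------------------------------
# cosegregation of risk variants with tract carriage


def merge_sample_tracts(tracts: list[ArchaicTract]) -> dict[str, list]:
    """Merge overlapping tracts within each sample.

    Returns {sample: [(start, end, zygosity), ...]} with disjoint spans; a
    merged span is ``hom`` if any constituent tract was called hom.
    """
    by_sample: dict[str, list] = {}
    for t in tracts:
        by_sample.setdefault(t.sample, []).append(t)
    merged = {}
    for sample, ts in by_sample.items():
        ts.sort(key=lambda t: t.start_bp)
        spans = []
        for t in ts:
            if spans and t.start_bp <= spans[-1][1] + 1:
                prev = spans[-1]
                spans[-1] = (prev[0], max(prev[1], t.end_bp),
                             "hom" if "hom" in (prev[2], t.zygosity) else "het")
            else:
                spans.append((t.start_bp, t.end_bp, t.zygosity))
        merged[sample] = spans
    return merged


def tract_dosage(tracts: list[ArchaicTract], sample: str, pos: int) -> int:
    """Archaic-haplotype dosage {0,1,2} of one sample at a position.

    0 if no tract of the sample covers pos, 1 for a heterozygous tract,
    2 for a homozygous one.  Overlapping tracts are merged first.
    """
    spans = merge_sample_tracts([t for t in tracts if t.sample == sample]
                                ).get(sample, [])
    for start, end, zyg in spans:
        if start <= pos <= end:
            return 2 if zyg == "hom" else 1
    return 0


def tract_dosage_vector(tracts: list[ArchaicTract], samples: list,
                        pos: int) -> np.ndarray:
    """Archaic dosage at ``pos`` for every sample, in panel order."""
    merged = merge_sample_tracts(tracts)
    out = np.zeros(len(samples), dtype=np.int8)
    for i, s in enumerate(samples):
        for start, end, zyg in merged.get(s, []):
            if start <= pos <= end:
                out[i] = 2 if zyg == "hom" else 1
                break
    return out


def cosegregation_r2(variant_dosages, tract_dosages,
                     archaic_source: str = "archaic",
                     variant=None) -> CosegregationResult:
    """Squared Pearson correlation between variant and tract dosages.

    This is the unphased genotype r-squared (the quantity PLINK reports for
    unphased data).  Zero variance in either vector leaves r2 undefined
    and flagged, never silently 0.
    """
    x = np.asarray(variant_dosages, dtype=float)
    y = np.asarray(tract_dosages, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("dosage vectors must have equal length >= 2")
    n_carrier = int(np.sum(y))
    if np.var(x) == 0 or np.var(y) == 0:
        return CosegregationResult(r2=float("nan"), defined=False,
                                   n_carrier_haplotypes=n_carrier,
                                   archaic_source=archaic_source,
                                   variant=variant)
    r = np.corrcoef(x, y)[0, 1]
    return CosegregationResult(r2=float(r * r), defined=True,
                               n_carrier_haplotypes=n_carrier,
                               archaic_source=archaic_source,
                               variant=variant)


#: r2 below which a locus shows no archaic cosegregation
R2_SCREEN = 0.2
#: r2 above which a risk variant is called cosegregating with archaic tracts
R2_COSEGREGATING = 0.5


def classify_locus(coseg_by_source: dict[str, CosegregationResult],
                   screen: float = R2_SCREEN,
                   cosegregating: float = R2_COSEGREGATING) -> dict:
    """Classify a locus's archaic cosegregation per archaic source.

    Labels: ``"none"`` for r2 <= screen, ``"candidate"`` for
    screen < r2 <= cosegregating, ``"cosegregating"`` above that (boundary
    values fall to the lower class).  Returns per-source labels plus the
    best source and overall label under the max-r2 source.
    """
    labels, best_source, best_r2 = {}, None, -1.0
    for source, res in coseg_by_source.items():
        r2 = res.r2 if res.defined else float("nan")
        if not res.defined or not np.isfinite(r2) or r2 <= screen:
            labels[source] = "none"
        elif r2 <= cosegregating:
            labels[source] = "candidate"
        else:
            labels[source] = "cosegregating"
        if res.defined and np.isfinite(r2) and r2 > best_r2:
            best_r2, best_source = r2, source
    overall = labels[best_source] if best_source is not None else "none"
    return {"per_source": labels, "best_source": best_source,
            "best_r2": best_r2 if best_source is not None else float("nan"),
            "label": overall}
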