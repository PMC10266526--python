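"""Coalescent-free generator of panels, archaic references, phenotypes and
per-study GWAS summary statistics.

The generator produces exactly the statistical structure the downstream
analyses assume, with every knob explicit and every draw a pure function of
its seed:

* modern haplotypes are a mosaic: a neutral background plus archaic-origin
  segments of two kinds.  Introgressed tracts (gene flow ~2,000 generations
  ago) have Exponential genetic lengths with mean 100/t_admix cM and occupy
  an expected ``admix_fraction`` of each haplotype's genetic length;
  incomplete-lineage-sorting (ILS) tracts are older and shorter, with
  Gamma(shape 2, rate (2*t_div - t_admix)/100 per cM) lengths — the exact
  null of the ILS length test.
* archaic-diagnostic marker sites are scattered along the chromosome; a
  haplotype carries the archaic allele at a marker iff an archaic-origin
  segment covers it (plus a small background carrier frequency).
* the archaic reference is homozygous for the archaic allele at markers,
  an independent population draw elsewhere, and missing at random at a
  rate emulating the ~50% callability of archaic genomes.
* case-control labels follow a logistic model whose intercept is solved by
  bisection so the population prevalence is exact; per-study summary
  statistics are allelic 2x2 Wald odds ratios with Haldane correction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (ArchaicGenotypes, HaplotypePanel, MISSING,
                         RecombinationMap, TruthTract, Variant,
                         SUMSTAT_COLUMNS, write_recombination_map,
                         write_summary_stats, write_vcf)
from .meta_analysis import log10_tail_p

_BASES = ("A", "C", "G", "T")


@dataclass
class DemographyParams:
    """Demographic and marker-density knobs of the panel simulator.

    t_div_gen : generations since the modern-archaic common ancestor
        (default 21,500)
    t_admix_gen : generations since archaic admixture (default 2,000)
    admix_fraction : expected archaic-ancestry proportion per haplotype
        (default 0.02)
    n_ils_tracts_per_hap : mean ILS segment count per haplotype
    archaic_marker_rate : archaic-diagnostic sites per kb
    background_site_rate : neutral polymorphic sites per kb
    marker_background_freq : modern carrier frequency of the archaic allele
        at marker sites outside archaic-origin segments
    seed : generator seed
    """

    t_div_gen: float = 21_500.0
    t_admix_gen: float = 2_000.0
    admix_fraction: float = 0.02
    n_ils_tracts_per_hap: float = 5.0
    archaic_marker_rate: float = 0.3
    background_site_rate: float = 0.5
    marker_background_freq: float = 0.002
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.t_admix_gen < self.t_div_gen:
            raise ValueError("need 0 < t_admix_gen < t_div_gen")
        if not 0 <= self.admix_fraction <= 1:
            raise ValueError("admix_fraction must lie in [0, 1]")

    @property
    def mean_introgressed_length_cM(self) -> float:
        return 100.0 / self.t_admix_gen

    @property
    def ils_rate_per_cM(self) -> float:
        return (2.0 * self.t_div_gen - self.t_admix_gen) / 100.0


@dataclass
class PhenotypeModel:
    """Disease model: population prevalence plus per-risk-allele odds
    ratios for the causal variants."""

    prevalence: float
    causal: list  # [(Variant, odds_ratio, risk_allele), ...]

    def __post_init__(self):
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must lie in (0, 1)")
        for _, oratio, _ in self.causal:
            if oratio <= 0:
                raise ValueError("odds ratios must be > 0")


@dataclass
class StudyDesign:
    study_id: str
    n_cases: int
    n_controls: int

    def __post_init__(self):
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("case/control counts must be >= 1")


def sample_ils_lengths(rng, n: int, demography: DemographyParams) -> np.ndarray:
    """Genetic lengths (cM) of ILS tracts: Gamma(2, rate (2t_div-t_admix)/100).

    Equivalently the sum of two Exponential draws, one per branch."""
    return rng.gamma(shape=2.0, scale=1.0 / demography.ils_rate_per_cM, size=n)


def _random_alleles(rng, n: int) -> tuple[np.ndarray, np.ndarray]:
    ref = rng.integers(0, 4, size=n)
    alt = (ref + rng.integers(1, 4, size=n)) % 4
    return ref, alt


def simulate_modern_panel(demography: DemographyParams,
                          rec_map: RecombinationMap,
                          n_samples: int,
                          chrom_length_bp: int) -> HaplotypePanel:
    """Simulate a phased modern panel with annotated archaic-origin tracts.

    Sites come in two classes: neutral background sites with alt
    frequencies drawn Uniform(0.05, 0.95), and archaic-diagnostic marker
    sites where the alt (archaic) allele is rare in the background but
    fixed on archaic-origin sequence.  Tracts are placed uniformly in
    genetic coordinates and truncated at chromosome ends; ground truth is
    recorded in ``panel.truth_tracts``.  Two extra arrays are attached for
    downstream simulators: ``site_is_marker`` and ``site_background_freq``.
    """
    rng = np.random.default_rng(demography.seed)
    chrom = rec_map.chrom
    g0 = rec_map.genetic_position(1)
    g1 = rec_map.genetic_position(chrom_length_bp)
    total_cM = g1 - g0

    # site positions: two independent Poisson processes along the chromosome
    n_marker = rng.poisson(demography.archaic_marker_rate * chrom_length_bp / 1e3)
    n_bg = rng.poisson(demography.background_site_rate * chrom_length_bp / 1e3)
    pos_m = np.sort(rng.choice(np.arange(1, chrom_length_bp + 1),
                               size=n_marker, replace=False))
    pos_b = np.sort(rng.choice(np.arange(1, chrom_length_bp + 1),
                               size=n_bg, replace=False))
    pos_b = pos_b[~np.isin(pos_b, pos_m)]
    pos = np.concatenate([pos_m, pos_b])
    is_marker = np.concatenate([np.ones(pos_m.size, bool),
                                np.zeros(pos_b.size, bool)])
    order = np.argsort(pos)
    pos, is_marker = pos[order], is_marker[order]

    freq = np.where(is_marker, demography.marker_background_freq,
                    rng.uniform(0.05, 0.95, size=pos.size))
    ref, alt = _random_alleles(rng, pos.size)
    sites = [Variant(chrom, int(p), _BASES[r], _BASES[a])
             for p, r, a in zip(pos, ref, alt)]

    samples = [f"S{i:04d}" for i in range(n_samples)]
    n_hap = 2 * n_samples
    alleles = (rng.random((n_hap, pos.size)) < freq).astype(np.int8)

    # archaic-origin tracts per haplotype
    mean_mig = demography.mean_introgressed_length_cM
    exp_n_mig = demography.admix_fraction * total_cM / mean_mig
    truth = []
    for h in range(n_hap):
        sample, hap = samples[h // 2], h % 2
        tracts = []
        for _ in range(rng.poisson(exp_n_mig)):
            length = rng.exponential(mean_mig)
            tracts.append((length, "introgressed"))
        for _ in range(rng.poisson(demography.n_ils_tracts_per_hap)):
            length = sample_ils_lengths(rng, 1, demography)[0]
            tracts.append((length, "ILS"))
        for length, origin in tracts:
            g_start = rng.uniform(g0, g1)
            g_end = min(g_start + length, g1)  # truncate at chromosome end
            start_bp = int(round(rec_map.physical_position(g_start)))
            end_bp = int(round(rec_map.physical_position(g_end)))
            start_bp = max(1, min(start_bp, chrom_length_bp))
            end_bp = max(start_bp, min(end_bp, chrom_length_bp))
            truth.append(TruthTract(sample, hap, start_bp, end_bp, origin))
            covered = is_marker & (pos >= start_bp) & (pos <= end_bp)
            alleles[h, covered] = 1

    panel = HaplotypePanel(samples, sites, alleles, phased=True,
                           truth_tracts=truth)
    panel.site_is_marker = is_marker
    panel.site_background_freq = freq
    return panel


def simulate_archaic_reference(sites, missing_rate: float, seed: int,
                               diagnostic=None,
                               background_freq=None) -> ArchaicGenotypes:
    """Simulate an archaic reference genome aligned to panel sites.

    Archaic-diagnostic sites are homozygous for the archaic (alt) allele;
    all other sites are Hardy-Weinberg draws at the supplied ancestral
    frequencies (default 0.5).  Every site is then masked missing
    independently with ``missing_rate`` — archaic genomes have roughly
    half of their positions uncallable.
    """
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    n = len(sites)
    diagnostic = (np.zeros(n, bool) if diagnostic is None
                  else np.asarray(diagnostic, bool))
    freq = (np.full(n, 0.5) if background_freq is None
            else np.asarray(background_freq, float))
    gt = ((rng.random(n) < freq).astype(np.int8)
          + (rng.random(n) < freq).astype(np.int8))
    gt[diagnostic] = 2
    gt[rng.random(n) < missing_rate] = MISSING
    return ArchaicGenotypes(sites, gt, sample="archaic_sim")


def _solve_intercept(risk_scores: np.ndarray, prevalence: float) -> float:
    """Bisection for the logistic intercept giving the target mean risk."""
    def mean_risk(alpha):
        return np.mean(1.0 / (1.0 + np.exp(-(alpha + risk_scores))))

    lo, hi = -40.0, 20.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mean_risk(mid) < prevalence:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_phenotypes(panel_or_dosages, model: PhenotypeModel,
                        seed: int) -> np.ndarray:
    """Draw case/control labels under a logistic disease model.

    Per-individual risk is logistic(alpha + sum dosage_i * ln OR_i) with
    alpha calibrated by bisection so the population mean equals the model
    prevalence; labels are then independent Bernoulli draws.  Accepts a
    :class:`HaplotypePanel` or a precomputed (n_individuals, n_causal)
    dosage matrix whose columns follow ``model.causal`` order.
    """
    if isinstance(panel_or_dosages, HaplotypePanel):
        panel = panel_or_dosages
        cols = []
        for variant, _, _ in model.causal:
            try:
                cols.append(panel.site_index(variant))
            except KeyError:
                raise ValueError(f"causal variant {variant} absent from panel")
        dos = panel.dosages()[:, cols].astype(float)
    else:
        dos = np.asarray(panel_or_dosages, dtype=float)
    betas = np.array([np.log(oratio) for _, oratio, _ in model.causal])
    score = dos @ betas
    alpha = _solve_intercept(score, model.prevalence)
    risk = 1.0 / (1.0 + np.exp(-(alpha + score)))
    rng = np.random.default_rng(seed)
    return (rng.random(risk.size) < risk).astype(np.int8)


def allelic_wald(a: float, b: float, c: float, d: float) -> tuple[float, float]:
    """ln OR and se from a 2x2 allele-count table (alt/ref x case/control).

    Applies the Haldane 0.5 correction to every cell when any cell is 0.
    """
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    beta = np.log((a * d) / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return float(beta), float(se)


def simulate_study_sumstats(dosages: np.ndarray, labels: np.ndarray,
                            sites: list, design: StudyDesign, seed: int,
                            pool=None) -> pd.DataFrame:
    """Subsample one case-control study and compute per-variant summary
    statistics.

    ``dosages`` is the (n_individuals, n_sites) genotype matrix of the
    source cohort.  ``pool`` optionally restricts sampling to a subset of
    individuals (so several studies can use disjoint subjects).  Per
    variant the 2x2 allele-count table gives the Wald ln OR, its standard
    error and a two-sided p-value from z = beta/se computed in log space;
    monomorphic variants are emitted with beta 0, infinite se and flagged
    by that se.
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    idx = np.arange(labels.size) if pool is None else np.asarray(pool)
    cases = idx[labels[idx] == 1]
    controls = idx[labels[idx] == 0]
    if cases.size < design.n_cases or controls.size < design.n_controls:
        raise ValueError(
            f"study {design.study_id}: need {design.n_cases} cases / "
            f"{design.n_controls} controls, pool has {cases.size} / "
            f"{controls.size}")
    cases = rng.choice(cases, size=design.n_cases, replace=False)
    controls = rng.choice(controls, size=design.n_controls, replace=False)

    dc = dosages[cases].sum(axis=0).astype(float)       # alt alleles, cases
    du = dosages[controls].sum(axis=0).astype(float)
    n2c, n2u = 2.0 * design.n_cases, 2.0 * design.n_controls
    rows = []
    for j, v in enumerate(sites):
        a, b = dc[j], n2c - dc[j]
        c, d = du[j], n2u - du[j]
        if (a + c == 0) or (b + d == 0):                # monomorphic
            beta, se, nlp = 0.0, np.inf, 0.0
        else:
            beta, se = allelic_wald(a, b, c, d)
            nlp = log10_tail_p(beta / se)
        rows.append((v.chrom, v.pos, v.ref, v.alt, beta, se, nlp,
                     (a + c) / (n2c + n2u), design.n_cases,
                     design.n_controls))
    df = pd.DataFrame(rows, columns=SUMSTAT_COLUMNS)
    df.insert(0, "study", design.study_id)
    return df


# ---------------------------------------------------------------------------
# the bundled end-to-end fixture


def default_config() -> dict:
    """Default fixture configuration.

    Three case-control studies share five causal variants: three planted
    on archaic-introgressed haplotypes with the worked-example odds ratios
    (1.79, 1/0.72 and 1.14 per risk allele) and two on ordinary modern
    variants.  The introgression panel is desk-scale (150 diploid samples,
    a 10-Mb chromosome at 1 cM/Mb); the association cohort is larger
    (60,000 individuals, 5% prevalence) so study-level effect estimates
    are usable.
    """
    return {
        "seed": 2024,
        "chrom": "chr1",
        "chrom_length_bp": 10_000_000,
        "n_panel_samples": 150,
        "n_cohort": 60_000,
        "n_null_variants": 300,
        "prevalence": 0.05,
        "archaic_missing_rate": 0.5,
        "demography": {},
        "archaic_odds_ratios": [1.79, 1.0 / 0.72, 1.14],
        "modern_odds_ratios": [1.35, 1.25],
        "studies": [
            {"study_id": "study1", "n_cases": 900, "n_controls": 9000},
            {"study_id": "study2", "n_cases": 900, "n_controls": 9000},
            {"study_id": "study3", "n_cases": 900, "n_controls": 9000},
        ],
    }


def _pick_causal_sites(panel: HaplotypePanel, rec_map: RecombinationMap,
                       rng, n_archaic: int, n_modern: int,
                       min_spacing_bp: int = 1_200_000,
                       min_tract_cM: float = 0.03):
    """Choose well-separated causal sites.

    Archaic causal sites are marker sites whose alt-allele carriers lie
    predominantly on long (>= ``min_tract_cM``) introgressed truth tracts,
    i.e. risk alleles genuinely riding archaic haplotypes; modern causal
    sites are ordinary background variants at catalogue-typical
    frequencies.
    """
    freq = panel.dosages().mean(axis=0) / 2.0
    pos = panel.positions
    is_marker = panel.site_is_marker
    chosen: list[int] = []

    # per-haplotype coverage by long introgressed truth tracts
    hap_of = {s: i for i, s in enumerate(panel.samples)}
    covered = np.zeros_like(panel.alleles, dtype=bool)
    for t in panel.truth_tracts:
        if t.origin != "introgressed":
            continue
        length = (rec_map.genetic_position(t.end_bp)
                  - rec_map.genetic_position(t.start_bp))
        if length < min_tract_cM:
            continue
        h = 2 * hap_of[t.sample] + t.hap
        covered[h, (pos >= t.start_bp) & (pos <= t.end_bp)] = True

    alt_copies = panel.alleles.sum(axis=0)
    tagged = (panel.alleles.astype(bool) & covered).sum(axis=0)
    with np.errstate(invalid="ignore"):
        purity = np.where(alt_copies > 0, tagged / alt_copies, 0.0)
    min_copies = max(6, int(round(0.03 * panel.alleles.shape[0])))
    mod_cand = np.flatnonzero(~is_marker & (freq >= 0.20) & (freq <= 0.35))

    # strict conditions first; small panels/chromosomes may need looser
    # carrier counts, purity or spacing before every locus fits
    relaxations = [(min_copies, 0.85, min_spacing_bp),
                   (min_copies, 0.85, min_spacing_bp // 2),
                   (5, 0.8, min_spacing_bp // 2),
                   (4, 0.7, min_spacing_bp // 4),
                   (3, 0.5, min_spacing_bp // 8)]
    for copies, purity_min, spacing in relaxations:
        arch_cand = np.flatnonzero(is_marker & (alt_copies >= copies)
                                   & (freq <= 0.12)
                                   & (purity >= purity_min))
        chosen.clear()

        def admissible(j, spacing=spacing):
            return all(abs(pos[j] - pos[k]) >= spacing for k in chosen)

        ok = True
        for cand, n_want in ((arch_cand, n_archaic), (mod_cand, n_modern)):
            picked = 0
            for j in rng.permutation(cand):
                if picked == n_want:
                    break
                if admissible(j):
                    chosen.append(int(j))
                    picked += 1
            ok = ok and picked == n_want
        if ok:
            return chosen[:n_archaic], chosen[n_archaic:]
    raise RuntimeError("could not place causal variants; "
                       "enlarge the chromosome or relax spacing")


@dataclass
class Fixture:
    """In-memory bundle produced by :func:`build_fixture`."""

    config: dict
    rec_map: RecombinationMap
    panel: HaplotypePanel
    archaic: ArchaicGenotypes
    cohort_dosages: np.ndarray
    cohort_sites: list
    labels: np.ndarray
    sumstats: list          # one DataFrame per study
    causal_table: pd.DataFrame  # variant, odds_ratio, archaic flag
    phenotype_model: PhenotypeModel = None


def build_fixture(config: dict | None = None) -> Fixture:
    """Simulate the full study: panel, archaic reference, association
    cohort, labels and three studies' summary statistics.

    Deterministic given ``config['seed']``; stage seeds are fanned out
    from the master seed through a fixed SeedSequence spawn.
    """
    cfg = default_config()
    if config:
        cfg = {**cfg, **config}
    ss = np.random.SeedSequence(cfg["seed"])
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(6)]

    demography = DemographyParams(**cfg["demography"], seed=seeds[0])
    rec_map = RecombinationMap.uniform(cfg["chrom"], cfg["chrom_length_bp"])
    panel = simulate_modern_panel(demography, rec_map,
                                  cfg["n_panel_samples"],
                                  cfg["chrom_length_bp"])
    archaic = simulate_archaic_reference(
        panel.sites, cfg["archaic_missing_rate"], seeds[1],
        diagnostic=panel.site_is_marker,
        background_freq=panel.site_background_freq)

    rng = np.random.default_rng(seeds[2])
    arch_idx, mod_idx = _pick_causal_sites(
        panel, rec_map, rng, len(cfg["archaic_odds_ratios"]),
        len(cfg["modern_odds_ratios"]))
    causal_idx = arch_idx + mod_idx
    causal_or = list(cfg["archaic_odds_ratios"]) + list(cfg["modern_odds_ratios"])
    panel_freq = panel.dosages().mean(axis=0) / 2.0

    # association cohort: causal variants + null variants drawn at the
    # panel frequencies (independent sites; LD is not needed here)
    null_pool = np.flatnonzero(~np.isin(np.arange(len(panel.sites)),
                                        causal_idx)
                               & (panel_freq > 0.01) & (panel_freq < 0.99))
    null_idx = np.sort(rng.choice(null_pool, size=cfg["n_null_variants"],
                                  replace=False))
    cohort_idx = np.concatenate([np.array(causal_idx, int), null_idx])
    cohort_sites = [panel.sites[j] for j in cohort_idx]
    f = panel_freq[cohort_idx]
    n = cfg["n_cohort"]
    dosages = ((rng.random((n, f.size)) < f).astype(np.int8)
               + (rng.random((n, f.size)) < f).astype(np.int8))

    model = PhenotypeModel(
        prevalence=cfg["prevalence"],
        causal=[(panel.sites[j], oratio, panel.sites[j].alt)
                for j, oratio in zip(causal_idx, causal_or)])
    labels = simulate_phenotypes(dosages[:, :len(causal_idx)].astype(float),
                                 model, seeds[3])

    # disjoint per-study pools
    perm = np.random.default_rng(seeds[4]).permutation(n)
    pools = np.array_split(perm, len(cfg["studies"]))
    sumstats = []
    for i, st in enumerate(cfg["studies"]):
        design = StudyDesign(**st)
        sumstats.append(simulate_study_sumstats(
            dosages, labels, cohort_sites, design,
            seed=seeds[5] + i, pool=pools[i]))

    causal_table = pd.DataFrame({
        "chrom": [panel.sites[j].chrom for j in causal_idx],
        "pos": [panel.sites[j].pos for j in causal_idx],
        "ref": [panel.sites[j].ref for j in causal_idx],
        "alt": [panel.sites[j].alt for j in causal_idx],
        "odds_ratio": causal_or,
        "archaic": [True] * len(arch_idx) + [False] * len(mod_idx),
    })
    return Fixture(config=cfg, rec_map=rec_map, panel=panel, archaic=archaic,
                   cohort_dosages=dosages, cohort_sites=cohort_sites,
                   labels=labels, sumstats=sumstats,
                   causal_table=causal_table, phenotype_model=model)


def make_fixture(config: dict | None, output_dir, force: bool = False) -> dict:
    """Write the simulated study to disk and return the manifest.

    Produces panel.vcf, archaic.vcf, map.txt, one summary-statistics TSV
    per study, truth_tracts.bed and manifest.json.
    """
    out = Path(output_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} is not empty (use force=True)")
    out.mkdir(parents=True, exist_ok=True)
    fx = build_fixture(config)

    write_vcf(fx.panel, out / "panel.vcf")
    write_vcf(fx.archaic, out / "archaic.vcf")
    write_recombination_map(fx.rec_map, out / "map.txt")
    study_files = []
    for df in fx.sumstats:
        name = f"sumstats_{df['study'].iloc[0]}.tsv"
        write_summary_stats(df, out / name)
        study_files.append(name)
    with open(out / "truth_tracts.bed", "w") as fh:
        fh.write("#chrom\tstart\tend\tsample\thap\torigin\n")
        for t in sorted(fx.panel.truth_tracts,
                        key=lambda t: (t.start_bp, t.sample, t.hap)):
            fh.write(f"{fx.rec_map.chrom}\t{t.start_bp - 1}\t{t.end_bp}\t"
                     f"{t.sample}\t{t.hap}\t{t.origin}\n")
    manifest = {
        "config": fx.config,
        "causal_variants": fx.causal_table.to_dict(orient="records"),
        "n_sites": len(fx.panel.sites),
        "n_truth_tracts": len(fx.panel.truth_tracts),
        "n_truth_introgressed": sum(
            1 for t in fx.panel.truth_tracts if t.origin == "introgressed"),
        "archaic_missing_fraction": fx.archaic.missing_fraction,
        "prevalence_realized": float(np.mean(fx.labels)),
        "files": ["panel.vcf", "archaic.vcf", "map.txt",
                  *study_files, "truth_tracts.bed"],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
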