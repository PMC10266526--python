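"""Published worked-example inputs for the Dupuytren's disease analysis.

These constants are the printed results of the published three-biobank
Dupuytren's disease meta-analysis (UK Biobank, FinnGen, MGI; hg38
coordinates) that the package's worked examples and consistency checks
consume as inputs: the three Neandertal-introgressed risk loci with their
odds ratios and confidence intervals, and the nine-variant 95% credible
set of the strongest Neandertal-derived locus (the EPDR1 locus on
chromosome 7).
"""

from __future__ import annotations

import numpy as np

from .io_formats import Variant
from .heritability_prs import LocusEffect, se_from_ci


def _neg_log10(mantissa: float, exponent: int) -> float:
    """-log10 of mantissa x 10**exponent without underflow."""
    return float(-np.log10(mantissa) - exponent)


#: The three Neandertal-introgressed Dupuytren's disease risk loci:
#: (variant, odds ratio for the alt allele, 95% CI, risk allele).
#: The chr8 locus is protective on the alt allele (OR 0.72), i.e. the
#: reference G allele — the one tagging the introgressed haplotype — is
#: the risk allele.
NEANDERTAL_RISK_LOCI = [
    {"variant": Variant("chr7", 37_984_972, "G", "A", id="rs17171240"),
     "odds_ratio": 1.79, "ci": (1.71, 1.88), "risk_allele": "A",
     "neg_log10_p": _neg_log10(6.4, -132)},
    {"variant": Variant("chr8", 69_142_848, "G", "A", id="rs652483"),
     "odds_ratio": 0.72, "ci": (0.70, 0.75), "risk_allele": "G",
     "neg_log10_p": _neg_log10(9.2, -69)},
    {"variant": Variant("chr17", 13_547_115, "C", "T", id="rs34017855"),
     "odds_ratio": 1.14, "ci": (1.09, 1.20), "risk_allele": "T",
     "neg_log10_p": _neg_log10(1.1, -8)},
]


def neandertal_risk_effects() -> list[LocusEffect]:
    """The three loci as risk-allele-aligned effects with se from the CI.

    Protective printed ORs are inverted (beta = -ln OR) so every effect is
    odds-increasing; the se is recovered from the printed CI symmetrically
    on the log scale.
    """
    effects = []
    for row in NEANDERTAL_RISK_LOCI:
        beta = float(np.log(row["odds_ratio"]))
        se = se_from_ci(*row["ci"])
        if beta < 0:
            beta = -beta
        effects.append(LocusEffect(variant=row["variant"],
                                   risk_allele=row["risk_allele"],
                                   beta=beta, se=se, archaic=True))
    return effects


#: The published 95% credible set of the chromosome 7 (EPDR1) locus under
#: a single-causal-variant model: per variant the printed odds ratio and
#: p-value (as mantissa x 10**exponent) plus the published posterior
#: inclusion probability for reference.
EPDR1_CREDIBLE_SET = [
    {"variant": Variant("chr7", 37_984_972, "G", "A", id="rs17171240"),
     "odds_ratio": 1.79, "p_mantissa": 6.4, "p_exponent": -132,
     "published_pip": 0.21},
    {"variant": Variant("chr7", 37_984_802, "G", "A", id="rs2044830"),
     "odds_ratio": 1.79, "p_mantissa": 7.4, "p_exponent": -132,
     "published_pip": 0.18},
    {"variant": Variant("chr7", 37_984_011, "T", "C", id="rs117329120"),
     "odds_ratio": 1.79, "p_mantissa": 8.2, "p_exponent": -132,
     "published_pip": 0.16},
    {"variant": Variant("chr7", 37_983_798, "A", "G", id="rs117575966"),
     "odds_ratio": 1.79, "p_mantissa": 8.7, "p_exponent": -132,
     "published_pip": 0.15},
    {"variant": Variant("chr7", 37_964_710, "G", "A", id="rs117387543"),
     "odds_ratio": 1.78, "p_mantissa": 2.0, "p_exponent": -131,
     "published_pip": 0.07},
    {"variant": Variant("chr7", 37_964_701, "A", "G", id="rs114929416"),
     "odds_ratio": 1.78, "p_mantissa": 2.0, "p_exponent": -131,
     "published_pip": 0.06},
    {"variant": Variant("chr7", 37_964_907, "A", "G", id="rs79590116"),
     "odds_ratio": 1.78, "p_mantissa": 2.0, "p_exponent": -131,
     "published_pip": 0.06},
    {"variant": Variant("chr7", 37_966_121, "T", "A", id="rs75182114"),
     "odds_ratio": 1.77, "p_mantissa": 2.4, "p_exponent": -131,
     "published_pip": 0.06},
    {"variant": Variant("chr7", 37_976_920, "T", "G", id="rs74335252"),
     "odds_ratio": 1.79, "p_mantissa": 2.5, "p_exponent": -131,
     "published_pip": 0.05},
]


def epdr1_or_p_pairs() -> list[tuple[Variant, float, float]]:
    """(variant, odds_ratio, neg_log10_p) for the nine credible-set rows."""
    return [(row["variant"], row["odds_ratio"],
             _neg_log10(row["p_mantissa"], row["p_exponent"]))
            for row in EPDR1_CREDIBLE_SET]


#: Expected-contribution frequency assumptions: genome-wide archaic
#: ancestry fraction among Europeans, typical archaic-haplotype frequency
#: (half the genome carrying gene flow at ~2% ancestry gives ~4%), and the
#: GWAS-catalogue average minor allele frequency.
ARCHAIC_ANCESTRY_FRACTION = 0.02
ARCHAIC_HAPLOTYPE_FREQ = 0.04
CATALOGUE_MEAN_MAF = 0.266
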