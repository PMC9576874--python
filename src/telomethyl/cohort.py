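"""Published ENVIRONAGE cohort margins used to calibrate the simulator.

The birth cohort behind this pipeline published descriptive statistics for
its 281 analyzed mother-newborn pairs and the genomic panel of 26 candidate
ageing/telomere SNPs (rsID, position, major/minor allele).  Individual-level
data are not deposited, so these printed margins are the only calibration
anchors available: the synthetic-cohort generator draws covariates from
them, and :func:`characteristic_percentages` recomputes the published
percentages from the published counts (a pure-arithmetic check on the
descriptive layer).
"""
from __future__ import annotations

from .datamodel import GenomicPosition

N_PAIRS = 281

#: Printed category counts over the 281 analyzed pairs.
CATEGORY_COUNTS: dict[str, dict[str, int]] = {
    "sex": {"female": 139, "male": 142},
    "ethnicity": {"european": 263, "non_european": 18},
    "education": {"no_diploma": 16, "high_school": 80,
                  "college_3yr": 148, "university_4yr": 37},
    "smoking": {"never": 205, "former": 43, "current": 33},
    "parity": {"primiparous": 145, "secundiparous": 105, "multiparous": 31},
    "pregnancy_complications": {"yes": 48, "no": 233},
}

#: Printed mean +/- SD margins for continuous covariates (units in name).
CONTINUOUS_MARGINS: dict[str, tuple[float, float]] = {
    "birth_weight": (3.38, 0.48),        # kg
    "gestational_age": (39.03, 1.64),    # weeks
    "tl": (1.03, 0.20),                  # T/S ratio
    "maternal_age": (30.11, 4.17),       # years
    "pre_pregnancy_bmi": (24.03, 4.21),  # kg/m^2
    "paternal_age": (32.48, 4.99),       # years
}

#: The 26-SNP candidate panel: rsID -> (position, major, minor, gene).
SNP_PANEL: dict[str, tuple[GenomicPosition, str, str, str]] = {
    "rs1475398": (GenomicPosition("chr1", 65517574), "G", "C", "LEPR"),
    "rs1343981": (GenomicPosition("chr1", 65579645), "A", "G", "LEPR"),
    "rs10493379": (GenomicPosition("chr1", 65580244), "G", "A", "LEPR"),
    "rs6669117": (GenomicPosition("chr1", 65595389), "T", "C", "LEPR"),
    "rs11125529": (GenomicPosition("chr2", 54248729), "C", "A", "ACYP2"),
    "rs4452212": (GenomicPosition("chr2", 136258421), "G", "A", "CXCR4"),
    "rs10496799": (GenomicPosition("chr2", 139261401), "T", "C", "NXPH2"),
    "rs10936599": (GenomicPosition("chr3", 169774313), "C", "T", "TERC"),
    "rs16847897": (GenomicPosition("chr3", 169850328), "G", "C", "TERC"),
    "rs40184": (GenomicPosition("chr5", 1394962), "C", "T", "DAT1"),
    "rs2841505": (GenomicPosition("chr6", 13571363), "T", "G", "SIRT5"),
    "rs3757354": (GenomicPosition("chr6", 16235386), "C", "T", "MYLIP"),
    "rs911847": (GenomicPosition("chr6", 159647936), "G", "A", "SOD2"),
    "rs2371208": (GenomicPosition("chr7", 82708543), "G", "T", "-"),
    "rs9419958": (GenomicPosition("chr10", 103916188), "C", "T", "OBFC1"),
    "rs9420907": (GenomicPosition("chr10", 103916707), "A", "C", "OBFC1"),
    "rs511744": (GenomicPosition("chr11", 219089), "C", "T", "SIRT3"),
    "rs4764600": (GenomicPosition("chr12", 6492814), "C", "G", "GAPDH"),
    "rs17653722": (GenomicPosition("chr12", 52193734), "G", "T", "KRT80"),
    "rs4570625": (GenomicPosition("chr12", 71938143), "G", "T", "TPH2"),
    "rs1386494": (GenomicPosition("chr12", 71958763), "C", "T", "TPH2"),
    "rs2535913": (GenomicPosition("chr14", 72948525), "G", "A", "DCAF4"),
    "rs3027234": (GenomicPosition("chr17", 8232774), "C", "T", "CTC1"),
    "rs107251": (GenomicPosition("chr19", 4176088), "C", "T", "SIRT6"),
    "rs412658": (GenomicPosition("chr19", 22176638), "C", "T", "ZNF676"),
    "rs755017": (GenomicPosition("chr20", 63790269), "A", "G", "RTEL1"),
}


def percentage(count: int, total: int = N_PAIRS) -> float:
    """Percentage of ``count`` over ``total``, rounded to one decimal."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= count <= total:
        raise ValueError(f"count {count} outside [0, {total}]")
    return round(100.0 * count / total, 1)


def category_percentages(counts: dict[str, dict[str, int]] | None = None,
                         total: int = N_PAIRS) -> dict[str, dict[str, float]]:
    """Per-level percentages for every categorical characteristic."""
    counts = CATEGORY_COUNTS if counts is None else counts
    return {char: {lvl: percentage(n, total) for lvl, n in levels.items()}
            for char, levels in counts.items()}


def characteristic_percentages() -> dict[str, float]:
    """The headline cohort percentages, recomputed from the printed counts.

    Returns the single summary percentage per characteristic: European
    ethnicity, higher education (3-year college or university), primiparity,
    any pregnancy complication, and smoking during pregnancy.
    """
    c = CATEGORY_COUNTS
    return {
        "ethnicity_european": percentage(c["ethnicity"]["european"]),
        "education_higher": percentage(
            c["education"]["college_3yr"] + c["education"]["university_4yr"]),
        "parity_primiparous": percentage(c["parity"]["primiparous"]),
        "pregnancy_complications": percentage(
            c["pregnancy_complications"]["yes"]),
        "smoking_during_pregnancy": percentage(c["smoking"]["current"]),
    }


def category_probabilities(char: str) -> dict[str, float]:
    """Sampling probabilities for one characteristic (counts / N)."""
    counts = CATEGORY_COUNTS[char]
    total = sum(counts.values())
    return {lvl: n / total for lvl, n in counts.items()}
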