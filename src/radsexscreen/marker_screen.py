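"""Discovery screen: exclusive tags, SNP-sex association, heterogamety call.

The screen has two arms.  The tag arm flags RAD tags present in every
individual of one phenotypic sex and absent from the other (with optional
tolerances for missing data).  The SNP arm tests each biallelic locus for
association between genotype and phenotypic sex: the genotype table is
collapsed to heterozygous vs homozygous — heterozygosity of one sex being
exactly the signature of a ZW (or, mirrored, XY) system — and a two-sided
Fisher exact test is applied, using the minimum-likelihood rule (sum of all
tables at the observed margins whose point probability does not exceed the
observed table's).  Loci are ranked by ascending p-value, and the genotype
pattern of the top candidates classifies the heterogametic system.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genotype_io import (
    GenotypeMatrix,
    MISSING_GENOTYPE,
    Sex,
    SexLabels,
    TagMatrix,
    TagState,
)

log = logging.getLogger("radsexscreen")

DEFAULT_MIN_DEPTH = 3  # single-read presence is indistinguishable from noise
DEFAULT_TOP_K = 10

GENOTYPE_CLASSES = ("hom_ref", "het", "hom_alt")


@dataclass
class TagCandidate:
    """A sex-exclusive tag: present in the target-sex cohort, absent elsewhere."""

    tag_id: str
    specificity_sex: Sex
    n_present_target: int
    n_absent_other: int
    n_missing: int


@dataclass
class SnpCandidate:
    """A locus with its sex-association statistics.

    ``counts_by_sex`` maps 'female'/'male' to (hom-ref, het, hom-alt)
    genotype counts with missing individuals excluded.  ``p_value`` is the
    primary het/hom-collapse Fisher p; ``p_value_2x3`` the secondary exact p
    on the full sex x genotype table; ``q_value`` the Benjamini-Hochberg
    adjusted p across all tested loci.
    """

    locus_id: str
    counts_by_sex: dict[str, tuple[int, int, int]]
    p_value: float
    p_value_2x3: float = float("nan")
    q_value: float = float("nan")
    heterogamety_call: str = "inconclusive"


# ---------------------------------------------------------------------------
# Presence calling
# ---------------------------------------------------------------------------


def call_presence(tags: TagMatrix, min_depth: int = DEFAULT_MIN_DEPTH) -> TagMatrix:
    """Re-call tag states from read depth.

    depth >= min_depth -> present; 0 < depth < min_depth -> missing
    (too shallow to call either way); depth == 0 -> absent.
    """
    if tags.depth is None:
        raise ValueError("tag matrix has no depth; use the pre-called states")
    if min_depth < 1:
        raise ValueError("min_depth must be a positive integer")
    state = np.where(
        tags.depth >= min_depth, np.int8(TagState.PRESENT),
        np.where(tags.depth > 0, np.int8(TagState.MISSING), np.int8(TagState.ABSENT)),
    )
    return TagMatrix(list(tags.tag_ids), list(tags.individual_ids), state,
                     tags.depth.copy())


# ---------------------------------------------------------------------------
# Exclusive-tag screen
# ---------------------------------------------------------------------------


def screen_exclusive_tags(tags: TagMatrix, labels: SexLabels,
                          max_missing_target: int = 0,
                          max_present_other: int = 0) -> list[TagCandidate]:
    """Find tags exclusive to one phenotypic sex.

    A tag is a male candidate iff it is present in every male (allowing up
    to ``max_missing_target`` missing calls, none absent) and present in at
    most ``max_present_other`` females; female candidates mirror this.  The
    strict defaults (0, 0) implement the all-present vs all-absent rule.
    Unknown-sex individuals are ignored.  Output is sorted by tag_id.
    """
    col = {ind: j for j, ind in enumerate(tags.individual_ids)}
    females = [col[i] for i in labels.ids_of(Sex.FEMALE) if i in col]
    males = [col[i] for i in labels.ids_of(Sex.MALE) if i in col]
    if not females or not males:
        raise ValueError("need at least one labeled individual of each sex "
                         "present in the tag matrix")

    out: list[TagCandidate] = []
    for i, tag_id in enumerate(tags.tag_ids):
        row = tags.state[i]
        for target_sex, target, other in ((Sex.MALE, males, females),
                                          (Sex.FEMALE, females, males)):
            t = row[target]
            o = row[other]
            n_missing = int((t == TagState.MISSING).sum())
            n_absent_target = int((t == TagState.ABSENT).sum())
            n_present_other = int((o == TagState.PRESENT).sum())
            if (n_absent_target == 0 and n_missing <= max_missing_target
                    and n_present_other <= max_present_other):
                out.append(TagCandidate(
                    tag_id=tag_id,
                    specificity_sex=target_sex,
                    n_present_target=int((t == TagState.PRESENT).sum()),
                    n_absent_other=int((o == TagState.ABSENT).sum()),
                    n_missing=n_missing + int((o == TagState.MISSING).sum()),
                ))
    out.sort(key=lambda c: c.tag_id)
    return out


# ---------------------------------------------------------------------------
# SNP-sex association
# ---------------------------------------------------------------------------


def fisher_exact_2x2(table: np.ndarray | list[list[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 table (minimum-likelihood rule)."""
    return float(stats.fisher_exact(np.asarray(table), alternative="two-sided")[1])


def exact_2x3_p(counts_female: tuple[int, int, int],
                counts_male: tuple[int, int, int]) -> float:
    """Exact conditional p for a 2x3 sex x genotype table.

    Sums the multivariate hypergeometric point probabilities, over all
    tables with the observed margins, of every table whose probability does
    not exceed the observed one (Freeman-Halton generalization of the
    two-sided Fisher rule).  Computed with exact integer arithmetic.
    """
    cf, cm = list(counts_female), list(counts_male)
    col = [f + m for f, m in zip(cf, cm)]
    nf = sum(cf)
    n = nf + sum(cm)
    if nf == 0 or nf == n:
        return 1.0

    def weight(a: int, b: int) -> int:
        c = nf - a - b
        if c < 0 or c > col[2]:
            return 0
        return math.comb(col[0], a) * math.comb(col[1], b) * math.comb(col[2], c)

    obs = weight(cf[0], cf[1])
    total = 0
    extreme = 0
    for a in range(col[0] + 1):
        for b in range(col[1] + 1):
            w = weight(a, b)
            total += w
            if w <= obs:
                extreme += w
    return extreme / total


def snp_sex_association(genotypes: GenotypeMatrix, labels: SexLabels
                        ) -> list[SnpCandidate]:
    """Test every locus for genotype-sex association.

    Per locus the sex x {hom-ref, het, hom-alt} count table is built with
    missing genotypes excluded, collapsed to sex x {het, hom} and tested
    with the two-sided Fisher exact test (primary p); the full 2x3 exact p
    is reported alongside.  Monomorphic loci and loci with an ungenotyped
    sex are skipped with a logged reason.  Benjamini-Hochberg q-values are
    computed across all tested loci; the result is sorted ascending by
    (p_value, locus_id).
    """
    females = set(labels.ids_of(Sex.FEMALE))
    males = set(labels.ids_of(Sex.MALE))
    sex_of = [
        "female" if ind in females else "male" if ind in males else None
        for ind in genotypes.individual_ids
    ]

    candidates: list[SnpCandidate] = []
    for i, locus in enumerate(genotypes.loci):
        hom_ref = f"{locus.ref_allele}/{locus.ref_allele}"
        hom_alt = f"{locus.alt_allele}/{locus.alt_allele}"
        counts = {"female": [0, 0, 0], "male": [0, 0, 0]}
        observed_alleles: set[str] = set()
        for j, sex in enumerate(sex_of):
            if sex is None:
                continue
            g = genotypes.genotype[i, j]
            if g == MISSING_GENOTYPE:
                continue
            observed_alleles.update(g.split("/"))
            cls = 0 if g == hom_ref else 2 if g == hom_alt else 1
            counts[sex][cls] += 1
        nf, nm = sum(counts["female"]), sum(counts["male"])
        if nf == 0 or nm == 0:
            log.info("locus %s skipped: no genotyped %s", locus.locus_id,
                     "females" if nf == 0 else "males")
            continue
        if len(observed_alleles) < 2:
            log.info("locus %s skipped: monomorphic", locus.locus_id)
            continue
        het_f, het_m = counts["female"][1], counts["male"][1]
        table = [[het_f, nf - het_f], [het_m, nm - het_m]]
        candidates.append(SnpCandidate(
            locus_id=locus.locus_id,
            counts_by_sex={s: tuple(c) for s, c in counts.items()},
            p_value=fisher_exact_2x2(table),
            p_value_2x3=exact_2x3_p(tuple(counts["female"]), tuple(counts["male"])),
        ))

    if candidates:
        qvals = multipletests([c.p_value for c in candidates], method="fdr_bh")[1]
        for cand, q in zip(candidates, qvals):
            cand.q_value = float(q)
    candidates.sort(key=lambda c: (c.p_value, c.locus_id))
    for cand in candidates:
        cand.heterogamety_call = classify_heterogamety(cand)
    return candidates


def select_top_k(candidates: list[SnpCandidate], k: int = DEFAULT_TOP_K
                 ) -> list[SnpCandidate]:
    """First k candidates by ascending (p_value, locus_id)."""
    if k <= 0:
        raise ValueError("k must be a positive integer")
    ranked = sorted(candidates, key=lambda c: (c.p_value, c.locus_id))
    if k > len(ranked):
        log.warning("top-k saturated: k=%d but only %d candidates", k, len(ranked))
    return ranked[:k]


def classify_heterogamety(candidate: SnpCandidate, min_fraction: float = 1.0) -> str:
    """Call the heterogametic system from one locus's genotype pattern.

    ZW iff at least ``min_fraction`` of genotyped females are heterozygous
    AND at least that fraction of males are homozygous; XY for the mirror
    image; otherwise inconclusive.
    """
    cf = candidate.counts_by_sex.get("female", (0, 0, 0))
    cm = candidate.counts_by_sex.get("male", (0, 0, 0))
    nf, nm = sum(cf), sum(cm)
    if nf == 0 or nm == 0:
        log.info("locus %s: heterogamety inconclusive (a sex has no genotypes)",
                 candidate.locus_id)
        return "inconclusive"
    het_frac_f = cf[1] / nf
    het_frac_m = cm[1] / nm
    if het_frac_f >= min_fraction and 1 - het_frac_m >= min_fraction:
        return "ZW"
    if het_frac_m >= min_fraction and 1 - het_frac_f >= min_fraction:
        return "XY"
    return "inconclusive"
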