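"""Validation-population statistics at a single sex-linked locus.

Given one genotyped marker and phenotypic sex calls for a breeding
population, this module computes the genotype x sex contingency table, the
dominant (modal) genotype of each sex with its fraction, the overall
genotype-phenotype consistency, the list of discordant individuals, an
exact binomial test of the sex ratio against 1:1, and a two-parameter
maximum-likelihood model that explains off-pattern genotypes by a
Z-chromosome alternate-allele frequency q and a phenotype-genotype
discordance (sex-reversal) probability r.

All fractions use the full per-sex cohort of genotyped individuals as the
denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
from scipy import stats
from scipy.optimize import minimize_scalar

from .genotype_io import MISSING_GENOTYPE, Sex, SexLabels

log = logging.getLogger("radsexscreen")

GRID_STEP = 0.005  # coarse-grid resolution on both q and r axes
R_MAX = 0.5


def _round_half_up(x: float, ndigits: int) -> float:
    return float(Decimal(repr(x)).quantize(Decimal(f"1e-{ndigits}"),
                                           rounding=ROUND_HALF_UP))


@dataclass
class ConcordanceReport:
    """Genotype x phenotypic-sex concordance at one locus."""

    contingency: dict[str, dict[str, int]]  # sex -> genotype -> count
    dominant_genotype_by_sex: dict[str, str]
    per_sex_dominant_fraction: dict[str, float]  # 4-decimal proportions
    per_sex_dominant_percent: dict[str, float]  # 2-decimal percents
    overall_consistency: float  # 4-decimal proportion
    overall_consistency_percent: float
    discordant_ids: list[str]
    n_total: int
    n_missing: int
    notes: list[str]


@dataclass
class SexRatioResult:
    """Exact binomial test of a female:male count against 1:1."""

    n_female: int
    n_male: int
    ratio_text: str  # "x:1", female:male orientation, x to 2 decimals
    p_two_sided: float


@dataclass
class LinkageFit:
    """Maximum-likelihood (q, r) under the ZW linkage/discordance model."""

    q_hat: float
    r_hat: float
    log_likelihood: float
    log_likelihood_r0: float
    lrt_p_value: float  # boundary-mixture approximation, see fit_zw_linkage
    converged: bool


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------


def build_concordance(genotypes_at_locus: dict[str, str],
                      labels: SexLabels) -> ConcordanceReport:
    """Tabulate genotype against phenotypic sex and measure concordance.

    The dominant genotype of a sex is its modal genotype (ties broken by
    the lexicographically smallest genotype, logged and noted).  The
    per-sex dominant fraction divides by all genotyped individuals of that
    sex; overall consistency is the summed dominant counts over all
    genotyped individuals.  Discordant individuals carry a genotype other
    than their sex's dominant one.  Missing genotypes are excluded and
    counted separately.
    """
    notes: list[str] = []
    contingency: dict[str, dict[str, int]] = {"female": {}, "male": {}}
    carriers: dict[tuple[str, str], list[str]] = {}
    n_missing = 0
    for ind, sex in labels.sex_by_id.items():
        if sex is Sex.UNKNOWN:
            continue
        g = genotypes_at_locus.get(ind, MISSING_GENOTYPE)
        if g == MISSING_GENOTYPE:
            n_missing += 1
            continue
        contingency[sex.value][g] = contingency[sex.value].get(g, 0) + 1
        carriers.setdefault((sex.value, g), []).append(ind)

    for sex_name, table in contingency.items():
        if not table:
            raise ValueError(f"no genotyped {sex_name} individuals")

    dominant: dict[str, str] = {}
    for sex_name, table in contingency.items():
        top = max(table.values())
        modal = sorted(g for g, c in table.items() if c == top)
        dominant[sex_name] = modal[0]
        if len(modal) > 1:
            msg = (f"dominant-genotype tie in {sex_name}s between "
                   f"{', '.join(modal)}; kept {modal[0]} (lexicographic rule)")
            log.warning(msg)
            notes.append(msg)

    n_by_sex = {s: sum(t.values()) for s, t in contingency.items()}
    n_total = sum(n_by_sex.values())
    dom_counts = {s: contingency[s][dominant[s]] for s in contingency}
    fractions = {s: _round_half_up(dom_counts[s] / n_by_sex[s], 4) for s in contingency}
    percents = {s: _round_half_up(100 * dom_counts[s] / n_by_sex[s], 2)
                for s in contingency}
    consistency = sum(dom_counts.values()) / n_total
    discordant = sorted(
        ind
        for (sex_name, g), inds in carriers.items()
        if g != dominant[sex_name]
        for ind in inds
    )
    return ConcordanceReport(
        contingency=contingency,
        dominant_genotype_by_sex=dominant,
        per_sex_dominant_fraction=fractions,
        per_sex_dominant_percent=percents,
        overall_consistency=_round_half_up(consistency, 4),
        overall_consistency_percent=_round_half_up(100 * consistency, 2),
        discordant_ids=discordant,
        n_total=n_total,
        n_missing=n_missing,
        notes=notes,
    )


# ---------------------------------------------------------------------------
# Sex ratio
# ---------------------------------------------------------------------------


def sex_ratio_test(n_female: int, n_male: int) -> SexRatioResult:
    """Exact two-sided binomial test of the female:male split against 1:1.

    The p-value sums Binomial(n, 0.5) point masses not exceeding the
    observed count's mass.  ``ratio_text`` is female:male with the quotient
    rounded half-up to 2 decimals ("inf:1" when there are no males).
    """
    n = n_female + n_male
    if n < 1:
        raise ValueError("need at least one individual")
    if n_male == 0:
        ratio_text = "inf:1"
    else:
        ratio_text = f"{_round_half_up(n_female / n_male, 2):.2f}:1"
    p = float(stats.binomtest(n_female, n, 0.5, alternative="two-sided").pvalue)
    return SexRatioResult(n_female=n_female, n_male=n_male,
                          ratio_text=ratio_text, p_two_sided=min(p, 1.0))


# ---------------------------------------------------------------------------
# ZW linkage / discordance likelihood model
# ---------------------------------------------------------------------------


def genotype_class_counts(contingency: dict[str, dict[str, int]],
                          ref_allele: str, alt_allele: str
                          ) -> tuple[tuple[int, int, int], tuple[int, int, int]]:
    """Collapse a concordance contingency to per-sex [hom-ref, het, hom-alt]."""
    hom_ref = f"{ref_allele}/{ref_allele}"
    hom_alt = f"{alt_allele}/{alt_allele}"
    out = []
    for sex_name in ("female", "male"):
        table = contingency.get(sex_name, {})
        counts = [0, 0, 0]
        for g, c in table.items():
            counts[0 if g == hom_ref else 2 if g == hom_alt else 1] += c
        out.append(tuple(counts))
    return out[0], out[1]


def genotype_probs_female(q: float) -> np.ndarray:
    """ZW female law over [hom-ref, het, hom-alt]: W fixed for alt, Z alt freq q."""
    return np.array([0.0, 1.0 - q, q])


def genotype_probs_male(q: float) -> np.ndarray:
    """ZZ male Hardy-Weinberg law over [hom-ref, het, hom-alt]."""
    return np.array([(1.0 - q) ** 2, 2.0 * q * (1.0 - q), q ** 2])


def mixture_probs(q: float, r: float) -> tuple[np.ndarray, np.ndarray]:
    """Genotype laws of phenotypic females and males under discordance r."""
    f, m = genotype_probs_female(q), genotype_probs_male(q)
    return (1 - r) * f + r * m, (1 - r) * m + r * f


def _log_likelihood(q: float, r: float, counts_female: np.ndarray,
                    counts_male: np.ndarray) -> float:
    pf, pm = mixture_probs(q, r)
    ll = 0.0
    for counts, probs in ((counts_female, pf), (counts_male, pm)):
        for c, p in zip(counts, probs):
            if c > 0:
                if p <= 0.0:
                    return -np.inf
                ll += c * np.log(p)
    return float(ll)


def fit_zw_linkage(counts_female, counts_male) -> LinkageFit:
    """Maximize the multinomial likelihood over (q, r) in [0,1] x [0,0.5].

    Phenotypic-female genotype probabilities are (1-r) F(q) + r M(q) and
    phenotypic-male probabilities (1-r) M(q) + r F(q), where F is the ZW
    female law and M the Hardy-Weinberg male law (1:1 genetic-sex prior).
    Optimization is a coarse grid (step 0.005 on both axes) followed by
    coordinate-wise golden-section refinement.  The r=0 constrained model
    is fitted the same way for a likelihood-ratio comparison whose p-value
    uses the 0.5 chi2(0) + 0.5 chi2(1) boundary mixture — approximate,
    because r sits on the parameter boundary under the null.
    """
    cf = np.asarray(counts_female, dtype=float)
    cm = np.asarray(counts_male, dtype=float)
    if cf.shape != (3,) or cm.shape != (3,):
        raise ValueError("counts must be length-3 [hom-ref, het, hom-alt]")
    degenerate = int((cf > 0).sum() + (cm > 0).sum()) <= 1

    q_grid = np.arange(0.0, 1.0 + GRID_STEP / 2, GRID_STEP)
    r_grid = np.arange(0.0, R_MAX + GRID_STEP / 2, GRID_STEP)
    ll_grid = np.array([[_log_likelihood(q, r, cf, cm) for r in r_grid]
                        for q in q_grid])
    iq, ir = np.unravel_index(np.argmax(ll_grid), ll_grid.shape)
    q_hat, r_hat = float(q_grid[iq]), float(r_grid[ir])
    q_hat, r_hat, ll = _refine(q_hat, r_hat, cf, cm)

    iq0 = int(np.argmax(ll_grid[:, 0]))
    q0, _, ll0 = _refine(float(q_grid[iq0]), 0.0, cf, cm, fix_r=True)
    ll0 = max(ll0, _log_likelihood(q0, 0.0, cf, cm))
    if ll0 > ll:  # the r=0 profile is a restriction; never let it win
        q_hat, r_hat, ll = q0, 0.0, ll0

    lrt = max(0.0, 2.0 * (ll - ll0))
    lrt_p = 1.0 if lrt == 0.0 else 0.5 * float(stats.chi2.sf(lrt, df=1))
    return LinkageFit(q_hat=q_hat, r_hat=r_hat, log_likelihood=ll,
                      log_likelihood_r0=ll0, lrt_p_value=lrt_p,
                      converged=not degenerate)


def _refine(q: float, r: float, cf: np.ndarray, cm: np.ndarray,
            fix_r: bool = False, passes: int = 3) -> tuple[float, float, float]:
    """Coordinate-wise golden-section polish within one grid step per axis."""
    for _ in range(passes):
        lo, hi = max(0.0, q - GRID_STEP), min(1.0, q + GRID_STEP)
        res = minimize_scalar(lambda x: -_log_likelihood(x, r, cf, cm),
                              bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-10})
        if np.isfinite(res.fun) and -res.fun >= _log_likelihood(q, r, cf, cm):
            q = float(res.x)
        if not fix_r:
            lo, hi = max(0.0, r - GRID_STEP), min(R_MAX, r + GRID_STEP)
            res = minimize_scalar(lambda x: -_log_likelihood(q, x, cf, cm),
                                  bounds=(lo, hi), method="bounded",
                                  options={"xatol": 1e-10})
            if np.isfinite(res.fun) and -res.fun >= _log_likelihood(q, r, cf, cm):
                r = float(res.x)
    return q, r, _log_likelihood(q, r, cf, cm)
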