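"""Simulator for tag and genotype matrices under ZW heterogamety.

The generator emulates the statistical structure the downstream screen
assumes: genetic females are ZW and genetic males ZZ; at every sex-linked
locus the W chromosome carries the alternate allele fixed while the Z
chromosome carries it at frequency ``q``; phenotypic sex disagrees with
genetic sex ("sex reversal") with probability ``r``; planted sex-exclusive
tags are present in every genetic individual of the target sex and absent
in the other; background tags, per-tag read depth and missing data fill in
realistic noise.  One seeded generator drives everything, so a given
configuration is byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .genotype_io import (
    GenotypeMatrix,
    LocusInfo,
    Sex,
    SexLabels,
    TagMatrix,
    TagState,
    canonical_genotype,
    write_genotype_table,
    write_json_report,
    write_sex_labels,
    write_tag_matrix,
)

BACKGROUND_TAG_PRESENCE = 0.95  # presence probability of a non-sex-linked tag


class ConfigError(ValueError):
    """A simulation configuration is internally inconsistent."""


@dataclass
class SimConfig:
    """Parameters of one simulated study population.

    ``n_female``/``n_male`` are *phenotypic* cohort sizes and are hit
    exactly.  ``q`` is the Z-chromosome alternate-allele frequency, ``r``
    the phenotype-genotype discordance (sex-reversal) probability.
    Defaults mirror the discovery-cohort design: 10 phenotypic females and
    10 males, a 1,000-tag matrix carrying a handful of planted exclusive
    tags, 200 loci of which 10 are sex-linked, mean tag depth ~34x.
    """

    n_female: int = 10
    n_male: int = 10
    n_tags: int = 1000
    n_sexlinked_tags_male: int = 5
    n_sexlinked_tags_female: int = 3
    n_loci: int = 200
    n_sexlinked_loci: int = 10
    q: float = 0.0
    r: float = 0.0
    missing_rate: float = 0.0
    mean_depth: float = 33.75
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_female < 0 or self.n_male < 0:
            raise ConfigError("cohort sizes must be non-negative")
        if self.n_sexlinked_tags_male + self.n_sexlinked_tags_female > self.n_tags:
            raise ConfigError("more planted exclusive tags than tags")
        if self.n_sexlinked_loci > self.n_loci:
            raise ConfigError("n_sexlinked_loci exceeds n_loci")
        if not 0.0 <= self.q <= 1.0:
            raise ConfigError("q must lie in [0, 1]")
        if not 0.0 <= self.r <= 0.5:
            raise ConfigError("r must lie in [0, 0.5]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate must lie in [0, 1)")
        if self.mean_depth <= 0:
            raise ConfigError("mean_depth must be positive")


@dataclass
class SimTruth:
    """Ground truth of one simulated population."""

    genetic_sex: dict[str, Sex]
    male_exclusive_tags: list[str]
    female_exclusive_tags: list[str]
    sexlinked_loci: list[str]
    discordant_ids: list[str]


def simulate_population(config: SimConfig) -> tuple[TagMatrix, GenotypeMatrix,
                                                    SexLabels, SimTruth]:
    """Draw one population under the ZW model.

    Phenotypic cohort sizes are exact by construction: with a 1:1 genetic-
    sex prior and flip probability ``r``, the genetic sex of a phenotypic
    female is female with probability 1-r, so genetic sex is drawn
    conditionally per individual instead of flipping and rejecting.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_female + config.n_male

    ids = [f"F{i + 1}" for i in range(config.n_female)] + \
          [f"M{i + 1}" for i in range(config.n_male)]
    phenotype = [Sex.FEMALE] * config.n_female + [Sex.MALE] * config.n_male
    labels = SexLabels(dict(zip(ids, phenotype)))

    concordant = rng.random(n) >= config.r
    genetic = [ph if ok else (Sex.MALE if ph is Sex.FEMALE else Sex.FEMALE)
               for ph, ok in zip(phenotype, concordant)]
    is_gfemale = np.array([s is Sex.FEMALE for s in genetic])
    discordant_ids = [i for i, ok in zip(ids, concordant) if not ok]

    tags = _simulate_tags(config, rng, ids, is_gfemale)
    genotypes, sexlinked_ids = _simulate_genotypes(config, rng, ids, is_gfemale)

    truth = SimTruth(
        genetic_sex=dict(zip(ids, genetic)),
        male_exclusive_tags=[f"tag{k + 1}" for k in range(config.n_sexlinked_tags_male)],
        female_exclusive_tags=[
            f"tag{k + 1}" for k in range(config.n_sexlinked_tags_male,
                                         config.n_sexlinked_tags_male
                                         + config.n_sexlinked_tags_female)],
        sexlinked_loci=sexlinked_ids,
        discordant_ids=discordant_ids,
    )
    return tags, genotypes, labels, truth


def _simulate_tags(config: SimConfig, rng: np.random.Generator,
                   ids: list[str], is_gfemale: np.ndarray) -> TagMatrix:
    n = len(ids)
    n_excl = config.n_sexlinked_tags_male + config.n_sexlinked_tags_female
    tag_ids = [f"tag{k + 1}" for k in range(config.n_tags)]
    present = np.zeros((config.n_tags, n), dtype=bool)
    present[:config.n_sexlinked_tags_male, :] = ~is_gfemale
    present[config.n_sexlinked_tags_male:n_excl, :] = is_gfemale
    present[n_excl:, :] = rng.random((config.n_tags - n_excl, n)) < BACKGROUND_TAG_PRESENCE

    # Poisson depth truncated at >=1 for present tags (resample zeros).
    depth = np.zeros(present.shape, dtype=np.int64)
    d = rng.poisson(config.mean_depth, size=int(present.sum()))
    while (zero := d == 0).any():
        d[zero] = rng.poisson(config.mean_depth, size=int(zero.sum()))
    depth[present] = d

    state = np.where(present, np.int8(TagState.PRESENT), np.int8(TagState.ABSENT))
    if config.missing_rate > 0:
        mask = rng.random(present.shape) < config.missing_rate
        state[mask] = TagState.MISSING
        depth[mask] = 0
    return TagMatrix(tag_ids, list(ids), state, depth)


def _genotype_probs_female(q: float) -> np.ndarray:
    """ZW female genotype law over [hom-ref, het, hom-alt]; W fixed for alt."""
    return np.array([0.0, 1.0 - q, q])


def _genotype_probs_male(q: float) -> np.ndarray:
    """ZZ male Hardy-Weinberg law over [hom-ref, het, hom-alt]."""
    return np.array([(1 - q) ** 2, 2 * q * (1 - q), q ** 2])


def _simulate_genotypes(config: SimConfig, rng: np.random.Generator,
                        ids: list[str], is_gfemale: np.ndarray
                        ) -> tuple[GenotypeMatrix, list[str]]:
    n = len(ids)
    loci: list[LocusInfo] = []
    rows = np.empty((config.n_loci, n), dtype=object)
    sexlinked_ids: list[str] = []
    bases = np.array(list("ACGT"))

    pf = _genotype_probs_female(config.q)
    pm = _genotype_probs_male(config.q)
    for i in range(config.n_loci):
        sexlinked = i < config.n_sexlinked_loci
        if sexlinked:
            ref, alt = "G", "A"  # the validated marker's alleles
        else:
            ref, alt = rng.choice(bases, size=2, replace=False)
        locus_id = f"snp{i + 1}"
        loci.append(LocusInfo(locus_id, f"scaffold{i + 1}", 100 + i, str(ref), str(alt)))
        if sexlinked:
            sexlinked_ids.append(locus_id)
            codes = np.where(
                is_gfemale,
                rng.choice(3, size=n, p=pf),
                rng.choice(3, size=n, p=pm),
            )
        else:
            p_alt = rng.uniform(0.1, 0.9)
            hw = np.array([(1 - p_alt) ** 2, 2 * p_alt * (1 - p_alt), p_alt ** 2])
            codes = rng.choice(3, size=n, p=hw)
        geno = {0: canonical_genotype(ref, ref),
                1: canonical_genotype(ref, alt),
                2: canonical_genotype(alt, alt)}
        rows[i, :] = [geno[int(c)] for c in codes]

    if config.missing_rate > 0:
        mask = rng.random(rows.shape) < config.missing_rate
        rows[mask] = "./."
    return GenotypeMatrix(loci, list(ids), rows), sexlinked_ids


# ---------------------------------------------------------------------------
# Fixture emission
# ---------------------------------------------------------------------------


def write_fixture_set(config: SimConfig, out_dir: str | Path) -> Path:
    """Simulate one population and write it as TSV fixtures plus a manifest.

    Emits ``tags.tsv``, ``tag_depth.tsv``, ``genotypes.tsv``,
    ``sex_labels.tsv`` and ``truth.json``; ``manifest.json`` lists every
    emitted file with its SHA-256 checksum.  Same config (same seed) gives
    identical checksums.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tags, genotypes, labels, truth = simulate_population(config)

    files = {
        "tags": write_tag_matrix(tags, out_dir / "tags.tsv",
                                 depth_path=out_dir / "tag_depth.tsv"),
        "tag_depth": out_dir / "tag_depth.tsv",
        "genotypes": write_genotype_table(genotypes, out_dir / "genotypes.tsv"),
        "sex_labels": write_sex_labels(labels, out_dir / "sex_labels.tsv"),
        "truth": write_json_report(
            {
                "genetic_sex": {k: v.value for k, v in truth.genetic_sex.items()},
                "male_exclusive_tags": truth.male_exclusive_tags,
                "female_exclusive_tags": truth.female_exclusive_tags,
                "sexlinked_loci": truth.sexlinked_loci,
                "discordant_ids": truth.discordant_ids,
            },
            out_dir / "truth.json",
        ),
    }
    manifest = {
        "config": asdict(config),
        "files": {
            name: {"path": p.name, "sha256": _sha256(p)} for name, p in files.items()
        },
    }
    return write_json_report(manifest, out_dir / "manifest.json")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()
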