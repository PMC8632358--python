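"""Readers and writers for the on-disk formats the pipeline consumes.

Tab-separated tag presence/absence matrices, biallelic genotype matrices
(TSV or a minimal VCF 4.x subset), phenotypic sex labels, FASTA sequences
and JSON reports.  All genomic coordinates are 1-based inclusive (VCF
convention).  Genotypes are unordered allele pairs; the canonical text form
sorts the two alleles lexicographically, so ``G/A`` and ``A/G`` are the
same genotype and serialize as ``A/G``.  Missing genotypes are ``./.``.
"""

from __future__ import annotations

import enum
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("radsexscreen")

MISSING_GENOTYPE = "./."
VALID_BASES = frozenset("ACGT")


class FormatError(ValueError):
    """A file violates the expected dialect (malformed cell, bad header...)."""


class BiallelicViolationError(FormatError):
    """More than two distinct alleles observed at a single locus."""


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"
    UNKNOWN = "unknown"


_SEX_TOKENS = {
    "f": Sex.FEMALE,
    "female": Sex.FEMALE,
    "m": Sex.MALE,
    "male": Sex.MALE,
    "u": Sex.UNKNOWN,
    "unknown": Sex.UNKNOWN,
}


class TagState(enum.IntEnum):
    ABSENT = 0
    PRESENT = 1
    MISSING = -1


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LocusInfo:
    """Coordinates and alleles of one biallelic SNP locus (1-based position)."""

    locus_id: str
    scaffold: str
    position: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"locus {self.locus_id}: position must be >= 1")
        for name in ("ref_allele", "alt_allele"):
            base = getattr(self, name)
            if base not in VALID_BASES:
                raise ValueError(f"locus {self.locus_id}: {name} {base!r} not in A/C/G/T")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"locus {self.locus_id}: ref and alt alleles are identical")


@dataclass
class SexLabels:
    """Phenotypic sex per individual; ids are unique."""

    sex_by_id: dict[str, Sex]

    def __post_init__(self) -> None:
        if len(self.sex_by_id) == 0:
            raise ValueError("empty sex-label table")

    @property
    def individual_ids(self) -> list[str]:
        return list(self.sex_by_id)

    def ids_of(self, sex: Sex) -> list[str]:
        return [i for i, s in self.sex_by_id.items() if s is sex]

    def counts(self) -> dict[Sex, int]:
        out = {s: 0 for s in Sex}
        for s in self.sex_by_id.values():
            out[s] += 1
        return out


@dataclass
class TagMatrix:
    """Per-individual presence/absence (optionally depth) of RAD tags.

    ``state`` is tags x individuals over {present, absent, missing};
    ``depth`` has the same shape when given, and a zero depth can only
    accompany an absent or missing state.
    """

    tag_ids: list[str]
    individual_ids: list[str]
    state: np.ndarray  # int8, values from TagState
    depth: Optional[np.ndarray] = None  # non-negative int

    def __post_init__(self) -> None:
        self.state = np.asarray(self.state, dtype=np.int8)
        expected = (len(self.tag_ids), len(self.individual_ids))
        if self.state.shape != expected:
            raise ValueError(f"state shape {self.state.shape} != {expected}")
        if len(set(self.tag_ids)) != len(self.tag_ids):
            raise ValueError("duplicate tag ids")
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("duplicate individual ids")
        if self.depth is not None:
            self.depth = np.asarray(self.depth, dtype=np.int64)
            if self.depth.shape != expected:
                raise ValueError(f"depth shape {self.depth.shape} != {expected}")
            if (self.depth < 0).any():
                raise ValueError("negative depth")
            bad = (self.depth == 0) & (self.state == TagState.PRESENT)
            if bad.any():
                raise ValueError("depth 0 at a cell marked present")


@dataclass
class GenotypeMatrix:
    """Unordered diploid genotypes at biallelic loci.

    ``genotype`` is loci x individuals of canonical strings (``"A/G"`` with
    alleles sorted, or ``"./."``).  Alleles at each locus must come from
    that locus's {ref, alt}.
    """

    loci: list[LocusInfo]
    individual_ids: list[str]
    genotype: np.ndarray  # dtype=object of canonical genotype strings

    def __post_init__(self) -> None:
        self.genotype = np.asarray(self.genotype, dtype=object)
        expected = (len(self.loci), len(self.individual_ids))
        if self.genotype.shape != expected:
            raise ValueError(f"genotype shape {self.genotype.shape} != {expected}")
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("duplicate individual ids")
        for i, locus in enumerate(self.loci):
            allowed = {locus.ref_allele, locus.alt_allele}
            for j in range(len(self.individual_ids)):
                g = self.genotype[i, j]
                if g == MISSING_GENOTYPE:
                    continue
                a, b = g.split("/")
                if not {a, b} <= allowed:
                    raise BiallelicViolationError(
                        f"locus {locus.locus_id}, individual "
                        f"{self.individual_ids[j]}: genotype {g} has alleles "
                        f"outside {{{locus.ref_allele},{locus.alt_allele}}}"
                    )

    def locus_index(self, locus_id: str) -> int:
        for i, locus in enumerate(self.loci):
            if locus.locus_id == locus_id:
                return i
        raise KeyError(f"locus {locus_id!r} not in matrix")

    def genotypes_at(self, locus_id: str) -> dict[str, str]:
        """Map individual id -> canonical genotype string at one locus."""
        i = self.locus_index(locus_id)
        return dict(zip(self.individual_ids, self.genotype[i, :]))


def canonical_genotype(allele_a: str, allele_b: str) -> str:
    """Canonical unordered-genotype string: alleles sorted lexicographically."""
    a, b = sorted((allele_a, allele_b))
    return f"{a}/{b}"


# ---------------------------------------------------------------------------
# Sex labels
# ---------------------------------------------------------------------------


def read_sex_labels(path: str | Path) -> SexLabels:
    """Read a two-column TSV (individual id, sex token F/M/U, case folded).

    A header line is accepted if its second field is not a sex token.
    """
    path = Path(path)
    sex_by_id: dict[str, Sex] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            ind, token = parts
            if lineno == 1 and token.strip().lower() in ("sex", "phenotypic_sex"):
                continue  # header row
            key = token.strip().lower()
            if key not in _SEX_TOKENS:
                raise FormatError(f"{path}:{lineno}: unknown sex token {token!r}")
            if ind in sex_by_id:
                raise FormatError(f"{path}:{lineno}: duplicate individual id {ind!r}")
            sex_by_id[ind] = _SEX_TOKENS[key]
    return SexLabels(sex_by_id)


def write_sex_labels(labels: SexLabels, path: str | Path) -> Path:
    path = Path(path)
    token = {Sex.FEMALE: "F", Sex.MALE: "M", Sex.UNKNOWN: "U"}
    with path.open("w") as fh:
        fh.write("individual_id\tsex\n")
        for ind, sex in labels.sex_by_id.items():
            fh.write(f"{ind}\t{token[sex]}\n")
    return path


# ---------------------------------------------------------------------------
# Tag matrices
# ---------------------------------------------------------------------------

_STATE_TO_TEXT = {TagState.PRESENT: "1", TagState.ABSENT: "0", TagState.MISSING: "."}
_TEXT_TO_STATE = {v: k for k, v in _STATE_TO_TEXT.items()}


def read_tag_matrix(path: str | Path, depth_path: str | Path | None = None) -> TagMatrix:
    """Read a tag state TSV (rows=tags, header=individuals, cells 1/0/.)
    plus an optional same-shaped integer depth TSV."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    state = np.empty(df.shape, dtype=np.int8)
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = df.iat[i, j]
            if cell not in _TEXT_TO_STATE:
                raise FormatError(
                    f"{path}: tag {df.index[i]!r}, individual {df.columns[j]!r}: "
                    f"bad state cell {cell!r}"
                )
            state[i, j] = _TEXT_TO_STATE[cell]
    depth = None
    if depth_path is not None:
        ddf = pd.read_csv(Path(depth_path), sep="\t", index_col=0)
        if list(ddf.index) != list(df.index) or list(ddf.columns) != list(df.columns):
            raise FormatError("depth table ids do not match state table ids")
        depth = ddf.to_numpy(dtype=np.int64)
    return TagMatrix(list(df.index), list(df.columns), state, depth)


def write_tag_matrix(
    tags: TagMatrix, path: str | Path, depth_path: str | Path | None = None
) -> Path:
    path = Path(path)
    if tags.state.size:
        cells = np.vectorize(lambda s: _STATE_TO_TEXT[TagState(s)])(tags.state)
    else:
        cells = np.empty(tags.state.shape, dtype=object)
    pd.DataFrame(cells, index=pd.Index(tags.tag_ids, name="tag_id"),
                 columns=tags.individual_ids).to_csv(path, sep="\t")
    if depth_path is not None:
        if tags.depth is None:
            raise ValueError("tag matrix has no depth to write")
        pd.DataFrame(tags.depth, index=pd.Index(tags.tag_ids, name="tag_id"),
                     columns=tags.individual_ids).to_csv(Path(depth_path), sep="\t")
    return path


# ---------------------------------------------------------------------------
# Genotype matrices
# ---------------------------------------------------------------------------

_META_COLUMNS = ["locus_id", "scaffold", "position", "ref", "alt"]


def read_genotype_table(path: str | Path, dialect: str = "tsv") -> GenotypeMatrix:
    """Read a genotype matrix from TSV or a minimal VCF.

    TSV dialect: columns ``locus_id, scaffold, position, ref, alt`` followed
    by one column per individual; cells ``X/Y`` or ``./.``.  VCF dialect
    (``vcf-min``): VCF 4.x with single-base REF/ALT; only the GT subfield of
    FORMAT is consumed (other subfields are ignored with a warning).  Locus
    order is preserved from the file.
    """
    path = Path(path)
    if dialect == "tsv":
        return _read_genotype_tsv(path)
    if dialect == "vcf-min":
        return _read_genotype_vcf(path)
    raise ValueError(f"unknown dialect {dialect!r} (expected 'tsv' or 'vcf-min')")


def _parse_genotype_cell(cell: str, locus: LocusInfo, where: str) -> str:
    if cell == MISSING_GENOTYPE:
        return MISSING_GENOTYPE
    parts = cell.split("/")
    if len(parts) != 2:
        if len(parts) > 2 and all(p in VALID_BASES for p in parts):
            raise BiallelicViolationError(f"{where}: genotype {cell!r} has >2 alleles")
        raise FormatError(f"{where}: malformed genotype cell {cell!r}")
    a, b = parts
    allowed = {locus.ref_allele, locus.alt_allele}
    if a not in VALID_BASES or b not in VALID_BASES:
        raise FormatError(f"{where}: malformed genotype cell {cell!r}")
    if not {a, b} <= allowed:
        raise BiallelicViolationError(
            f"{where}: genotype {cell!r} has alleles outside "
            f"{{{locus.ref_allele},{locus.alt_allele}}}"
        )
    return canonical_genotype(a, b)


def _read_genotype_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing_meta = [c for c in _META_COLUMNS if c not in df.columns]
    if missing_meta:
        raise FormatError(f"{path}: missing metadata columns {missing_meta}")
    ind_cols = [c for c in df.columns if c not in _META_COLUMNS]
    loci: list[LocusInfo] = []
    rows: list[list[str]] = []
    for i, rec in df.iterrows():
        try:
            locus = LocusInfo(rec["locus_id"], rec["scaffold"], int(rec["position"]),
                              rec["ref"], rec["alt"])
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: row {i + 2}: {exc}") from exc
        row = [
            _parse_genotype_cell(
                str(rec[c]), locus, f"{path}: locus {locus.locus_id}, column {c}"
            )
            for c in ind_cols
        ]
        loci.append(locus)
        rows.append(row)
    genotype = np.array(rows, dtype=object) if rows else np.empty((0, len(ind_cols)), object)
    return GenotypeMatrix(loci, ind_cols, genotype)


def _read_genotype_vcf(path: Path) -> GenotypeMatrix:
    loci: list[LocusInfo] = []
    rows: list[list[str]] = []
    individuals: list[str] = []
    sites_only = False
    seen_header = False
    warned_format = False
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("##"):
                continue
            fields = line.split("\t")
            if line.startswith("#CHROM"):
                seen_header = True
                sites_only = len(fields) == 8  # no FORMAT/sample columns
                if not sites_only and len(fields) < 10:
                    raise FormatError(f"{path}:{lineno}: VCF header has FORMAT "
                                      "but no sample columns")
                individuals = [] if sites_only else fields[9:]
                continue
            if not seen_header:
                raise FormatError(f"{path}:{lineno}: data line before #CHROM header")
            expected = 8 if sites_only else 9 + len(individuals)
            if len(fields) != expected:
                raise FormatError(f"{path}:{lineno}: expected {expected} "
                                  f"columns, got {len(fields)}")
            chrom, pos, vid, ref, alt = fields[0], fields[1], fields[2], fields[3], fields[4]
            if not sites_only:
                fmt = fields[8].split(":")
                if fmt[0] != "GT":
                    raise FormatError(f"{path}:{lineno}: FORMAT must begin with GT")
                if len(fmt) > 1 and not warned_format:
                    log.warning("%s: ignoring FORMAT subfields %s (only GT is consumed)",
                                path, fmt[1:])
                    warned_format = True
            if "," in alt:
                raise BiallelicViolationError(f"{path}:{lineno}: multiallelic ALT {alt!r}")
            locus = LocusInfo(vid if vid != "." else f"{chrom}:{pos}", chrom, int(pos),
                              ref, alt)
            alleles = {"0": ref, "1": alt}
            row: list[str] = []
            for sample, cell in zip(individuals, fields[9:]):
                gt = cell.split(":")[0].replace("|", "/")
                where = f"{path}:{lineno}: sample {sample}"
                if gt in (".", MISSING_GENOTYPE):
                    row.append(MISSING_GENOTYPE)
                    continue
                codes = gt.split("/")
                if len(codes) != 2 or any(c not in alleles for c in codes):
                    raise FormatError(f"{where}: malformed GT {gt!r}")
                row.append(canonical_genotype(alleles[codes[0]], alleles[codes[1]]))
            loci.append(locus)
            rows.append(row)
    genotype = np.array(rows, dtype=object) if rows else np.empty((0, len(individuals)), object)
    return GenotypeMatrix(loci, individuals, genotype)


def write_genotype_table(matrix: GenotypeMatrix, path: str | Path) -> Path:
    """Write the TSV dialect (1-based positions, canonical genotypes)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(_META_COLUMNS + matrix.individual_ids) + "\n")
        for i, locus in enumerate(matrix.loci):
            cells = [locus.locus_id, locus.scaffold, str(locus.position),
                     locus.ref_allele, locus.alt_allele]
            cells.extend(matrix.genotype[i, :])
            fh.write("\t".join(cells) + "\n")
    return path


# ---------------------------------------------------------------------------
# Candidate VCF output
# ---------------------------------------------------------------------------


def write_candidate_vcf(candidates: Sequence, loci: Iterable[LocusInfo],
                        path: str | Path) -> Path:
    """Write SNP candidates as a minimal VCF 4.2 file (1-based positions).

    Each candidate must expose ``locus_id``, ``p_value`` and
    ``heterogamety_call``; the latter two are encoded as INFO keys ``SEXP``
    and ``HET``.  Data lines are sorted by (scaffold, position).
    """
    path = Path(path)
    by_id = {l.locus_id: l for l in loci}
    records = []
    for cand in candidates:
        if cand.locus_id not in by_id:
            raise KeyError(f"candidate locus {cand.locus_id!r} has no locus metadata")
        records.append((by_id[cand.locus_id], cand))
    records.sort(key=lambda rec: (rec[0].scaffold, rec[0].position))
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SEXP,Number=1,Type=Float,'
                 'Description="Two-sided Fisher exact p-value of the sex association">\n')
        fh.write('##INFO=<ID=HET,Number=1,Type=String,'
                 'Description="Heterogamety call (ZW, XY or inconclusive)">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for locus, cand in records:
            het = getattr(cand.heterogamety_call, "value", cand.heterogamety_call)
            info = f"SEXP={cand.p_value:.6g};HET={het}"
            fh.write(f"{locus.scaffold}\t{locus.position}\t{locus.locus_id}\t"
                     f"{locus.ref_allele}\t{locus.alt_allele}\t.\tPASS\t{info}\n")
    return path


# ---------------------------------------------------------------------------
# FASTA and JSON helpers
# ---------------------------------------------------------------------------


def read_fasta_sequence(path: str | Path, record_id: str | None = None) -> str:
    """Return one sequence from a FASTA file (first record by default).

    RNA 'U' is normalized to DNA 'T' on ingestion; case is folded to upper.
    """
    from Bio import SeqIO

    for rec in SeqIO.parse(str(path), "fasta"):
        if record_id is None or rec.id == record_id:
            return str(rec.seq).upper().replace("U", "T")
    raise KeyError(f"record {record_id!r} not found in {path}")


def write_fasta_sequence(seq: str, name: str, path: str | Path, width: int = 70) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i:i + width] + "\n")
    return path


def write_json_report(report: Mapping, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        json.dump(report, fh, indent=2, sort_keys=False, default=_json_default)
        fh.write("\n")
    return path


def _json_default(obj):
    if isinstance(obj, enum.Enum):
        return obj.value
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
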