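"""Cohort containers and file IO: VCF genotypes, pedigrees, reference allele counts.

The pipeline works on diploid genotype calls coded as alternate-allele
counts (0, 1, 2) with ``-1`` for missing. Multi-allelic VCF records are
split into biallelic variants on read; phase separators in the input are
accepted but ignored, because phase is re-derived from parental genotypes
downstream.
"""

from __future__ import annotations

import dataclasses
import enum
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import pysam

MISSING = -1

__all__ = [
    "MISSING",
    "FunctionalClass",
    "VariantRecord",
    "GenotypeMatrix",
    "PedigreeTable",
    "ReferenceCountTable",
    "VcfParseError",
    "ConfigurationError",
    "read_vcf",
    "write_vcf",
    "read_ped",
    "write_ped",
    "read_reference_counts",
    "apply_missingness_filter",
]


class VcfParseError(ValueError):
    """Raised for malformed VCF input (bad header, non-diploid calls, half calls)."""


class ConfigurationError(ValueError):
    """Raised when an analysis is requested on an inconsistent configuration."""


class FunctionalClass(str, enum.Enum):
    MISSENSE = "missense"
    FRAMESHIFT = "frameshift"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


@dataclasses.dataclass(frozen=True)
class VariantRecord:
    """A single biallelic variant.

    Identity is the VCF-convention key ``(chrom, pos, ref, alt)`` with a
    1-based position. ``annotation_scores`` carries opaque pass-through
    annotations (e.g. CADD) and does not participate in identity.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    variant_id: str = ""
    functional_class: FunctionalClass = FunctionalClass.OTHER
    annotation_scores: tuple = ()

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical at {self.chrom}:{self.pos}")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


class GenotypeMatrix:
    """Individuals x variants matrix of alt-allele counts (0/1/2, -1 missing)."""

    def __init__(self, individuals: Iterable[str], variants: list[VariantRecord],
                 calls: np.ndarray):
        self.individuals = list(individuals)
        self.variants = list(variants)
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(self.individuals), len(self.variants)):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.variants)} variants")
        bad = ~np.isin(calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"invalid call values: {np.unique(calls[bad])}")
        self.calls = calls
        self._ind_index = {s: i for i, s in enumerate(self.individuals)}
        if len(self._ind_index) != len(self.individuals):
            raise ValueError("duplicate individual identifiers")
        self._var_index = {v.key: j for j, v in enumerate(self.variants)}

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def has_individual(self, individual: str) -> bool:
        return individual in self._ind_index

    def individual_index(self, individual: str) -> int:
        return self._ind_index[individual]

    def variant_index(self, key: tuple) -> int:
        return self._var_index[key]

    def call(self, individual: str, variant_key: tuple) -> int:
        return int(self.calls[self._ind_index[individual], self._var_index[variant_key]])

    def rows(self, individuals: Iterable[str]) -> np.ndarray:
        idx = [self._ind_index[s] for s in individuals]
        return self.calls[idx]

    def subset_variants(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        variants = [v for v, k in zip(self.variants, keep) if k]
        return GenotypeMatrix(self.individuals, variants, self.calls[:, keep])

    def __eq__(self, other) -> bool:
        return (isinstance(other, GenotypeMatrix)
                and self.individuals == other.individuals
                and self.variants == other.variants
                and np.array_equal(self.calls, other.calls))


class Status(str, enum.Enum):
    CASE = "case"
    CONTROL = "control"
    PARENT = "parent"


@dataclasses.dataclass
class PedigreeTable:
    """Trio structure and affection status.

    PED phenotype coding: 2 = affected (case), 1 = unaffected (control),
    0 = missing, which this pipeline uses for parents. Parent identifiers
    of "0" mean unknown.
    """

    table: pd.DataFrame  # columns: family, individual, father, mother, sex, status

    def __post_init__(self):
        t = self.table
        dup = t["individual"].duplicated()
        if dup.any():
            raise ValueError(f"duplicate individuals in pedigree: "
                             f"{t.loc[dup, 'individual'].tolist()}")
        # no individual is its own ancestor
        for _, row in t.iterrows():
            if row["individual"] in (row["father"], row["mother"]):
                raise ValueError(f"{row['individual']} is its own parent")

    @property
    def cases(self) -> list[str]:
        return self.table.loc[self.table["status"] == Status.CASE, "individual"].tolist()

    @property
    def controls(self) -> list[str]:
        return self.table.loc[self.table["status"] == Status.CONTROL, "individual"].tolist()

    def status_of(self, individual: str) -> Status:
        row = self.table.loc[self.table["individual"] == individual]
        if row.empty:
            raise KeyError(individual)
        return row["status"].iloc[0]

    def parents_of(self, individual: str) -> tuple[str | None, str | None]:
        row = self.table.loc[self.table["individual"] == individual]
        if row.empty:
            return (None, None)
        f = row["father"].iloc[0]
        m = row["mother"].iloc[0]
        return (f if f not in (None, "0", "") else None,
                m if m not in (None, "0", "") else None)

    def complete_trios(self, genotyped: Iterable[str]) -> list[tuple[str, str, str]]:
        """(child, mother, father) triples where both parents are genotyped.

        A trio exists only when both parent identifiers resolve to
        individuals present in the genotype data.
        """
        present = set(genotyped)
        trios = []
        for _, row in self.table.iterrows():
            child, father, mother = row["individual"], row["father"], row["mother"]
            if father in present and mother in present and child in present \
                    and father not in (None, "0") and mother not in (None, "0"):
                trios.append((child, mother, father))
        return trios


def read_ped(path) -> PedigreeTable:
    """Read a 6-column whitespace-delimited PED file."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 PED columns, got {len(parts)}")
            fam, ind, father, mother, sex, pheno = parts[:6]
            status = {"2": Status.CASE, "1": Status.CONTROL, "0": Status.PARENT}.get(pheno)
            if status is None:
                raise ValueError(f"{path}:{lineno}: bad phenotype code {pheno!r}")
            rows.append((fam, ind, father, mother, sex, status))
    table = pd.DataFrame(rows, columns=["family", "individual", "father", "mother",
                                        "sex", "status"])
    return PedigreeTable(table)


def write_ped(ped: PedigreeTable, path) -> None:
    code = {Status.CASE: "2", Status.CONTROL: "1", Status.PARENT: "0"}
    with open(path, "w") as fh:
        for _, r in ped.table.iterrows():
            fh.write(f"{r['family']}\t{r['individual']}\t{r['father'] or '0'}\t"
                     f"{r['mother'] or '0'}\t{r['sex']}\t{code[r['status']]}\n")


class ReferenceCountTable:
    """External per-variant, per-population allele counts (ExAC-style).

    Lookup is by the ``(chrom, pos, ref, alt)`` key. A variant absent from
    the table is declared absent: alt count 0 over a per-population default
    allele number (the largest allele number observed for that population,
    i.e. the full reference panel size).
    """

    def __init__(self, counts: Mapping[tuple, Mapping[str, tuple[int, int]]]):
        self._counts = {k: dict(v) for k, v in counts.items()}
        self.populations: set[str] = set()
        self._default_an: dict[str, int] = {}
        for pops in self._counts.values():
            for pop, (ac, an) in pops.items():
                if an <= 0:
                    raise ValueError(f"allele_number must be positive, got {an}")
                if ac < 0 or ac > an:
                    raise ValueError(f"alt_count {ac} outside [0, allele_number={an}]")
                self.populations.add(pop)
                self._default_an[pop] = max(self._default_an.get(pop, 0), an)

    def counts(self, key: tuple, population: str) -> tuple[int, int]:
        """(alt_count, allele_number); absent variants are (0, default AN)."""
        pops = self._counts.get(key, {})
        if population in pops:
            return pops[population]
        an = self._default_an.get(population)
        if an is None:
            raise KeyError(f"unknown reference population {population!r}")
        return (0, an)

    def frequency(self, key: tuple, population: str) -> float:
        ac, an = self.counts(key, population)
        return ac / an

    def max_maf(self, key: tuple) -> float:
        """Maximum minor-allele frequency across all reference populations."""
        maxi = 0.0
        for pop in self.populations:
            f = self.frequency(key, pop)
            maxi = max(maxi, min(f, 1.0 - f))
        return maxi


def _parse_variant_key(text: str) -> tuple:
    parts = text.replace(">", ":").replace("/", ":").split(":")
    if len(parts) != 4:
        raise ValueError(f"bad variant key {text!r}; expected chrom:pos:ref:alt")
    chrom, pos, ref, alt = parts
    return (chrom, int(pos), ref, alt)


def read_reference_counts(path) -> ReferenceCountTable:
    """Read a TSV of columns: variant, population, alt_count, allele_number.

    The variant column is ``chrom:pos:ref:alt`` (``>`` accepted between
    alleles). Duplicate (variant, population) rows are a validation error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"population": str})
    required = {"variant", "population", "alt_count", "allele_number"}
    if not required.issubset(df.columns):
        raise ValueError(f"reference count table must have columns {sorted(required)}")
    counts: dict[tuple, dict[str, tuple[int, int]]] = {}
    for _, row in df.iterrows():
        key = _parse_variant_key(str(row["variant"]))
        pop = row["population"]
        ac, an = int(row["alt_count"]), int(row["allele_number"])
        if ac > an:
            raise ValueError(f"alt_count {ac} > allele_number {an} for {row['variant']}")
        pops = counts.setdefault(key, {})
        if pop in pops:
            raise ValueError(f"duplicate reference entry for {row['variant']} / {pop}")
        pops[pop] = (ac, an)
    return ReferenceCountTable(counts)


_GT_FIELDS = {"GENE": "gene", "VID": "variant_id", "CLASS": "functional_class"}


def read_vcf(path) -> tuple[GenotypeMatrix, list[VariantRecord]]:
    """Read a VCF v4.2 file with GT genotypes into a GenotypeMatrix.

    Multi-allelic records are split into one biallelic VariantRecord per
    alternate allele; each split call counts copies of that allele only, so
    total alt copies per site are conserved. ``./.`` maps to missing; phased
    separators are accepted but the file's phase is discarded. Non-diploid
    or half calls raise :class:`VcfParseError` naming the offending record.
    """
    try:
        vcf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"{path}: malformed VCF header: {exc}") from exc
    samples = list(vcf.header.samples)
    variants: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    for recno, rec in enumerate(vcf.fetch() if vcf.index else vcf, 1):
        alts = rec.alts or ()
        gts = []
        for s in samples:
            gt = rec.samples[s].get("GT", (None,))
            if gt is None:
                gt = (None, None)
            if len(gt) != 2:
                raise VcfParseError(
                    f"{path}: record {recno} ({rec.chrom}:{rec.pos}): "
                    f"ploidy {len(gt)} != 2 for sample {s}")
            if (gt[0] is None) != (gt[1] is None):
                raise VcfParseError(
                    f"{path}: record {recno} ({rec.chrom}:{rec.pos}): "
                    f"half call for sample {s}")
            gts.append(gt)
        info = dict(rec.info)
        gene = str(info.get("GENE", ""))
        vid = str(info.get("VID", rec.id or ""))
        fclass = str(info.get("CLASS", "other"))
        try:
            fclass = FunctionalClass(fclass)
        except ValueError:
            fclass = FunctionalClass.OTHER
        scores = tuple((k, float(v)) for k, v in info.items()
                       if k not in _GT_FIELDS and isinstance(v, (int, float)))
        for ai, alt in enumerate(alts, start=1):
            col = np.full(len(samples), MISSING, dtype=np.int8)
            for si, gt in enumerate(gts):
                if gt[0] is None:
                    continue
                col[si] = sum(1 for a in gt if a == ai)
            suffix = f".{ai}" if len(alts) > 1 and vid else ""
            variants.append(VariantRecord(
                chrom=str(rec.chrom), pos=rec.pos, ref=rec.ref, alt=str(alt),
                gene=gene, variant_id=vid + suffix, functional_class=fclass,
                annotation_scores=scores))
            columns.append(col)
    calls = (np.stack(columns, axis=1) if columns
             else np.empty((len(samples), 0), dtype=np.int8))
    return GenotypeMatrix(samples, variants, calls), variants


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a GenotypeMatrix as an uncompressed biallelic VCF v4.2."""
    header = pysam.VariantHeader()
    for chrom in dict.fromkeys(v.chrom for v in gm.variants):
        header.contigs.add(chrom)
    header.info.add("GENE", 1, "String", "Gene symbol")
    header.info.add("VID", 1, "String", "Variant label")
    header.info.add("CLASS", 1, "String", "Functional class")
    score_keys = dict.fromkeys(k for v in gm.variants for k, _ in v.annotation_scores)
    for k in score_keys:
        header.info.add(k, 1, "Float", "Pass-through annotation score")
    header.formats.add("GT", 1, "String", "Genotype")
    for s in gm.individuals:
        header.add_sample(s)
    gt_map = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j, v in enumerate(gm.variants):
            rec = out.new_record(contig=v.chrom, start=v.pos - 1,
                                 alleles=(v.ref, v.alt))
            rec.id = v.variant_id or None
            if v.gene:
                rec.info["GENE"] = v.gene
            if v.variant_id:
                rec.info["VID"] = v.variant_id
            rec.info["CLASS"] = v.functional_class.value
            for k, val in v.annotation_scores:
                rec.info[k] = val
            for i, s in enumerate(gm.individuals):
                rec.samples[s]["GT"] = gt_map[int(gm.calls[i, j])]
            out.write(rec)


def apply_missingness_filter(gm: GenotypeMatrix, ped: PedigreeTable,
                             threshold: float = 0.10) -> GenotypeMatrix:
    """Drop variants with missing-call rate >= threshold in cases OR controls.

    The boundary is inclusive: a site missing in exactly ``threshold`` of
    either group is removed. Parents do not count toward either rate; they
    enter only the phasing and de novo stages.
    """
    if not (0 < threshold <= 1):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    cases = [s for s in ped.cases if gm.has_individual(s)]
    controls = [s for s in ped.controls if gm.has_individual(s)]
    if not cases or not controls:
        raise ConfigurationError("missingness filter needs at least one genotyped "
                                 "case and one genotyped control")
    case_missing = (gm.rows(cases) == MISSING).mean(axis=0)
    ctrl_missing = (gm.rows(controls) == MISSING).mean(axis=0)
    keep = (case_missing < threshold) & (ctrl_missing < threshold)
    return gm.subset_variants(keep)
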