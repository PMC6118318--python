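"""Trio genetics: Mendelian checks, gamete-logic phasing, de novo calls,
and the carrier covariate encodings for the two effect-size models.

Phase is derived purely from parental genotypes: a two-variant
configuration is called cis or trans only when every parental gamete
combination consistent with Mendelian transmission forces it. No
read-backed or population phasing is attempted.
"""

from __future__ import annotations

import dataclasses
import enum

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import (MISSING, ConfigurationError, GenotypeMatrix, PedigreeTable,
                     ReferenceCountTable, VariantRecord)

__all__ = [
    "MendelStatus",
    "PhaseConfiguration",
    "PhaseCall",
    "DeNovoCall",
    "Panel",
    "CarrierEncoding",
    "check_mendelian",
    "phase_pair",
    "detect_de_novo",
    "de_novo_burden_test",
    "build_carrier_encoding",
]


class MendelStatus(str, enum.Enum):
    CONSISTENT = "consistent"
    INCONSISTENT = "inconsistent"
    UNKNOWN = "unknown"


_GAMETES = {0: (0,), 1: (0, 1), 2: (1,), MISSING: (0, 1)}


def check_mendelian(child: int, mother: int, father: int) -> MendelStatus:
    """Classify a single-site trio genotype as Mendelian-consistent or not.

    Returns ``unknown`` if any call is missing; ``inconsistent`` iff no
    combination of one maternal and one paternal gamete can produce the
    child's genotype.
    """
    calls = (child, mother, father)
    if any(c not in (0, 1, 2, MISSING) for c in calls):
        raise ValueError(f"calls must be in {{0,1,2,{MISSING}}}, got {calls}")
    if MISSING in calls:
        return MendelStatus.UNKNOWN
    for gm in _GAMETES[mother]:
        for gf in _GAMETES[father]:
            if gm + gf == child:
                return MendelStatus.CONSISTENT
    return MendelStatus.INCONSISTENT


class PhaseConfiguration(str, enum.Enum):
    CIS = "cis"
    TRANS = "trans"
    AMBIGUOUS = "ambiguous"
    UNPHASABLE = "unphasable"


@dataclasses.dataclass(frozen=True)
class PhaseCall:
    """Phase of a double-heterozygous variant pair in one individual."""

    individual: str
    variant_pair: tuple[VariantRecord, VariantRecord] | tuple
    configuration: PhaseConfiguration | None
    mendelian_error: bool = False


def phase_pair(child: tuple[int, int], mother: tuple[int, int],
               father: tuple[int, int], individual: str = "",
               variant_pair: tuple = ()) -> PhaseCall:
    """Phase two heterozygous sites of one gene from parental genotypes.

    The child must be heterozygous at both sites. All maternal x paternal
    gamete pairs compatible with the parents' (unphased) genotypes are
    enumerated; a missing parental call contributes both alleles. The
    call is trans when every compatible transmission puts the two alt
    alleles on opposite child haplotypes, cis when always on the same
    haplotype, ambiguous when both remain possible, and unphasable when
    no parental genotypes are available at either site. A pair explained
    by no gamete combination is flagged as a Mendelian inconsistency with
    no phase call.
    """
    if tuple(child) != (1, 1):
        raise ValueError(f"phase_pair requires a double-heterozygous child, got {child}")
    if all(c == MISSING for c in (*mother, *father)):
        return PhaseCall(individual, variant_pair, PhaseConfiguration.UNPHASABLE)
    configs = set()
    for gm1 in _GAMETES[mother[0]]:
        for gm2 in _GAMETES[mother[1]]:
            for gf1 in _GAMETES[father[0]]:
                for gf2 in _GAMETES[father[1]]:
                    if gm1 + gf1 == 1 and gm2 + gf2 == 1:
                        # maternal gamete (gm1, gm2) carries alt at site i iff gmi == 1
                        configs.add("cis" if gm1 == gm2 else "trans")
    if not configs:
        return PhaseCall(individual, variant_pair, None, mendelian_error=True)
    if configs == {"cis"}:
        cfg = PhaseConfiguration.CIS
    elif configs == {"trans"}:
        cfg = PhaseConfiguration.TRANS
    else:
        cfg = PhaseConfiguration.AMBIGUOUS
    return PhaseCall(individual, variant_pair, cfg)


@dataclasses.dataclass(frozen=True)
class DeNovoCall:
    trio_id: str
    variant: VariantRecord
    cohort_occurrence: int  # carriers among cases + controls (includes the child)
    max_reference_maf: float


def detect_de_novo(gm: GenotypeMatrix, ped: PedigreeTable,
                   ref: ReferenceCountTable | None = None,
                   max_maf: float = 0.005,
                   max_occurrence: int = 1) -> list[DeNovoCall]:
    """Mendelian de novo candidates surviving the frequency and recurrence filters.

    A candidate is a complete trio where the child is heterozygous and
    both parents are confidently homozygous reference (a missing parent
    call suppresses the candidate). Candidates are excluded when the
    variant's minor-allele frequency exceeds ``max_maf`` (0.5%) in any
    reference population, or when carriers among cases and controls
    jointly number two or more (the affected child must be the only
    carrier). Variants absent from the reference table count as MAF 0.
    """
    trios = ped.complete_trios(gm.individuals)
    if not trios:
        raise ConfigurationError("de novo detection requires at least one complete trio")
    case_ctrl = [s for s in ped.cases + ped.controls if gm.has_individual(s)]
    carrier_counts = (gm.rows(case_ctrl) >= 1).sum(axis=0)
    calls = []
    for child, mother, father in trios:
        ci = gm.individual_index(child)
        mi = gm.individual_index(mother)
        fi = gm.individual_index(father)
        for j, variant in enumerate(gm.variants):
            if gm.calls[ci, j] != 1 or gm.calls[mi, j] != 0 or gm.calls[fi, j] != 0:
                continue
            maf = ref.max_maf(variant.key) if ref is not None else 0.0
            if maf > max_maf:
                continue
            occurrence = int(carrier_counts[j])
            if occurrence > max_occurrence:
                continue
            calls.append(DeNovoCall(trio_id=child, variant=variant,
                                    cohort_occurrence=occurrence,
                                    max_reference_maf=maf))
    return calls


def de_novo_burden_test(observed: int, gene_length: int, n_trios: int,
                        rate_snv: float = 1.2e-8, rate_indel: float = 4e-10) -> float:
    """Upper-tail Poisson p-value for a gene's de novo mutation count.

    The expected count is 2 x n_trios x gene_length x (rate_snv +
    rate_indel), rates being per haploid base per generation. This is a
    plain mutation-rate burden test; it deliberately does not reproduce
    functional-prioritisation de novo association p-values (VARPRISM),
    which weight mutations by predicted impact.
    """
    if min(observed, gene_length, n_trios) < 0 or min(rate_snv, rate_indel) < 0:
        raise ValueError("all arguments must be non-negative")
    lam = 2.0 * n_trios * gene_length * (rate_snv + rate_indel)
    return float(stats.poisson.sf(observed - 1, lam))


@dataclasses.dataclass(frozen=True)
class Panel:
    """Risk-variant panel: common (MAF >= 1%) and rare putative risk variants.

    Keys are (chrom, pos, ref, alt); ``labels`` maps keys to display
    names for encoding columns.
    """

    common: tuple
    rare: tuple
    labels: tuple = ()

    def label(self, key: tuple) -> str:
        return dict(self.labels).get(key, f"{key[0]}:{key[1]}:{key[2]}:{key[3]}")


@dataclasses.dataclass
class CarrierEncoding:
    """Per-individual indicator covariates for the two regression models.

    Model 1 mirrors an unphased genotyping study: one heterozygote
    indicator per common risk variant plus an any-homozygote indicator;
    het indicators may overlap each other but not the homozygote flag.
    Model 2 adds sequencing and parental phase: homozygotes, confidently
    trans-phased compound heterozygotes, single common heterozygotes and
    rare heterozygotes are mutually exclusive, with precedence
    homozygote > compound > common het > rare het. Double heterozygotes
    whose phase is ambiguous or unphasable are conservatively NOT called
    compound and fall through to the heterozygote categories.
    """

    model1: pd.DataFrame
    model2: pd.DataFrame
    provenance: pd.DataFrame  # per-individual category notes

    def model_matrix(self, model: int) -> tuple[np.ndarray, list[str]]:
        df = self.model1 if model == 1 else self.model2
        cols = [c for c in df.columns if c != "status"]
        return df[cols].to_numpy(dtype=float), cols


def _pair_phase(gm: GenotypeMatrix, ped: PedigreeTable, individual: str,
                j1: int, j2: int) -> PhaseCall:
    father, mother = ped.parents_of(individual)
    ci = gm.individual_index(individual)
    child = (int(gm.calls[ci, j1]), int(gm.calls[ci, j2]))
    if mother is not None and gm.has_individual(mother):
        mi = gm.individual_index(mother)
        mo = (int(gm.calls[mi, j1]), int(gm.calls[mi, j2]))
    else:
        mo = (MISSING, MISSING)
    if father is not None and gm.has_individual(father):
        fi = gm.individual_index(father)
        fa = (int(gm.calls[fi, j1]), int(gm.calls[fi, j2]))
    else:
        fa = (MISSING, MISSING)
    return phase_pair(child, mo, fa, individual=individual,
                      variant_pair=(gm.variants[j1], gm.variants[j2]))


def build_carrier_encoding(gm: GenotypeMatrix, ped: PedigreeTable,
                           panel: Panel) -> CarrierEncoding:
    """Build Model-1 and Model-2 covariate indicator tables for cases and controls."""
    for key in (*panel.common, *panel.rare):
        try:
            gm.variant_index(key)
        except KeyError:
            raise ConfigurationError(f"panel variant {key} absent from genotype matrix")
    common_idx = {key: gm.variant_index(key) for key in panel.common}
    rare_idx = {key: gm.variant_index(key) for key in panel.rare}
    all_idx = {**common_idx, **rare_idx}
    subjects = [s for s in ped.cases + ped.controls if gm.has_individual(s)]

    m1_rows, m2_rows, notes = [], [], []
    common_labels = [panel.label(k) for k in panel.common]
    for ind in subjects:
        i = gm.individual_index(ind)
        g = {key: int(gm.calls[i, j]) for key, j in all_idx.items()}
        het_common = [k for k in panel.common if g[k] == 1]
        het_rare = [k for k in panel.rare if g[k] == 1]
        hom_common = [k for k in panel.common if g[k] == 2]
        hom_rare = [k for k in panel.rare if g[k] == 2]

        m1 = {f"het_{panel.label(k)}": int(g[k] == 1) for k in panel.common}
        m1["any_homozygote"] = int(bool(hom_common))
        m1_rows.append(m1)

        # Model 2: exclusive non-het categories by precedence.
        het_sites = het_common + het_rare
        compound = False
        note = "non_carrier"
        if hom_common:
            note = f"common_homozygote:{panel.label(hom_common[0])}"
        else:
            if hom_rare:
                compound = True  # two rare risk alleles, trivially in trans
                note = f"rare_homozygote_as_compound:{panel.label(hom_rare[0])}"
            else:
                for x in range(len(het_sites)):
                    for y in range(x + 1, len(het_sites)):
                        k1, k2 = het_sites[x], het_sites[y]
                        v1 = gm.variants[all_idx[k1]]
                        v2 = gm.variants[all_idx[k2]]
                        if v1.gene and v2.gene and v1.gene != v2.gene:
                            continue
                        call = _pair_phase(gm, ped, ind, all_idx[k1], all_idx[k2])
                        if (not call.mendelian_error
                                and call.configuration is PhaseConfiguration.TRANS):
                            compound = True
                            note = (f"compound:{panel.label(k1)}+{panel.label(k2)}")
                            break
                    if compound:
                        break
        m2 = {f"het_{panel.label(k)}": 0 for k in panel.common}
        m2["common_homozygote"] = int(bool(hom_common))
        m2["compound_heterozygote"] = int(compound)
        m2["rare_heterozygote"] = 0
        if not hom_common and not compound:
            if het_common:
                for k in het_common:
                    m2[f"het_{panel.label(k)}"] = 1
                note = "common_heterozygote:" + "+".join(panel.label(k) for k in het_common)
            elif het_rare:
                m2["rare_heterozygote"] = 1
                note = "rare_heterozygote:" + "+".join(panel.label(k) for k in het_rare)
        m2_rows.append(m2)
        notes.append({"individual": ind,
                      "status": ped.status_of(ind).value,
                      "category": note})

    status = [ped.status_of(s).value for s in subjects]
    model1 = pd.DataFrame(m1_rows, index=subjects)
    model2 = pd.DataFrame(m2_rows, index=subjects)
    model1["status"] = status
    model2["status"] = status
    return CarrierEncoding(model1=model1, model2=model2,
                           provenance=pd.DataFrame(notes))
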