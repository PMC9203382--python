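"""Mendelian segregation filtering and the rare-variant filter cascade.

A dominant, fully penetrant causal variant must be carried by every
affected family member and by no unaffected member. On autosomes the
carrier state is heterozygous; on chrX affected males are hemizygous for
the alternate allele and affected females heterozygous, while unaffected
males are hemizygous reference. Variants consistent with one of these
patterns are then filtered on population minor-allele frequency
(< 5% in the reference population, or no reported frequency) and on
annotation impact class (HIGH/MODERATE retained).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Literal, Sequence

from .pedigree import Pedigree
from .variants import GenotypeCall, Impact, VariantRecord

log = logging.getLogger(__name__)


class InheritanceModel(Enum):
    AUTOSOMAL_DOMINANT = "AD"
    X_LINKED_DOMINANT = "XLD"


class SegregationError(ValueError):
    pass


@dataclass
class FilterStep:
    """One applied filter: name, verdict, and a human-readable detail."""

    name: str
    passed: bool
    detail: str = ""

    def as_tuple(self) -> tuple[str, bool, str]:
        return (self.name, self.passed, self.detail)


@dataclass
class CandidateVariant:
    """A variant, the inheritance models it segregates under, and its trail."""

    variant: VariantRecord
    models: set[InheritanceModel]
    filter_trail: list[FilterStep] = field(default_factory=list)

    @property
    def passed_all(self) -> bool:
        return all(s.passed for s in self.filter_trail)


@dataclass
class PrioritizeConfig:
    maf_threshold: float = 0.05
    population: str = "ASN"
    missing_policy: Literal["strict", "lenient"] = "strict"
    on_error: Literal["skip", "raise"] = "skip"


MissingPolicy = Literal["strict", "lenient"]


def _call_matches(
    call: GenotypeCall,
    *,
    required: Literal["het", "hom_ref", "hemi_alt", "hemi_ref"],
    missing_policy: MissingPolicy,
) -> bool:
    if call.missing:
        return missing_policy == "lenient"
    if required == "het":
        return call.is_het
    if required == "hom_ref":
        return len(call.alleles) == 2 and call.alt_count == 0
    if required == "hemi_alt":
        return call.is_hemizygous and call.alt_count == 1
    if required == "hemi_ref":
        return call.is_hemizygous and call.alt_count == 0
    raise AssertionError(required)


def required_pattern(
    model: InheritanceModel, *, male: bool, affected: bool
) -> Literal["het", "hom_ref", "hemi_alt", "hemi_ref"]:
    """Genotype a labelled member must show for the variant to segregate."""
    if model is InheritanceModel.AUTOSOMAL_DOMINANT:
        return "het" if affected else "hom_ref"
    if affected:
        return "hemi_alt" if male else "het"
    return "hemi_ref" if male else "hom_ref"


def model_for_chrom(chrom: str) -> InheritanceModel:
    return (
        InheritanceModel.X_LINKED_DOMINANT
        if chrom == "X"
        else InheritanceModel.AUTOSOMAL_DOMINANT
    )


def consistent_under_model(
    v: VariantRecord,
    ped: Pedigree,
    m: InheritanceModel,
    *,
    missing_policy: MissingPolicy = "strict",
) -> bool:
    """True iff the genotypes segregate with affection status under model m.

    Autosomal dominant: every genotyped affected member heterozygous, every
    genotyped unaffected member carrying zero alternate alleles. X-linked
    dominant: affected females heterozygous, affected males hemizygous-alt,
    unaffected females homozygous reference, unaffected males
    hemizygous-ref. Unknown-phenotype members never veto. Under the default
    strict missing policy a missing call in any labelled member fails the
    variant; under "lenient" missing calls never veto.
    """
    if (m is InheritanceModel.X_LINKED_DOMINANT) != v.is_x_linked:
        raise SegregationError(
            f"model {m.value} does not apply to chromosome {v.chrom}"
        )
    affected = sorted(ped.genotyped_affected() & set(v.genotypes))
    unaffected = sorted(ped.genotyped_unaffected() & set(v.genotypes))
    if not affected or not unaffected:
        raise SegregationError(
            f"{v.chrom}:{v.pos}: need ≥1 genotyped affected and ≥1 genotyped "
            "unaffected member"
        )
    from .pedigree import Sex

    for member_id in affected + unaffected:
        ind = ped[member_id]
        req = required_pattern(
            m,
            male=ind.sex is Sex.MALE,
            affected=member_id in affected,
        )
        if not _call_matches(
            v.genotypes[member_id], required=req, missing_policy=missing_policy
        ):
            return False
    return True


def segregation_scan(
    variants: Sequence[VariantRecord],
    ped: Pedigree,
    *,
    missing_policy: MissingPolicy = "strict",
    on_error: Literal["skip", "raise"] = "skip",
) -> list[CandidateVariant]:
    """Segregation-consistent candidates, in input order.

    Each variant is tested only under the model its chromosome admits
    (autosome → AD, chrX → XLD); candidates carry the model set and a
    trail entry recording the segregation verdict.
    """
    out: list[CandidateVariant] = []
    for v in variants:
        m = model_for_chrom(v.chrom)
        try:
            ok = consistent_under_model(v, ped, m, missing_policy=missing_policy)
        except SegregationError:
            if on_error == "raise":
                raise
            log.warning("skipping %s:%s: segregation not evaluable", v.chrom, v.pos)
            continue
        if ok:
            out.append(
                CandidateVariant(
                    variant=v,
                    models={m},
                    filter_trail=[
                        FilterStep("segregation", True, f"consistent under {m.value}")
                    ],
                )
            )
    return out


def maf_filter(
    cands: Sequence[CandidateVariant],
    threshold: float = 0.05,
    population: str = "ASN",
) -> list[CandidateVariant]:
    """Keep candidates rare in the given population, or with no reported MAF.

    The inequality is strict (a frequency exactly at the threshold is
    removed); an undefined frequency passes.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if cands and all(c.variant.maf_of(population) is None for c in cands):
        log.warning(
            "population %r has no defined MAF on any candidate; all pass", population
        )
    out = []
    for c in cands:
        f = c.variant.maf_of(population)
        passed = f is None or f < threshold
        detail = "undefined" if f is None else f"{population}={f:g}"
        c.filter_trail.append(FilterStep("maf", passed, detail))
        if passed:
            out.append(c)
    return out


def impact_filter(
    cands: Sequence[CandidateVariant],
    *,
    on_missing: Literal["fail", "pass"] = "fail",
) -> list[CandidateVariant]:
    """Keep HIGH and MODERATE impact candidates; LOW and MODIFIER are removed."""
    out = []
    for c in cands:
        imp = c.variant.impact_class
        if imp is None:
            passed = on_missing == "pass"
            detail = "impact missing"
            if not passed:
                log.warning(
                    "%s:%s: no impact class, failed", c.variant.chrom, c.variant.pos
                )
        else:
            passed = imp in (Impact.HIGH, Impact.MODERATE)
            detail = imp.value
        c.filter_trail.append(FilterStep("impact", passed, detail))
        if passed:
            out.append(c)
    return out


def _chrom_sort_key(chrom: str) -> tuple[int, str]:
    try:
        return (int(chrom), "")
    except ValueError:
        return (1000, chrom)  # X, Y, MT after numeric chroms


def prioritize(
    variants: Sequence[VariantRecord],
    ped: Pedigree,
    config: PrioritizeConfig | None = None,
) -> list[CandidateVariant]:
    """Full discovery cascade: segregation → MAF filter → impact filter.

    Returns surviving candidates sorted by (chrom, pos) for deterministic
    reporting; each candidate's trail records all three verdicts.
    """
    cfg = config or PrioritizeConfig()
    cands = segregation_scan(
        variants, ped, missing_policy=cfg.missing_policy, on_error=cfg.on_error
    )
    cands = maf_filter(cands, cfg.maf_threshold, cfg.population)
    cands = impact_filter(cands)
    return sorted(
        cands, key=lambda c: (_chrom_sort_key(c.variant.chrom), c.variant.pos)
    )


# -- reporting -------------------------------------------------------------

_REPORT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "rsid", "gene",
    "model", "maf", "impact", "filter_trail",
]


def _candidate_row(c: CandidateVariant, population: str) -> dict:
    v = c.variant
    f = v.maf_of(population)
    return {
        "chrom": v.chrom,
        "pos": v.pos,
        "ref": v.ref,
        "alt": v.alt,
        "rsid": v.rsid or ".",
        "gene": v.gene,
        "model": ",".join(sorted(m.value for m in c.models)),
        "maf": "undefined" if f is None else f"{f:g}",
        "impact": v.impact_class.value if v.impact_class else ".",
        "filter_trail": ";".join(
            f"{s.name}:{'pass' if s.passed else 'fail'}" for s in c.filter_trail
        ),
    }


def write_report(
    cands: Sequence[CandidateVariant],
    path: str | Path,
    *,
    population: str = "ASN",
    fmt: Literal["tsv", "json"] = "tsv",
) -> None:
    """Write the candidate report as TSV (default) or a JSON mirror."""
    rows = [_candidate_row(c, population) for c in cands]
    path = Path(path)
    if fmt == "json":
        path.write_text(json.dumps(rows, indent=2) + "\n")
        return
    lines = ["\t".join(_REPORT_COLUMNS)]
    lines += ["\t".join(str(r[k]) for k in _REPORT_COLUMNS) for r in rows]
    path.write_text("\n".join(lines) + "\n")
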