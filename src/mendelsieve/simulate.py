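"""Synthetic pedigrees and genotype cohorts for end-to-end testing.

The study family is not publicly deposited, so this module generates data
with the same statistical structure: a four-generation, 31-member pedigree
(9 affected, a genotyped subset of 12 with 8 affected), one fully
penetrant planted causal variant under a chosen dominant inheritance
model, and background noise variants whose founder alleles are drawn at
Hardy–Weinberg frequencies and transmitted Mendelianly — with correct
X-chromosome hemizygosity for males.

The canonical topology is count-faithful but invented: the published
pedigree figure is not enumerated in text, so this module fixes one
topology that is transmission-consistent with a dominant variant entering
through an affected founder female, under both the autosomal-dominant and
the X-linked-dominant model.

Also provided: the exact probability that a random (noise) variant matches
the dominant carrier pattern across the genotyped members, computed by
peeling over the pedigree's transmission tree — the analytic oracle against
which simulated survival frequencies are checked.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np

from .pedigree import Individual, Pedigree, Phenotype, Sex, write_ped
from .segregation import InheritanceModel
from .variants import (
    GenotypeCall,
    Impact,
    MISSING_CALL,
    VariantRecord,
    make_fixture_tables,
    write_annotation_table,
    write_vcf,
)

_FAMILY = "FAM1"

# (id, sex, affected, father, mother); generation by id prefix.
_CANONICAL_TOPOLOGY: list[tuple[str, str, bool, str | None, str | None]] = [
    ("1-1", "F", True, None, None),
    ("1-2", "M", False, None, None),
    ("2-1", "M", False, None, None),
    ("2-2", "F", True, "1-2", "1-1"),
    ("2-3", "M", False, None, None),
    ("2-4", "F", True, "1-2", "1-1"),
    ("2-5", "M", False, "1-2", "1-1"),
    ("2-6", "F", False, None, None),
    ("2-7", "F", False, "1-2", "1-1"),
    ("2-8", "M", False, None, None),
    ("3-1", "M", True, "2-1", "2-2"),
    ("3-2", "F", False, None, None),
    ("3-3", "M", True, "2-1", "2-2"),
    ("3-4", "F", False, "2-1", "2-2"),
    ("3-5", "M", True, "2-3", "2-4"),
    ("3-6", "F", False, "2-3", "2-4"),
    ("3-7", "F", False, "2-3", "2-4"),
    ("3-8", "M", False, "2-5", "2-6"),
    ("3-9", "F", False, "2-5", "2-6"),
    ("3-10", "M", False, "2-8", "2-7"),
    ("3-11", "F", False, None, None),
    ("3-12", "F", False, None, None),
    ("3-13", "F", False, "2-8", "2-7"),
    ("4-1", "M", False, "3-3", "3-11"),
    ("4-2", "M", False, "3-5", "3-12"),
    ("4-3", "M", False, "3-1", "3-2"),
    ("4-4", "M", False, "3-5", "3-12"),
    ("4-5", "M", False, "3-1", "3-2"),
    ("4-6", "F", True, "3-1", "3-2"),
    ("4-7", "F", True, "3-1", "3-2"),
    ("4-8", "F", True, "3-3", "3-11"),
]

#: The sequenced subset (8 affected, 4 unaffected; 7 female, 5 male).
GENOTYPED_SUBSET: tuple[str, ...] = (
    "2-1", "2-2", "2-4", "3-1", "3-3", "3-4",
    "3-5", "3-6", "4-3", "4-6", "4-7", "4-8",
)


def build_canonical_pedigree() -> Pedigree:
    """The deterministic 31-member, 4-generation family.

    9 affected members; the genotyped subset has 12 members of whom 8 are
    affected. The causal allele enters through the affected founder female
    1-1 and every affected member has an affected parent, so a fully
    penetrant dominant variant — autosomal or X-linked — can segregate
    exactly with the affection labels.
    """
    individuals = [
        Individual(
            member_id=mid,
            family_id=_FAMILY,
            father_id=fa,
            mother_id=mo,
            sex=Sex.MALE if sex == "M" else Sex.FEMALE,
            phenotype=Phenotype.AFFECTED if aff else Phenotype.UNAFFECTED,
        )
        for mid, sex, aff, fa, mo in _CANONICAL_TOPOLOGY
    ]
    return Pedigree(individuals, frozenset(GENOTYPED_SUBSET))


def fixture_pedigree() -> Pedigree:
    """The 12 genotyped members as a standalone pedigree (parents unknown),
    matching the published genotype-matrix membership."""
    canonical = build_canonical_pedigree()
    individuals = [
        replace(canonical[mid], father_id=None, mother_id=None)
        for mid in GENOTYPED_SUBSET
    ]
    return Pedigree(individuals, frozenset(GENOTYPED_SUBSET))


# -- configuration ---------------------------------------------------------

@dataclass
class SimulationConfig:
    """Study-scale simulation settings.

    Defaults mirror the study conditions: the canonical pedigree, a fully
    penetrant X-linked dominant causal variant at the reported population
    frequency of the index variant (0.0017), 200 background variants with
    population frequencies uniform on [0, 0.5], 5% of them X-linked
    (roughly chrX's share of exome variation), no phenocopies, and no
    missing calls.
    """

    pedigree: Pedigree | None = None  # None → canonical 31-member family
    model: InheritanceModel = InheritanceModel.X_LINKED_DOMINANT
    causal_pop_maf: float = 0.0017
    n_noise_variants: int = 200
    noise_maf_range: tuple[float, float] = (0.0, 0.5)
    fraction_x_linked_noise: float = 0.05
    penetrance: float = 1.0
    missing_rate: float = 0.0
    seed: int = 0
    impact_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        for name in ("causal_pop_maf", "fraction_x_linked_noise",
                     "penetrance", "missing_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_noise_variants < 0:
            raise ValueError("n_noise_variants must be ≥ 0")
        lo, hi = self.noise_maf_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"bad noise_maf_range {self.noise_maf_range}")
        if abs(sum(self.impact_probs) - 1.0) > 1e-9:
            raise ValueError("impact_probs must sum to 1")


_IMPACT_ORDER = (Impact.HIGH, Impact.MODERATE, Impact.LOW, Impact.MODIFIER)
_EFFECT_OF_IMPACT = {
    Impact.HIGH: "stop_gained",
    Impact.MODERATE: "missense_variant",
    Impact.LOW: "synonymous_variant",
    Impact.MODIFIER: "intergenic_region",
}

#: Position of the planted causal variant per model (the X-linked position
#: matches the index variant's coordinate).
CAUSAL_SITE = {
    InheritanceModel.X_LINKED_DOMINANT: ("X", 11_133_044, "G", "A"),
    InheritanceModel.AUTOSOMAL_DOMINANT: ("7", 100_000_001, "G", "A"),
}
CAUSAL_GENE = "CAUSAL1"


def _topological_members(ped: Pedigree) -> list[Individual]:
    """Members ordered so every parent precedes its children."""
    done: set[str] = set()
    out: list[Individual] = []
    pending = list(ped)
    while pending:
        rest = []
        for ind in pending:
            if ind.is_founder or (ind.father_id in done and ind.mother_id in done):
                out.append(ind)
                done.add(ind.member_id)
            else:
                rest.append(ind)
        if len(rest) == len(pending):
            raise ValueError("pedigree is not topologically orderable")
        pending = rest
    return out


def _transmit(ped: Pedigree, founder_geno: dict[str, tuple[int, ...]],
              x_linked: bool, rng: np.random.Generator) -> dict[str, tuple[int, ...]]:
    """Drop founder alleles down the pedigree.

    Autosomes: each parent passes one of its two alleles uniformly. chrX:
    mothers pass one of two X's; fathers pass their single X to daughters
    only; sons are hemizygous for the maternal draw.
    """
    geno = dict(founder_geno)
    for ind in _topological_members(ped):
        if ind.is_founder:
            continue
        fa, mo = geno[ind.father_id], geno[ind.mother_id]
        maternal = mo[rng.integers(2)]
        if x_linked:
            if ind.sex is Sex.MALE:
                geno[ind.member_id] = (maternal,)
            else:
                geno[ind.member_id] = (fa[0], maternal)
        else:
            geno[ind.member_id] = (fa[rng.integers(2)], maternal)
    return geno


def _founder_draw(ped: Pedigree, maf: float, x_linked: bool,
                  rng: np.random.Generator) -> dict[str, tuple[int, ...]]:
    geno: dict[str, tuple[int, ...]] = {}
    for ind in ped:
        if not ind.is_founder:
            continue
        n = 1 if (x_linked and ind.sex is Sex.MALE) else 2
        geno[ind.member_id] = tuple(int(a) for a in rng.random(n) < maf)
    return geno


def _carrier_pattern_geno(ind: Individual, carrier: bool,
                          x_linked: bool) -> tuple[int, ...]:
    if x_linked and ind.sex is Sex.MALE:
        return (1,) if carrier else (0,)
    return (0, 1) if carrier else (0, 0)


@dataclass
class SimulatedCohort:
    """In-memory simulation output, before any file is written."""

    pedigree: Pedigree
    records: list[VariantRecord]
    causal_key: tuple[str, int, str, str]


def simulate_records(config: SimulationConfig) -> SimulatedCohort:
    """Simulate the cohort in memory.

    Draw order (fixed for reproducibility): causal-variant transmission and
    phenotypes (only when penetrance < 1), then per noise variant — chrX
    flag, MAF, chromosome/position, impact class, founder alleles,
    transmission choices in pedigree order — then missing-call masks in
    record order.
    """
    ped = config.pedigree or build_canonical_pedigree()
    rng = np.random.default_rng(config.seed)
    x_causal = config.model is InheritanceModel.X_LINKED_DOMINANT

    # causal variant: with complete penetrance carriers are exactly the
    # affected members (no phenocopies); below 1, alleles descend from the
    # affected founder female and phenotypes are re-drawn from carrier state
    if config.penetrance >= 1.0:
        causal_geno = {
            ind.member_id: _carrier_pattern_geno(
                ind, ind.phenotype is Phenotype.AFFECTED, x_causal
            )
            for ind in ped
        }
    else:
        # the causal allele enters through one founder carrier: the first
        # affected founder if any, else the first founder in pedigree order
        founders = ped.founders()
        carriers = [f for f in founders if f.phenotype is Phenotype.AFFECTED]
        entry = (carriers or founders)[0].member_id
        founder_geno = {
            f.member_id: _carrier_pattern_geno(f, f.member_id == entry, x_causal)
            for f in founders
        }
        causal_geno = _transmit(ped, founder_geno, x_causal, rng)
        individuals = []
        for ind in ped:
            carrier = sum(causal_geno[ind.member_id]) > 0
            affected = carrier and bool(rng.random() < config.penetrance)
            individuals.append(replace(
                ind,
                phenotype=Phenotype.AFFECTED if affected else Phenotype.UNAFFECTED,
            ))
        ped = Pedigree(individuals, ped.genotyped_subset)

    chrom, pos, ref, alt = CAUSAL_SITE[config.model]
    causal = VariantRecord(
        chrom=chrom, pos=pos, ref=ref, alt=alt, rsid=None, gene=CAUSAL_GENE,
        transcript_id="ENST_CAUSAL", effect="missense_variant",
        impact_class=Impact.MODERATE,
        maf={"ASN": config.causal_pop_maf},
        genotypes={m: GenotypeCall(causal_geno[m]) for m in ped.member_ids},
    )

    records = [causal]
    used = {causal.key}
    lo, hi = config.noise_maf_range
    for k in range(config.n_noise_variants):
        x_linked = bool(rng.random() < config.fraction_x_linked_noise)
        maf = float(lo + (hi - lo) * rng.random())
        while True:
            c = "X" if x_linked else str(int(rng.integers(1, 23)))
            p = int(rng.integers(1, 200_000_000))
            if (c, p, "A", "G") not in used:
                break
        used.add((c, p, "A", "G"))
        impact = _IMPACT_ORDER[rng.choice(4, p=np.asarray(config.impact_probs))]
        geno = _transmit(ped, _founder_draw(ped, maf, x_linked, rng), x_linked, rng)
        records.append(VariantRecord(
            chrom=c, pos=p, ref="A", alt="G", rsid=None, gene=f"NOISE{k}",
            transcript_id=f"ENST_NOISE{k}", effect=_EFFECT_OF_IMPACT[impact],
            impact_class=impact, maf={"ASN": maf},
            genotypes={m: GenotypeCall(geno[m]) for m in ped.member_ids},
        ))

    if config.missing_rate > 0:
        for rec in records:
            for m in ped.member_ids:
                if rng.random() < config.missing_rate:
                    rec.genotypes[m] = MISSING_CALL

    records.sort(key=lambda v: ((23, v.chrom) if v.chrom == "X"
                                else (int(v.chrom), v.chrom), v.pos))
    return SimulatedCohort(pedigree=ped, records=records, causal_key=causal.key)


def simulate_cohort(config: SimulationConfig,
                    out_prefix: str | Path) -> tuple[Path, Path, Path]:
    """Simulate and write ``<prefix>.vcf``, ``<prefix>.ped``,
    ``<prefix>.annot.tsv``; VCF sample columns are the genotyped subset.

    Identical configs (same seed) produce byte-identical files.
    """
    cohort = simulate_records(config)
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    vcf_path = out_prefix.with_suffix(".vcf")
    ped_path = out_prefix.with_suffix(".ped")
    annot_path = Path(str(out_prefix) + ".annot.tsv")

    ped = cohort.pedigree
    samples = [m for m in ped.member_ids if m in ped.genotyped_subset]
    vcf_records = []
    for v in cohort.records:
        vcf_records.append(replace_genotypes(v, {m: v.genotypes[m] for m in samples}))
    write_vcf(vcf_records, samples, vcf_path)
    write_ped(ped, ped_path)
    write_annotation_table(cohort.records, annot_path)
    return vcf_path, ped_path, annot_path


def replace_genotypes(v: VariantRecord, genotypes) -> VariantRecord:
    return VariantRecord(
        chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt, rsid=v.rsid,
        gene=v.gene, transcript_id=v.transcript_id, effect=v.effect,
        impact_class=v.impact_class, maf=dict(v.maf), genotypes=dict(genotypes),
    )


def make_table_fixtures(out_dir: str | Path) -> tuple[Path, Path, Path]:
    """Write the published-genotype-matrix fixture as VCF + PED + TSV.

    Round-trips through the VCF reader into records equal to
    :func:`mendelsieve.variants.make_fixture_tables`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = make_fixture_tables()
    ped = fixture_pedigree()
    vcf_path = out_dir / "fixture.vcf"
    ped_path = out_dir / "fixture.ped"
    annot_path = out_dir / "fixture.annot.tsv"
    write_vcf(records, list(GENOTYPED_SUBSET), vcf_path)
    write_ped(ped, ped_path)
    write_annotation_table(records, annot_path)
    return vcf_path, ped_path, annot_path


# -- exact pattern probability (transmission-tree peeling) ----------------

def _domain(sex: Sex, x_linked: bool) -> tuple[int, ...]:
    return (0, 1) if (x_linked and sex is Sex.MALE) else (0, 1, 2)


def _prior(g: int, sex: Sex, maf: float, x_linked: bool) -> float:
    p, q = maf, 1.0 - maf
    if x_linked and sex is Sex.MALE:
        return q if g == 0 else p
    return (q * q, 2 * p * q, p * p)[g]


def _trans_prob(gc: int, gf: int, gm: int, child_sex: Sex, x_linked: bool) -> float:
    """P(child alt-dose gc | father dose gf, mother dose gm)."""
    pm = gm / 2.0  # P(maternal allele is alt)
    if x_linked:
        if child_sex is Sex.MALE:
            return pm if gc == 1 else 1.0 - pm
        pf = float(gf)  # father passes his single X
        return (1.0 - pf) * (1.0 - pm) if gc == 0 else (
            pf * (1.0 - pm) + (1.0 - pf) * pm if gc == 1 else pf * pm
        )
    pf = gf / 2.0
    if gc == 0:
        return (1 - pf) * (1 - pm)
    if gc == 1:
        return pf * (1 - pm) + (1 - pf) * pm
    return pf * pm


def pattern_probability(
    ped: Pedigree,
    maf: float,
    model: InheritanceModel,
    *,
    genotyped: frozenset[str] | None = None,
) -> float:
    """Exact probability that a random variant at population frequency
    ``maf`` matches the dominant carrier pattern over the genotyped
    labelled members (affected heterozygous / hemizygous-alt, unaffected
    carrying no alternate allele).

    Founders are Hardy–Weinberg at ``maf``; children receive alleles by
    Mendelian transmission (X hemizygosity respected). Computed by exact
    peeling over the pedigree's transmission tree; supports loop-free
    pedigrees in which every individual has at most one mate and each
    mated pair includes at least one founder — the structure of the
    canonical family.
    """
    x = model is InheritanceModel.X_LINKED_DOMINANT
    genotyped = ped.genotyped_subset if genotyped is None else genotyped

    def constraint(ind: Individual, g: int) -> bool:
        if ind.member_id not in genotyped:
            return True
        if ind.phenotype is Phenotype.AFFECTED:
            return g == 1
        if ind.phenotype is Phenotype.UNAFFECTED:
            return g == 0
        return True

    mates: dict[str, str] = {}
    children: dict[tuple[str, str], list[Individual]] = {}
    for ind in ped:
        if ind.is_founder:
            continue
        key = (ind.father_id, ind.mother_id)
        children.setdefault(key, []).append(ind)
        for a, b in ((ind.father_id, ind.mother_id), (ind.mother_id, ind.father_id)):
            if mates.setdefault(a, b) != b:
                raise ValueError("pattern_probability requires monogamous pedigrees")

    def couple_prob(fa: Individual, mo: Individual, gf: int, gm: int) -> float:
        total = 1.0
        for child in children[(fa.member_id, mo.member_id)]:
            acc = 0.0
            for gc in _domain(child.sex, x):
                if not constraint(child, gc):
                    continue
                t = _trans_prob(gc, gf, gm, child.sex, x)
                if t:
                    acc += t * down(child, gc)
            total *= acc
        return total

    def down(ind: Individual, g: int) -> float:
        mate_id = mates.get(ind.member_id)
        if mate_id is None:
            return 1.0
        mate = ped[mate_id]
        if not mate.is_founder:
            raise ValueError("pattern_probability: mated pair with no founder")
        fa, mo = (ind, mate) if ind.sex is Sex.MALE else (mate, ind)
        acc = 0.0
        for gs in _domain(mate.sex, x):
            if not constraint(mate, gs):
                continue
            prior = _prior(gs, mate.sex, maf, x)
            gf, gm = (g, gs) if ind.sex is Sex.MALE else (gs, g)
            acc += prior * couple_prob(fa, mo, gf, gm)
        return acc

    prob = 1.0
    handled: set[str] = set()

    def mark_subtree(ind: Individual) -> None:
        handled.add(ind.member_id)
        mate_id = mates.get(ind.member_id)
        if mate_id is not None and mate_id not in handled:
            handled.add(mate_id)
            fa_id = ind.member_id if ind.sex is Sex.MALE else mate_id
            mo_id = mate_id if ind.sex is Sex.MALE else ind.member_id
            for child in children.get((fa_id, mo_id), []):
                mark_subtree(child)

    for key, kids in children.items():
        fa, mo = ped[key[0]], ped[key[1]]
        if not (fa.is_founder and mo.is_founder):
            continue
        if fa.member_id in handled:
            continue
        acc = 0.0
        for gf in _domain(fa.sex, x):
            if not constraint(fa, gf):
                continue
            for gm in _domain(mo.sex, x):
                if not constraint(mo, gm):
                    continue
                acc += (_prior(gf, fa.sex, maf, x) * _prior(gm, mo.sex, maf, x)
                        * couple_prob(fa, mo, gf, gm))
        prob *= acc
        mark_subtree(fa)

    # remaining founders (no children: unmated, or a childless couple) are
    # independent of the rest; multiply their constrained prior mass in
    for ind in ped:
        if ind.member_id in handled or not ind.is_founder:
            continue
        prob *= sum(
            _prior(g, ind.sex, maf, x)
            for g in _domain(ind.sex, x)
            if constraint(ind, g)
        )
        handled.add(ind.member_id)

    return prob
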