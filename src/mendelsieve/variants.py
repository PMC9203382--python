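"""Multi-sample VCF records with genotypes and filter annotations.

Each record carries per-member genotype calls (diploid, or hemizygous
length-1 calls for males on chrX) plus the annotation columns the filter
cascade consumes: gene symbol, SnpEff-style impact class, and population
minor-allele frequencies. An *undefined* MAF (no reported frequency) is
distinct from a frequency of 0.0: it is simply absent from the mapping.

VCF parsing and writing go through pysam; annotations travel either in a
SnpEff-style ``ANN`` INFO field or in a sidecar TSV keyed by
chrom:pos:ref:alt.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Literal, Mapping

import pandas as pd
import pysam

from .pedigree import Pedigree, Sex

log = logging.getLogger(__name__)


class Impact(Enum):
    HIGH = "HIGH"
    MODERATE = "MODERATE"
    LOW = "LOW"
    MODIFIER = "MODIFIER"


class VariantError(ValueError):
    pass


class GenotypeInconsistency(VariantError):
    """A heterozygous diploid call for a male on chrX."""


def normalize_chrom(chrom: str) -> str:
    c = chrom.removeprefix("chr").removeprefix("Chr").upper()
    return "X" if c == "X" else chrom.removeprefix("chr")


@dataclass(frozen=True)
class GenotypeCall:
    """Alleles of one sample at one site: 0 = ref, 1 = alt.

    Length 2 for diploid calls, length 1 for hemizygous calls (males on
    chrX); empty with ``missing=True`` for no-calls.
    """

    alleles: tuple[int, ...]
    missing: bool = False

    def __post_init__(self) -> None:
        if self.missing and self.alleles:
            raise VariantError("missing call must have no alleles")
        if not self.missing and len(self.alleles) not in (1, 2):
            raise VariantError(f"call must be diploid or hemizygous: {self.alleles}")
        if any(a not in (0, 1) for a in self.alleles):
            raise VariantError(f"allele indices must be 0/1: {self.alleles}")

    @property
    def is_hemizygous(self) -> bool:
        return len(self.alleles) == 1

    @property
    def alt_count(self) -> int:
        return sum(self.alleles)

    @property
    def is_het(self) -> bool:
        return len(self.alleles) == 2 and self.alt_count == 1

    @property
    def is_hom_ref(self) -> bool:
        return not self.missing and self.alt_count == 0

    def to_vcf(self) -> str:
        if self.missing:
            return "./."
        return "/".join(str(a) for a in self.alleles)


MISSING_CALL = GenotypeCall(alleles=(), missing=True)


@dataclass
class VariantRecord:
    """One biallelic variant with per-member calls and annotations."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    rsid: str | None = None
    gene: str = ""
    transcript_id: str = ""
    effect: str = ""
    impact_class: Impact | None = None
    maf: dict[str, float] = field(default_factory=dict)
    genotypes: dict[str, GenotypeCall] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.chrom = normalize_chrom(self.chrom)
        if self.pos < 1:
            raise VariantError(f"pos must be ≥ 1, got {self.pos}")
        if self.ref == self.alt:
            raise VariantError("ref and alt alleles must differ")
        for label, f in self.maf.items():
            if not (0.0 <= f <= 1.0):
                raise VariantError(f"MAF[{label}] = {f} outside [0, 1]")

    @property
    def is_x_linked(self) -> bool:
        return self.chrom == "X"

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def maf_of(self, population: str) -> float | None:
        """Population MAF, or None when no frequency is reported."""
        return self.maf.get(population)


# -- VCF reading -----------------------------------------------------------

def _normalize_call(
    gt: tuple[int | None, ...],
    *,
    male: bool,
    x_linked: bool,
    inconsistency: Literal["raise", "drop"],
) -> GenotypeCall | None:
    """Map a pysam GT tuple to a GenotypeCall.

    On chrX, male calls are normalised to hemizygous length-1 calls:
    a single-allele GT is kept, a homozygous diploid GT collapses to its
    allele, and a heterozygous diploid GT is a genotype inconsistency
    (returns None under the "drop" policy, meaning: drop the variant).
    """
    alleles = tuple(a for a in gt if a is not None)
    if len(alleles) != len(gt) or not alleles:
        return MISSING_CALL
    if x_linked and male:
        if len(alleles) == 1:
            return GenotypeCall(alleles)
        if alleles[0] == alleles[1]:
            return GenotypeCall((alleles[0],))
        if inconsistency == "raise":
            raise GenotypeInconsistency(
                f"heterozygous diploid GT {alleles} for a male on chrX"
            )
        return None
    return GenotypeCall(alleles)


def read_vcf(
    path: str | Path,
    ped: Pedigree,
    annotations: "pd.DataFrame | str | Path | None" = None,
    *,
    population_map: Mapping[str, str] | None = None,
    multiallelic: Literal["error", "skip", "split"] = "error",
    x_inconsistency: Literal["raise", "drop"] = "raise",
) -> list[VariantRecord]:
    """Read a multi-sample VCF into VariantRecords for the pedigree's members.

    Samples absent from the pedigree are ignored; there must be at least one
    overlapping sample. Annotations come from a sidecar TSV (see
    :func:`read_annotation_table`) or, failing that, from a SnpEff-style
    ``ANN`` INFO field (impact = 3rd sub-field).
    """
    if annotations is not None and not isinstance(annotations, pd.DataFrame):
        annotations = read_annotation_table(annotations)
    ann_index = _annotation_index(annotations) if annotations is not None else {}

    with pysam.VariantFile(str(path)) as vcf:
        samples = [s for s in vcf.header.samples if s in ped]
        if not samples:
            raise VariantError("no VCF samples overlap the pedigree")
        records: list[VariantRecord] = []
        for rec in vcf:
            alts = rec.alts or ()
            if len(alts) != 1:
                if len(alts) == 0 or multiallelic == "skip":
                    log.warning("skipping non-biallelic record %s:%s", rec.chrom, rec.pos)
                    continue
                if multiallelic == "error":
                    raise VariantError(
                        f"multiallelic record at {rec.chrom}:{rec.pos} "
                        "(pass multiallelic='split' or 'skip')"
                    )
                for k in range(len(alts)):
                    out = _build_record(rec, alts[k], k + 1, samples, ped,
                                        ann_index, population_map, x_inconsistency)
                    if out is not None:
                        records.append(out)
                continue
            out = _build_record(rec, alts[0], 1, samples, ped,
                                ann_index, population_map, x_inconsistency)
            if out is not None:
                records.append(out)
    return records


def _build_record(rec, alt, alt_index, samples, ped, ann_index,
                  population_map, x_inconsistency) -> VariantRecord | None:
    chrom = normalize_chrom(rec.chrom)
    x_linked = chrom == "X"
    genotypes: dict[str, GenotypeCall] = {}
    for s in samples:
        gt = rec.samples[s].get("GT") or (None,)
        # when splitting multiallelics, any other alt is folded into ref
        gt = tuple(None if a is None else (1 if a == alt_index else 0) for a in gt)
        call = _normalize_call(
            gt,
            male=ped[s].sex is Sex.MALE,
            x_linked=x_linked,
            inconsistency=x_inconsistency,
        )
        if call is None:
            log.warning("dropping %s:%s: male X heterozygote in sample %s",
                        chrom, rec.pos, s)
            return None
        genotypes[s] = call

    v = VariantRecord(
        chrom=chrom,
        pos=rec.pos,
        ref=rec.ref,
        alt=alt,
        rsid=None if rec.id in (None, ".") else rec.id,
        genotypes=genotypes,
    )
    ann = ann_index.get(v.key)
    if ann is not None:
        v.gene = ann["gene"]
        v.transcript_id = ann["transcript"]
        v.effect = ann["effect"]
        v.impact_class = ann["impact"]
        v.maf = dict(ann["maf"])
    else:
        _annotate_from_info(v, rec, population_map)
    return v


def _info_get(rec, key):
    # pysam raises on INFO keys absent from the header; treat as undefined
    try:
        return rec.info.get(key)
    except (KeyError, ValueError):
        return None


def _annotate_from_info(v: VariantRecord, rec, population_map) -> None:
    ann = _info_get(rec, "ANN")
    if ann:
        first = (ann[0] if isinstance(ann, tuple) else ann).split("|")
        if len(first) >= 4:
            v.effect = first[1]
            try:
                v.impact_class = Impact(first[2])
            except ValueError:
                pass
            v.gene = first[3]
            if len(first) >= 7:
                v.transcript_id = first[6]
    for label, key in (population_map or {"ASN": "MAF_ASN", "ALL": "MAF_ALL"}).items():
        val = _info_get(rec, key)
        if val is not None:
            v.maf[label] = float(val[0] if isinstance(val, tuple) else val)


# -- sidecar annotation TSV ------------------------------------------------

_ANNOT_COLUMNS = ["chrom", "pos", "ref", "alt", "gene", "transcript",
                  "effect", "impact", "maf_asn", "maf_all"]


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    """Read the sidecar annotation TSV.

    Columns: chrom, pos, ref, alt, gene, transcript, effect, impact,
    maf_asn, maf_all. Empty / "NA" / "Not_defined" frequencies mean the
    MAF is unreported (undefined), not zero.
    """
    df = pd.read_csv(
        path, sep="\t", dtype={"chrom": str},
        na_values=["NA", "Not_defined", ""], keep_default_na=True,
    )
    missing = set(_ANNOT_COLUMNS) - set(df.columns)
    if missing:
        raise VariantError(f"annotation table lacks columns: {sorted(missing)}")
    return df


def write_annotation_table(records: list[VariantRecord], path: str | Path) -> None:
    rows = []
    for v in records:
        rows.append({
            "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
            "gene": v.gene, "transcript": v.transcript_id, "effect": v.effect,
            "impact": v.impact_class.value if v.impact_class else "NA",
            "maf_asn": v.maf.get("ASN", float("nan")),
            "maf_all": v.maf.get("ALL", float("nan")),
        })
    pd.DataFrame(rows, columns=_ANNOT_COLUMNS).to_csv(path, sep="\t", index=False)


def _annotation_index(df: pd.DataFrame) -> dict:
    index = {}
    for row in df.itertuples(index=False):
        maf = {}
        if pd.notna(row.maf_asn):
            maf["ASN"] = float(row.maf_asn)
        if pd.notna(row.maf_all):
            maf["ALL"] = float(row.maf_all)
        try:
            impact = Impact(str(row.impact))
        except ValueError:
            impact = None
        index[(normalize_chrom(str(row.chrom)), int(row.pos), row.ref, row.alt)] = {
            "gene": "" if pd.isna(row.gene) else str(row.gene),
            "transcript": "" if pd.isna(row.transcript) else str(row.transcript),
            "effect": "" if pd.isna(row.effect) else str(row.effect),
            "impact": impact,
            "maf": maf,
        }
    return index


# -- VCF writing -----------------------------------------------------------

def write_vcf(records: list[VariantRecord], sample_ids: list[str],
              path: str | Path) -> None:
    """Write records as a minimal VCF 4.2 with GT-only FORMAT fields.

    Output is deterministic (fixed header, no timestamps) so identical
    inputs produce byte-identical files. Hemizygous calls are written as
    single-allele GTs ("1"), which pysam reads back as length-1 tuples.
    """
    chroms = list(dict.fromkeys(v.chrom for v in records))
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in chroms]
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids))
    for v in records:
        gts = [v.genotypes.get(s, MISSING_CALL).to_vcf() for s in sample_ids]
        lines.append("\t".join([
            v.chrom, str(v.pos), v.rsid or ".", v.ref, v.alt,
            ".", "PASS", ".", "GT", *gts,
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


# -- in-memory worked example (published genotype matrix) ------------------

_FIXTURE_MEMBERS = [
    # (id, sex, affected)
    ("2-1", Sex.MALE, False),
    ("2-2", Sex.FEMALE, True),
    ("2-4", Sex.FEMALE, True),
    ("3-1", Sex.MALE, True),
    ("3-3", Sex.MALE, True),
    ("3-4", Sex.FEMALE, False),
    ("3-5", Sex.MALE, True),
    ("3-6", Sex.FEMALE, False),
    ("4-3", Sex.MALE, False),
    ("4-6", Sex.FEMALE, True),
    ("4-7", Sex.FEMALE, True),
    ("4-8", Sex.FEMALE, True),
]

_FIXTURE_VARIANTS = [
    # gene, rsid, chrom, pos, ref, alt, transcript, ASN MAF, overall MAF
    ("MROH7", "rs143029488", "1", 55175825, "G", "C", "ENST00000421030", 0.0105, 0.0027),
    ("FAT2", "rs7718054", "5", 150908812, "C", "T", "ENST00000261800", 0.0437, 0.0691),
    ("MTERF2", None, "12", 107372401, "G", "C", "ENST00000240050", None, None),
    ("HCCS", "rs191165757", "X", 11133044, "G", "A", "ENST00000321143", 0.0017, 0.0006),
]


def make_fixture_tables() -> list[VariantRecord]:
    """The four filtered candidate variants of the index family.

    Encodes the published 12-member genotype matrix: every affected member
    is a carrier (heterozygous, or hemizygous-alt for the X-linked HCCS
    variant in affected males) and every unaffected member is a
    non-carrier. The MTERF2 variant has no reported population frequency.
    """
    records = []
    for gene, rsid, chrom, pos, ref, alt, tx, maf_asn, maf_all in _FIXTURE_VARIANTS:
        x = chrom == "X"
        genotypes = {}
        for member, sex, affected in _FIXTURE_MEMBERS:
            male = sex is Sex.MALE
            if x and male:
                genotypes[member] = GenotypeCall((1,) if affected else (0,))
            else:
                genotypes[member] = GenotypeCall((0, 1) if affected else (0, 0))
        maf = {}
        if maf_asn is not None:
            maf["ASN"] = maf_asn
        if maf_all is not None:
            maf["ALL"] = maf_all
        records.append(VariantRecord(
            chrom=chrom, pos=pos, ref=ref, alt=alt, rsid=rsid, gene=gene,
            transcript_id=tx, effect="missense_variant",
            impact_class=Impact.MODERATE, maf=maf, genotypes=genotypes,
        ))
    return records
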