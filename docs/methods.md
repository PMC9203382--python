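# Methods

## Segregation model

The cascade targets a fully penetrant dominant variant in a single family:
carrier state must coincide exactly with affection status. Two models are
supported, selected automatically by chromosome — autosomal dominant for
autosomal records, X-linked dominant for chrX records. Testing each
variant only under its chromosome's model avoids vacuous autosomal tests
on hemizygous calls; the models are chromosome-specific by definition.

Assumptions, all strict by default:

- **Complete penetrance, no phenocopies.** An affected non-carrier or
  unaffected carrier anywhere in the genotyped, labelled members rejects
  the variant. No de novo allowance.
- **Heterozygous carriers.** Affected members must be heterozygous
  (hemizygous-alt for males on chrX); a homozygous-alt affected member
  fails the dominant single-copy pattern.
- **Missing genotypes** fail the variant under the default `strict`
  policy; a `lenient` policy lets missing calls abstain. Strict matches a
  complete genotype matrix; lenient is the right choice for call sets with
  appreciable no-call rates.
- **Unknown-phenotype members never veto** — they belong to neither
  comparison set.

Male chrX calls are normalised to hemizygous length-1 calls on input:
single-allele GTs are kept, homozygous diploid GTs collapse to one allele,
and a heterozygous diploid male X call is a genotype inconsistency
(configurable: raise, or drop the variant). All of chrX is treated as
hemizygous in males; pseudoautosomal regions are not modelled (documented
limitation — PAR variants in males would need diploid handling).

Filter order is segregation → MAF → impact. The MAF and impact stages
commute as set operations (property-tested); the order only fixes the
audit-trail sequence. Reports sort candidates by (chromosome, position)
for determinism regardless of input order.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `maf_threshold` | 0.05 | strict upper bound on population MAF; a variant at exactly the threshold is removed, an *undefined* MAF passes (three-valued semantics: undefined ≠ 0) |
| `population` | `"ASN"` | MAF column used by the filter; labels are free strings |
| `missing_policy` | `strict` | see above |
| impact classes kept | HIGH, MODERATE | SnpEff-style severity; LOW and MODIFIER removed |

## Literature co-citation enrichment

The co-citation question — are articles mentioning the gene enriched among
articles mentioning the disease? — is a one-sided Fisher exact test on the
2×2 table (a = co-mentions, b = gene-only, c = disease-only, d = neither).
The p-value is the hypergeometric upper tail

    p = Σ_{k=a}^{min(a+b, a+c)} C(a+b, k) C(c+d, a+c−k) / C(N, a+c),

computed term-by-term in log space with `lgamma`-based binomial
coefficients, so article universes of 10⁷ and beyond pose no overflow; for
every table with N ≤ 60 the result matches exact-rational enumeration to
10⁻¹². When a = 0 the tail is the whole support and p is returned as
exactly 1.0.

The odds ratio is the raw cross-product `ad/bc` with no Haldane–Anscombe
correction: a = 0 gives OR = 0, a vanishing denominator with a positive
numerator gives +inf, and a table where both products vanish is rejected
as undefined. The one-sided ("greater") alternative is used throughout —
the scientific question is enrichment, and zero-co-mention rows then take
the analytically fixed values OR = 0, p = 1 for *any* universe size.

The universe size N is a required input. It is typically not published
alongside co-citation tables, and a non-zero OR cannot be reproduced
without it; this package does not guess it. (For the motivating study's
non-zero row, back-solving the printed OR implies a universe of roughly
2.6 M articles, presumably the text-mining corpus's annotated subset; the
package treats that as user input, not as a constant.)

## Structure-based site assessment

SASA uses the Shrake–Rupley quadrature: each atom's van der Waals sphere
is inflated by the probe radius (default 1.4 Å, a water molecule), test
points are placed on a deterministic golden-spiral (Fibonacci) lattice
(default 960 points/atom), and a point is accessible iff it lies outside
every other atom's inflated sphere. Neighbour candidates come from a k-d
tree query at the maximal occlusion distance, keeping cost near-linear in
atom count. The golden-spiral lattice makes results exactly reproducible;
an isolated atom recovers 4π(r+p)² to machine accuracy because every point
is accessible, and doubling the point count changes cluster totals by
under 2% (tested). Rolling-probe tools that slice the surface instead
(Lee–Richards style, as in Naccess) agree to within a few percent but not
exactly; absolute SASA values from different tools should not be compared
at sub-percent precision.

Radii: C 1.70, N 1.55, O 1.52, S 1.80 Å; hydrogens are stripped (predicted
models and most depositions lack them); unknown elements fall back to the
carbon radius with a warning. The radius table is overridable.

RSA normalises residue SASA by a reference maximum per residue type. The
default table is the theoretical-maximum set (extended Gly-X-Gly context);
a Naccess-compatible Ala-X-Ala table is selectable for comparability with
that tool's output. Burial classes: RSA < 10% deeply buried, < 25%
buried, otherwise exposed.

Contacts: residues i, j with |i−j| > 1 are in contact iff any heavy-atom
pair is within 5.0 Å. Both cutoff and the sequence-neighbour window are
exposed, since published contact networks vary in their exact criterion;
side-chain-only contact counting is not implemented, so contact counts may
differ from tools that exclude backbone atoms. `assess_site` bundles SASA,
RSA, burial class, the contact set, and whether designated functional
residues (e.g. a catalytic histidine) are direct contacts. Qualitative
conclusions (buried vs exposed; functional contact present) are robust
across these conventions; exact RSA values and contact counts are
tool- and model-version-dependent.

## Synthetic cohorts

The generator emulates the study conditions: a canonical 4-generation,
31-member pedigree with 9 affected members and a sequenced subset of 12
(8 affected, 4 unaffected; 7 female, 5 male). The published counts fix the
pedigree's size and composition but not its full topology, so the topology
here is invented under two constraints: the causal allele enters through
an affected founder female, and the affection labels are transmission-
consistent under *both* dominant models (every affected male has an
affected mother; every affected father's daughters are affected). It is
count-faithful, not a reconstruction of the real family.

Simulation mechanics:

- **Causal variant.** At complete penetrance (default 1.0) carriers are
  exactly the affected members — heterozygous, or hemizygous-alt for males
  on chrX. Below 1.0, alleles descend from the founder carrier by
  simulated transmission and phenotypes are re-drawn as
  Bernoulli(penetrance) for carriers; non-carriers are always unaffected
  (no phenocopies). The X-linked causal site reuses the index variant's
  coordinate (chrX:11,133,044 G>A) with its reported population frequency
  0.0017 as the default `causal_pop_maf`.
- **Noise variants** (default 200/cohort): founders draw alleles
  independently at a per-variant MAF uniform on [0, 0.5]; children receive
  one allele from each parent (on chrX: fathers transmit their single X to
  daughters only, sons take a maternal draw). Impact classes are drawn
  25% each HIGH/MODERATE/LOW/MODIFIER so both downstream filters are
  exercised; 5% of noise variants are X-linked, roughly chrX's share of
  exome variation.
- **Determinism.** One seeded generator with a documented draw order;
  identical configs produce byte-identical VCF/PED/TSV files.
- Missing calls are injected at `missing_rate` (default 0).

Not emulated: linkage disequilibrium between variants, sequencing error,
genotype-calling artefacts, population structure among founders, and
phenocopies. Passing tests therefore demonstrate correctness of the
filtering logic under idealised Mendelian sampling, not robustness to
real-world call-set noise — the `lenient` missing policy and the
inconsistency-handling flags are the knobs for the latter.

### Exact pattern probability

`pattern_probability` returns the exact probability that a random variant
at a given population frequency matches the dominant carrier pattern
across the genotyped labelled members, by peeling (sum–product elimination)
over the pedigree: founder genotypes are Hardy–Weinberg, transmissions
Mendelian, and the X-linked variant uses sex-specific genotype domains.
The implementation covers loop-free pedigrees in which each individual has
at most one mate and every mated pair includes a founder — the canonical
family's structure — and is unit-tested against brute-force enumeration of
founder genotypes × transmission choices on small pedigrees. This is the
analytic oracle for the simulator: the observed number of noise variants
surviving the cascade is compared with the sum of per-variant exact
probabilities (a Poisson-binomial mean) within three standard errors.

## Problem sizes

The packaged verification sweep uses 100 cohorts × 200 noise variants on
the 31-member pedigree, exhaustive Fisher enumeration for tables with
N ≤ 25 plus 2,000 sampled tables up to N = 60, and 10⁵-point dense-grid
SASA oracles on 5-atom clusters — sizes at which every stochastic check is
backed by an exact expectation and the whole suite runs in seconds.

## Known limitations

- No autosomal-recessive or compound-heterozygous models; no linkage LOD
  scores; no imputation.
- chrX PAR handling (see above); multiallelic records must be split or
  skipped explicitly; indels pass through the segregation logic untouched
  but are not specially modelled.
- The real family's raw sequencing data are not public, so genome-scale
  variant totals cannot be reproduced here; the simulator provides the
  statistically matched stand-in.
- Enrichment applies no multiple-testing correction across genes (batch
  output reports raw per-gene p-values).
- SASA/RSA absolute values differ by a few percent across algorithms and
  reference tables; burial classes near a threshold can flip accordingly.
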