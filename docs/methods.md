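# Methods

`felmap` reconstructs genetic linkage maps from multigenerational pedigrees
genotyped on a dense biallelic SNP array, analyses the resulting
recombination landscape, and anchors assembly scaffolds along the maps. This
note records the models, the estimation machinery, the synthetic-data
generator, and the design decisions that were genuinely open.

## Inheritance model

A *meiosis* is one parent-to-offspring transmission. At a heterozygous
marker the parent transmits one of its two homologs; along a chromosome the
transmitted-homolog indicator follows a two-state Markov chain whose
transition probability across interval *i* is the interval recombination
fraction `r_i` (0 ≤ r ≤ 0.5). With no crossover interference (the Haldane
model) chains of different meioses are independent, and the number of
crossovers in a region of genetic length L Morgans is Poisson(L).

Whether the transmitted allele can be read off the genotypes varies by
marker: the parent must be heterozygous and the offspring/other-parent
genotypes must pin the transmitted allele ("informative meiosis", IM). The
*phase* — which observed allele sits on which homolog — is resolved where
the parent's own parents are genotyped and determine the parental origin of
its alleles; homolog 0 is defined as the homolog inherited from the
parent's sire. Where phase is unresolved it is treated as a per-marker
latent variable with prior 1/2 (exactly correct for founder haplotypes,
whose allele arrangements are independent across markers).

### Two-point likelihood

For a marker pair, phase-resolved meioses give a binomial likelihood
`r^k (1-r)^(n-k)`. Meioses whose relative phase is unresolved enter through
an exact per-parent two-phase mixture (all offspring of a parent share its
phase), which retains founder meioses instead of discarding them. `r̂`
maximises the mixture likelihood (closed form `k/n` when no mixture terms);
LOD = log10 L(r̂) − log10 L(0.5). Linkage groups are connected components of
the LOD ≥ 8 graph; groups are labelled by the majority physical chromosome
of their markers, with ties flagged.

### Multipoint likelihood (ordering)

Marker ordering uses a per-meiosis hidden-path likelihood: emissions fix
the chain state where the inheritance symbol is known, are free where it is
unknown, and unresolved-phase symbols contribute an exact constant factor
1/2 each (the per-marker phase sum for a single offspring). The total is
the sum of per-meiosis log10 likelihoods. An optional exact mode
(`MultipointEngine(joint_families=True)`) models all offspring of an
unresolved-phase parent jointly (state space 2^K, summing the shared
per-marker phase); it is verified against exhaustive enumeration but is not
the default because the per-meiosis form is orders of magnitude faster and
ordering decisions compare the same data under both hypotheses.

Interval fractions for a fixed order are estimated by EM: expected
recombination counts over expected informative transitions, with a floor of
1e-6 and convergence when the relative log-likelihood change drops below
1e-8 (default cap 100 iterations). Insertion scans and window-permutation
scans re-estimate only the intervals they touch against cached
forward/backward messages, which makes the build loop tractable; a full EM
polish runs periodically and at the end of every stage.

### Trio-genotype likelihood (distances)

Final interval distances and sex-specific maps use a different, finer
likelihood: each offspring is a four-state chain over (maternal homolog,
paternal homolog), the maternal bit switching with the female fraction
`r_f,i` and the paternal bit with the male `r_m,i`, and the emission is the
probability of the offspring's observed genotype given the two transmitted
homologs (parental phase marginalised per marker, missing parental calls
marginalised at the sample allele frequency). The sex-averaged map ties
`r_f = r_m` in the M-step.

The reason for the second likelihood is selection bias in the symbol
extraction: a marker is "informative" only when the offspring and
other-parent genotypes determine the transmitted allele, and that event
depends on the hidden states themselves (a het × het → het trio is
ambiguous precisely because of which homologs were transmitted).
Conditioning on informativeness therefore violates missing-at-random and
measurably distorts sex-specific map lengths — on simulated data the female
map deflates and the male map inflates by ~10–15%. Modelling the genotypes
directly removes the selection; the ambiguous trios then contribute their
genuine partial information (the two transmitted alleles must differ).

Dense marker grids bring a second, well-known effect: with ~25%
informativeness per meiosis, a 0.5 cM marker spacing gives each recombination
event a wide localisation bracket, and maximising hundreds of free interval
fractions against overlapping brackets inflates total length by several
percent. Interval estimates are therefore read off grids whose spacing is
commensurate with the localisation scale (the built map's positioned
markers, or a thinned physical grid for landscape profiles); this is also
why published dense maps report positioned subsets rather than every assayed
marker.

## Map construction

The pipeline mirrors classic pedigree-linkage practice:

1. **QC** — samples with call rate < 0.90 removed (boundary inclusive);
   markers kept only with call rate > 0.95 (strict); markers with any
   Mendelian-impossible trio call (or heterozygous male X call outside the
   PAR) removed; markers with fewer than 100 IM removed. Missing calls never
   count as violations or as informative. An optional duplicate-sample
   concordance check flags markers discordant between replicates.
2. **Framework** — markers with IM > 300 (strict) are ordered by iterative
   insertion; a marker is accepted when its best insertion position beats
   the runner-up by LOD ≥ 3. The seed is the strongest-linked eligible pair
   with r̂ in [0.04, 0.35]: a zero-length seed is left/right symmetric (no
   third marker can ever distinguish the ends) and a near-unlinked seed
   cannot discriminate sides, so a spanning, clearly linked core is
   required for growth. Deferred markers are retried after every pass.
3. **Windowed insertion** — remaining markers (IM ≥ 100) are assigned to
   500-marker physical windows stepping by 400 (overlap markers go to the
   window whose edge they are farthest from) and inserted at descending LOD
   tiers 2.0, 1.0, 0.5; placed markers immediately join the scaffold;
   framework relative order is never altered.
4. **Flips** — sliding 6-marker windows are permuted exhaustively (all 720
   orders, window fractions locally re-estimated per permutation); the best
   order is adopted on strict improvement, and passes repeat to a fixpoint.
5. **Expanders** — an interior non-framework marker whose removal (with
   local re-estimation of the merged interval) shrinks the map by more than
   3 cM is removed, largest first, one per rebuild, to a fixpoint. Terminal
   markers are exempt: removing an end marker always truncates the map,
   which is not inflation.
6. **Residuals** — markers that failed all tiers are assigned their most
   likely flanking interval when the best-vs-second interval gap is ≥ 0.1
   LOD (no cM position); otherwise they are reported unplaced with a reason.
7. **Sex maps** — female/male/sex-averaged cumulative cM from the
   trio-genotype EM on the final order; intervals with no informative
   bracketing meiosis of a sex are flagged and given a 0 cM increment.

Genetic distances use the Kosambi map function by default, with Haldane
selectable; simulation-recovery checks use Haldane end to end because the
generator's crossover process has no interference. Ties in insertion
position go to the lowest interval index; candidates are processed in
descending IM then marker id; all randomness is seeded.

## Recombination landscape

Positioned markers define a Marey map (cumulative cM against physical bp);
cM columns are made monotone by isotonic adjustment with adjusted markers
reported as order conflicts, and the interpolant is clamped outside the
terminal markers. Local rates are Marey-interpolant differences over 5 Mb
windows stepping by 1 Mb — interpolant-based rates are robust to uneven
marker spacing. Deserts are merged runs of windows below 0.1 cM/Mb spanning
at least 10 Mb (both thresholds are flags; the defaults flag a ~50 Mb
X-style desert while ignoring centromeric dips). Chromosome summaries
report cM/Mb and markers/Mb to one decimal, autosomal totals, and the
female:male map-length ratio.

## Scaffold anchoring

Scaffolds are assigned to chromosomes by majority marker vote (ties →
unplaced), ordered by median cM of supporting markers (ties by scaffold
id), and oriented by the sign of the Spearman correlation between scaffold
coordinate and map position ('?' with fewer than two distinct cM values).
Conflicts against a reference order: runs of ≥ 5 markers whose reference
coordinates run backwards are inversions; contiguous blocks of ≥ 5 markers
on a different reference chromosome are translocations; scaffolds whose
hits split into different map chromosomes (or cM clusters separated by
more than 25 cM) are chimeras with the breakpoint interval between the
flanking hits. The block size of 5 targets large-scale events only and is a
flag. Chromosome builds are written as AGP 2.0 with 100 bp scaffold gaps
(`linkage yes`, evidence `map`); unplaced scaffolds are singleton objects.

## Synthetic data generator

The generator emulates the mapping-colony data the pipeline expects:

* **Pedigree** — founders alternate sex; each generation mates every female
  to a male of the previous generation (males may serve several females,
  as in breeding colonies), Poisson family sizes (mean 4 by default, or
  exact with `offspring_dist="fixed"`). Offspring sexes alternate within a
  generation: the generator's job is to deliver a configured number of
  meioses, and random sex draws would let small colonies drift to
  single-sex generations and stall.
* **Landscape** — piecewise-linear cumulative cM per sex over bp knots,
  built from summary features: uniform base rate, ×2 within 10% of either
  chromosome end (telomere elevation), zero inside deserts, male cM flat
  outside the PAR on X. Female:male autosomal length ratio defaults to 1.7
  in the worked examples.
* **Gametes** — crossover count Poisson in genetic length, positions drawn
  uniformly in cM and mapped to bp by inverting the cumulative map (no
  interference; a gamma/chi-square interference model is deliberately not
  offered so that closed-form oracles hold). Male X gametes recombine only
  inside the PAR, and the non-PAR tail is pinned to the correct homolog.
* **Genotypes** — founder haplotypes drawn iid from per-marker B-allele
  frequencies (default Uniform(0.3, 0.7): array SNPs are ascertained to be
  common); males carry one X outside the PAR, coded as a homozygous diploid
  call; genotype error is symmetric random replacement; missingness is
  independent per call. Marker spacing defaults to 50 kb.
* **Truth files** — true marker order and cumulative cM per sex, and every
  crossover position per meiosis, written as TSV next to the PED/MAP pair.
  Founder phase is known internally but never exposed downstream.

What the generator does **not** emulate: linkage disequilibrium among
founders, breed structure, genotype-error patterns correlated with probe
chemistry, segmental duplications or other assembly artefacts, and
crossover interference. Passing recovery tests therefore demonstrate
correctness of the estimators under the stated model, not robustness to
every failure mode of real array data.

## Problem sizes in the shipped checks

The recovery checks simulate one ~100 cM chromosome with 150 markers at
50 kb and a 5-generation, 456-meiosis colony for the full build (framework
IM floor 100 here: an IM > 300 framework requires on the order of 900
meioses, as in colony-scale studies, and a ~450-meiosis design cannot
contain such markers); a 7-generation, 6048-meiosis colony for the
female:male ratio (read off a 5-marker-thinned grid, see the dense-grid
note above); and a 128 Mb X with a 50 Mb central desert, a 6 Mb PAR and
50 kb marker spacing for desert detection. The colonies use fixed family
sizes, which with alternating offspring sexes makes the meiosis count
deterministic. Map-length recovery is judged against the true genetic span
of the positioned markers — the estimand of the built map — and
marker-order recovery by Kendall's tau over positioned markers. At ~450
meioses the realized crossover total itself fluctuates with ~4.5%
standard deviation, which dominates the recovery error of the total
length; the estimator tracks the realized value within ~3%.

## Known limitations

* Ordering likelihoods condition on symbol informativeness (see above);
  the bias is immaterial for comparing candidate orders but is why final
  distances come from the trio-genotype chain instead.
* Phase is summed per marker with prior 1/2; for non-founder parents with
  partially resolved phase this discards the linkage information carried by
  the parent's own haplotype continuity.
* Ungenotyped ancestors are marginalised at sample allele frequencies, not
  peeled exactly (no Elston–Stewart machinery); multi-allelic markers and
  half-sib variance models are out of scope.
* The expander rule and window-overlap conflict rule are documented
  heuristics; the window conflict rule (assign to the window whose edge the
  marker is farthest from) keeps each marker's placement unique.
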