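# Methods

## Study design and model

`trioseg` implements the trio design for a rare, fully penetrant monogenic
trait. The proband is the unique affected individual whose recorded sire
and dam are both genotyped and unaffected (an explicit override is
available). Two mutually exclusive genotype patterns are screened at every
biallelic site:

| scenario | proband | sire | dam |
|---|---|---|---|
| dominant de novo | 0/1 | 0/0 | 0/0 |
| recessive | 1/1 | 0/1 | 0/1 |

Sites with any missing genotype among the three fail the pattern — a
conservative choice: a site that cannot be verified cannot be a candidate.
Phase is ignored throughout (`|` read as `/`); the patterns are unordered
genotype classes.

The privacy filter then removes candidates observed in the unrelated
control panel. In the dominant-de-novo scenario any control carrying the
alternative allele (het or hom) disqualifies the site: a de novo event
cannot pre-exist in the population. In the recessive scenario heterozygous
carriers are tolerated, but only among controls of the proband's breed —
within-breed carrier frequency of a recessive allele can be appreciable
while the trait stays rare — whereas a hom-alt control or an out-of-breed
carrier disqualifies. Breed labels live in a sidecar sample-metadata TSV
(sample_id, breed, role) because VCF has no breed field.

The final stage keeps protein-changing variants, defined as
{stop_gain, stop_loss, start_loss, missense, frameshift, inframe_indel,
splice_site} — approximately the HIGH + MODERATE impact classes of
conventional annotators. Synonymous and non-coding changes are dropped. A
variant overlapping several transcripts is annotated against every one and
is protein-changing if any annotation is; the reported consequence is the
most severe.

## Consequence annotation

Coding effects are computed from first principles rather than taken from a
pre-existing annotation field. A transcript model is an ordered list of
non-overlapping CDS segments in genomic coordinates with a strand; the
summed CDS length must be divisible by 3 and at least 6 bp (models are
phase-0 consistent; the GFF3 phase column is ignored). Coordinate
projection walks the segments in coding order — reversed, with
complemented bases, on the minus strand — giving a bijection between CDS
genomic positions and c.1..L. For an SNV at c-position c:

- codon index k = floor((c-1)/3) + 1, offset ((c-1) mod 3) + 1;
- the reference codon is read from the genome along the coding strand, the
  alternative base (strand-corrected) substituted, both codons translated
  with the standard genetic code;
- classification: alt='\*' and ref≠'\*' → stop_gain; ref='\*' and alt≠'\*'
  → stop_loss; codon 1 losing Met → start_loss; equal amino acids →
  synonymous; else missense.

The REF allele is verified against the genome and a mismatch is a hard
error — a silent disagreement between VCF and FASTA would corrupt every
downstream codon.

Stop gains additionally report the ORF truncation fraction
(L − k + 1)/L, where L counts the ORF's codons **including the terminal
stop**. For the PKD1 example (k = 2399, L = 4311) this gives
1913/4311 = 44.4%. The alternative protein-length convention
(1912/4310) differs by < 0.01 percentage points at this scale; the
ORF-codon convention was chosen because the quantity describes the open
reading frame, not the mature peptide.

Intronic SNVs within 2 bp of an internal CDS junction are splice_site (the
canonical GT/AG dinucleotides); contig ends and UTR-side boundaries have no
intron and get no splice window. Indels are classified by length delta mod
3 only (frameshift vs inframe_indel), without 3'-normalisation — the
package's scope is SNV-centric and indel names are flagged best-effort in
the HGVS layer.

## HGVS naming

Candidates are named at three levels: genomic `contig:POSREF>ALT`, coding
`ACC:c.POSREF>ALT` with coding-strand alleles (reverse-complemented from
the genomic record on minus-strand transcripts), and protein
`ACC:p.(Xaa###Yaa)` with three-letter amino-acid codes, `*` for a gained
stop and `p.(=)` for synonymous changes; predicted changes are
parenthesized. Machine output never contains thousands separators; a
display formatter adds them for human-readable reports. A regex parser for
the emitted grammar is provided and round-trips every generated name.

## Parentage verification

The Mendelian error rate is the fraction of complete-genotype trio sites
where the proband's genotype cannot be composed of one allele from each
recorded parent (exhaustive 2×2 allele rule). At least 100 informative
sites are required; the trio is called consistent below a 1% error rate
(default). On simulated data the only non-Mendelian sites in a true trio
are the planted de novo variant and the two planted decoys (which must
show the de-novo pattern to exercise the cascade), so the expected rate is
3/n_sites ≈ 0.15% at default scale; substituting an unrelated sample for a
parent raises the rate two orders of magnitude.

## Co-segregation tabulation

At a candidate site, individuals are categorized as proband, parents,
affected offspring, unaffected/affected other relatives (offspring,
littermates, sires), unknown-phenotype, plus caller-supplied unrelated
cohort groups. Genotype classes per category are counted and
co-segregation is perfect iff every phenotyped affected individual carries
the alt allele and every phenotyped unaffected individual is hom-ref;
discordant ids are listed. No LOD score or exact test is computed: for a
fully penetrant dominant variant in a family of this size the count table
and verdict are the decision-relevant summary, and a formal linkage
statistic would suggest precision the design does not have. Reports render
genotype classes as allele letters (GG/GT/TT).

The bundled example family (`trioseg.examples`) encodes the published
canine ADPKD association table: 22 genotyped family members (index female,
2 parents, 3 sires, 12 genotyped offspring of which 6 affected, 4
littermates) and 103 + 26 + 931 unrelated clear dogs.

## Synthetic-data generator

The generator builds the statistical structure the filters assume, at desk
scale:

- **Genome**: uniform-random A/C/G/T contigs (default 2 × 60 kb).
- **Transcripts** (default 20): 1–4 CDS segments, random strand, 30–120
  codons, introns 10–50 bp; each CDS is rewritten as ATG + sense codons +
  stop, so every ORF translates Met…stop with no internal stop.
- **Background polymorphisms** (default 2000): per-site fixed alternative
  allele frequency 0.2 with Hardy–Weinberg genotype sampling in founders
  (parents, sires, controls) and Mendelian transmission to the index
  female and her offspring. A single per-variant frequency is the simplest
  model that produces realistic shared/private partitioning; 0.2 makes a
  typical site polymorphic in a 50-dog panel without saturating it.
- **Breed-private variants** (default 40): carried only by same-breed
  controls — the structure that motivates the recessive breed-carrier
  allowance.
- **Planted truth**: one interior sense codon convertible to TAA/TAG/TGA by
  one substitution, heterozygous in the index female, absent from parents,
  sires and all controls; each of the 13 offspring inherits it with
  probability 1/2. Affection status equals carrier status with probability
  `penetrance` (default 1.0, i.e. perfect co-segregation; non-carriers are
  never affected — no phenocopies).
- **Decoys**: a protein-changing het shared with exactly one control and a
  private synonymous het in the index, so the privacy and
  protein-changing stages each demonstrably reject something.
- **Exclusivity**: background sites that happen to reproduce the joint
  de-novo-private-protein-changing pattern are re-drawn (bounded retries,
  then a control carrier is forced), so the planted variant is the unique
  cascade solution by construction.

All randomness flows from one `numpy` generator seeded by `SimConfig.seed`;
a fixed seed reproduces every bundle file byte-for-byte.

Default sizes (50 controls with 5 same-breed, 20 genes, 2000 background
variants, 13 offspring from 3 sires) are a deliberate desk-scale
miniature of a realistic design — hundreds of control genomes, dozens of
same-breed dogs, millions of genome-wide variants. What passing tests show
is therefore structural correctness of the filters and annotations, not
genome-scale performance: the generator has no linkage disequilibrium, no
sequencing error or missingness, no recombination, uniform base
composition, and variant density far above real genomes relative to its
genome length. Conclusions about real-data variant counts (the
millions-to-a-handful collapse) do not follow from these tests, only the
shape of the collapse does.

## Numerical and interface choices

- Coordinates are 1-based inclusive at every public surface (VCF/GFF3
  convention); any half-open arithmetic is internal.
- Multi-allelic VCF sites are decomposed to biallelic records; in each
  decomposed record reference alleles stay 0, the matching alternative
  becomes 1, any other alternative becomes missing. The decomposition
  conserves each sample's non-reference allele count across records.
- Genotypes are canonicalized unordered pairs over {0, 1, missing};
  round-tripping a VCF preserves CHROM/POS/REF/ALT/GT exactly, up to
  allele order.
- Cascade stage counts are validated non-increasing at construction.
- QUAL/FILTER/INFO and depth are not consulted; an optional
  `min_called_controls` fraction can drop poorly called sites.
- Test problem sizes: exhaustive per-position oracle checks run on 6–8-gene
  bundles (several thousand annotations); penetrance recovery uses 200
  replicates of a 3-gene, 25-variant configuration (~1500 carriers), which
  bounds the binomial standard error of the discordance estimate near 0.012.

## Known limitations

- No X-linked or compound-heterozygous scenarios; no mosaicism modelling.
- Indel consequence classification is length-based only; no HGVS 3'-rule
  shifting or indel normalisation.
- No NMD or expression prediction for premature stops — whether a mutant
  transcript is expressed is outside the scope of consequence arithmetic.
- The candidate-gene flag relies on a user-supplied gene list.
- `verify_parentage` checks the trio only; it is not a general kinship
  estimator.
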