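# virecruit

Competitive fragment recruitment of viral metagenome reads onto phage
genomes — with ORF-consensus genome annotation, a rho-independent
terminator screen, a translated homology-search engine, and normalized
cross-metagenome abundance statistics. A ground-truth synthetic-community
simulator makes every stage verifiable at desk scale, without downloading
environmental sequencing runs.

The package is aimed at phage ecologists asking the question behind any
fragment-recruitment plot: *how prevalent are sequences similar to my
phage in environmental viromes, and how does it compare to other phages?*

## The method

**Annotation.** ORFs are every maximal start-to-stop reading frame on both
strands with span > 100 nt (bacterial genetic code; starts ATG/GTG/TTG;
circular genomes are unwrapped across the origin). Call sets from two gene
finders are merged by the consensus rule: calls sharing a stop codon and
strand are the same locus, and *the longer of the two is kept*.
Rho-independent terminators are stem-loops scored by an explicit pair-energy
sum (G:C −3.0, A:T −2.0, G:U −1.0 kcal/mol, loop penalty 4.0 + 0.3·(ℓ−3))
accepted at energy ≤ −16 kcal/mol when followed by a poly-T tract.

**Recruitment.** Reads are translated in six frames and searched against
protein databases by affine-gap Smith–Waterman (BLOSUM62, gap open 11 /
extend 1) with Karlin–Altschul statistics

&nbsp;&nbsp;&nbsp;&nbsp;E = K·m·n·e^(−λS),&nbsp;&nbsp;λ = 0.267, K = 0.041.

Stage 1 *screens* reads against the focal phage's proteome at E ≤ 10⁻⁵.
Stage 2 *competitively assigns* each candidate against a composite database
of the focal proteome plus thousands of decoy phage proteomes: the read is
recruited only if its best hit — under the deterministic order bitscore
desc, E asc, subject id asc — is a focal protein. Recruited reads are
mapped through the matching ORF onto genome nucleotide coordinates.

**Abundance.** Recruited counts are normalized per predicted ORF (default)
or per kilobase of genome, and per gigabase of metagenome:
N = hits / (ORFs × Gb). Coverage summaries count, per ORF, the metagenomes
of each habitat class (freshwater/marine) with at least one overlapping
recruited read.

## Worked example

```python
from virecruit.simdata import make_standard_community, recovery_harness

community = make_standard_community(seed=5, n_phages=3, genome_len=20_000,
                                    n_decoys=2)
rho, table = recovery_harness(community, n_reads=3_000, seed=5)
print(table); print(rho)
```

prints

```
phage_id true_weight  n_hits  n_orfs normalized
  phage1       0.571     835      93    19952.2
  phage2       0.286     417      87    10651.3
  phage3       0.143     217      87     5542.8

Spearman rho between true weights and normalized abundance: 1.00
```

Three related phages (85% proteome identity to a common ancestor) were
present at weights 4:2:1 among 3,000 error-bearing reads, half of them
random background. Competitive recruitment against a composite database
that also held 60%-identity decoys assigned 835/417/217 reads to the three
phages; per-ORF-per-gigabase normalization recovers the true abundance
ranking exactly (Spearman ρ = 1). The scripts in `examples/` walk through
annotation, recruitment, and abundance recovery one capability at a time;
the `virecruit` CLI (`virecruit run-all --config run.yaml`) chains the
stages and writes a JSON run manifest.

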