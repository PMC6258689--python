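# prdlike

Analysis toolkit for **PRD-LIKE homeobox genes** — the rapidly evolving
LEUTX/ARGFX/CPHX/DPRX/TPRX family of transcription factors expressed around
embryonic genome activation. The package is for researchers in molecular
evolution and developmental genomics who need to (re)build gene models for
these unusual loci, quantify homeodomain conservation and DNA-binding
specificity determinants, scan for functional motifs, measure population-level
constraint from cohort variant data, and analyze dual-luciferase
transactivation assays.

## What it computes

**Gene models.** PRD-LIKE genes share a canonical three-exon architecture: a
short first exon with a phase-1 GT donor; a second exon starting 14 nt
upstream of the homeobox carrying homeodomain codons 1–46; a phase-0 intron
between homeodomain codons 46 and 47; a third exon with the rest. `genemodel`
finds homeodomains by six-frame profile scanning (position-specific BLOSUM62
sums, no gaps in the 60-column window), rebuilds the exon structure around the
anchor, and classifies loci: intronless → retro-pseudogene; ≥ 2 stop/frameshift
lesions → disrupted pseudogene; single lesions tolerated.

**Homeodomain analytics.** `hdanalysis` maps between full-length-protein and
homeodomain numbering (residue 1 of the human LEUTX homeodomain is protein
residue 8), types domains by the specificity-determining residue 50 (K50
factors target TAATCC), renders Gonnet PAM 250 conservation symbols
(`*`/`:`/`.`) and MView-style 90% consensus lines, computes percent-identity
matrices with explicit gap handling, screens residue combinations at
specificity positions 47/54, and enumerates single-base codon paths between
amino acids split into transitions (A↔G, C↔T) and transversions.

**Motif scans.** `domainscan` scores PEST degradation signals with the
epestfind formula

```
score = 0.55 · DEPST_mass%(corrected) − 0.5 · hydrophobicity_index
```

(candidates between R/K/H flanks, ≥ 10 residues, valid iff they contain P,
D/E and S/T), matches 9aaTAD transactivation motifs against shipped
residue-class patterns, and scans DNA for the PRD-LIKE binding motif TAATCC on
both strands.

**Constraint.** `popconstraint` annotates coding variants codon-by-codon
(synonymous/missense/nonsense/stop-loss, indels, splice context), counts
per-individual #N/#S burdens (any-zygosity or homozygous-only), regresses
average burden on CDS width through the origin (negative residual =
constrained gene), and triages variants into candidate function-impairing
alleles using phylogenetic acceptance, specificity positions and 9aaTAD
overlap, with a 1% max-allele-frequency "common" threshold.

**Reporter assays.** `reporterstats` recomputes Renilla-normalized
luminescence (RNL = firefly/renilla), forms per-batch fold changes (with/
without TF, or with/without promoter insert) and tests significance with a
Welch t-test.

**Synthetic data.** `simgen` generates all of the above inputs with known
ground truth — canonical loci with optional planted corruptions, diploid
cohorts with controlled synonymous:nonsynonymous mixes, star-tree protein
families with planted conserved columns, and reporter tables with known fold
changes and log-normal batch noise — so every stage is testable offline.

## Worked example

```python
from prdlike import simgen, genemodel, hdanalysis, domainscan

# a synthetic canonical locus, then recover its structure blind
res = simgen.simulate_locus(simgen.LocusSpec(seed=1))
anchor = genemodel.scan_homeodomain(res.contig)[0]
model = genemodel.reconstruct_gene(res.contig, anchor)
protein, lesions = genemodel.splice_and_translate(res.contig, model)
print(model.exons, genemodel.classify_locus(model, lesions))

# homeodomain coordinate mapping and typing
ann = hdanalysis.HomeodomainAnnotation("human_LEUTX", 8, simgen.DEFAULT_HOMEODOMAIN)
print(hdanalysis.map_coordinates(ann, 61, "protein_to_hd"))
print(hdanalysis.classify_hd_type(ann))

# codon reachability and binding-motif scan
paths, summary = hdanalysis.codon_paths("A", "V")
print(len(paths), summary["reachable_by_transition_only"])
print(domainscan.scan_binding_motif("CAGCCTCCCAAAGTGCTGGGATTACAGGCATGAGCC"))
```

prints

```
[(200, 207), (1707, 1859), (2759, 3134)] intact
54
K50
4 True
[MotifHit(position=18, strand='-', motif='TAATCC')]
```

The reconstructed exons equal the generator's truth exactly; protein position
61 lies at homeodomain position 54 (the recognition helix); the domain is
K50-type, so it targets TAATCC; alanine→valine is reachable by four
single-base codon changes, all transitions; and the 36-bp EEA promoter motif
contains exactly one TAATCC site, on the minus strand at offset 18.

A command-line layer mirrors the library:

```sh
prdlike simgen locus --seed 1 --out locus/
prdlike genemodel run --contigs locus/contig.fa --out models/
prdlike domainscan pest --in protein.fa --window 10 --threshold 5.0 --out pest.tsv
prdlike hdanalysis codonpaths A V
```

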