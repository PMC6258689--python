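# Methods

`prdlike` packages the computational methods used to characterize rapidly
evolving PRD-LIKE homeobox transcription factors of the LEUTX/ARGFX/DPRX/TPRX
group: reconstruction of their canonical gene structure from genomic sequence,
homeodomain-centric alignment analytics, scans for degradation (PEST) and
transactivation (9aaTAD) signals, population-level constraint analysis of
coding variation, and statistics for dual-luciferase transactivation assays.
This note records the models, the parameters that matter, and the design
decisions taken where the methods literature leaves room.

## Canonical gene architecture and reconstruction

PRD-LIKE genes of this family share a three-exon architecture:

* exon 1 — short, often just the start codon plus one more residue, ending in
  a GT splice donor in **phase 1** (one base past a codon boundary);
* exon 2 — begins **14 nt upstream of the homeobox** and carries homeodomain
  codons 1–46;
* intron 2 — sits between homeodomain **codons 46 and 47 in phase 0**, a
  typical PRD-LIKE splice position, usually around 1 kb;
* exon 3 — homeodomain codons 47–60 plus the C-terminal domain up to the stop.

`genemodel.scan_homeodomain` translates all six reading frames and slides a
60-column homeodomain profile along each translation, scoring with a
position-specific substitution-matrix sum (BLOSUM62 by default; no gaps inside
the window, since homeodomains are fixed-length). Partial hits down to
`min_span` columns (default 15) are reported, so a homeodomain split by the
canonical intron still yields its codon 1–46 portion as an anchor. The default
reporting threshold (score ≥ 100) sits far above the extreme-value noise of
random sequence (empirically ≤ ~40 on multi-kb random contigs) while a true
46-codon partial hit scores in the hundreds. Equal scores tie-break to the
plus strand, then leftmost — determinism over biological preference.

`reconstruct_gene` then tests two hypotheses at the codon-46/47 boundary by
scoring homeodomain codons 47–60 (a) read contiguously, and (b) read after
each candidate GT..AG intron within `max_intron2` (default 5 kb), accepting
whichever acceptor scores best (ties to the shortest intron) provided it
reaches half of the profile's self-score. Exon 1 is found by scanning upstream
of the exon-2 acceptor, nearest donor first, for a GT preceded by an in-frame
ATG-initiated stretch with no intervening stop codon; the search window is
20 kb (introns of several kb occur) and exon 1 may hold up to 50 codons.
Unresolvable parts — including any N run in the search region — leave
`status='fragment'` rather than a guess, since N-terminal exon prediction is
the least certain part of this architecture.

`splice_and_translate` reports lesions: internal stop codons (translation
continues through them so they can be counted), and a spliced length that is
not a multiple of 3 as a single `frameshift`. When the frame is shifted,
downstream internal stops are symptoms of the shift, not independent lesions,
and are suppressed. Consequently two compensating frameshifts (net 0 mod 3),
or a stop plus a frameshift, cannot be distinguished from a single lesion
without an orthologous alignment — the same reason manual curation against
orthologs was historically needed. This is a known limitation, not a bug.

`classify_locus`: a locus whose canonical homeobox intron is absent is a
retrotransposed pseudogene; two or more stop/frameshift lesions make a
disrupted pseudogene; a **single** lesion is tolerated (it may be a sequencing
or assembly error), so pseudogene calls require multiple errors. The tolerance
threshold is configurable (`max_tolerated`, default 1).

## Synthetic loci and identifiability

`simgen.simulate_locus` builds loci from a planted protein (random residues
around a 60-residue K50-type homeodomain) by reverse translation with uniform
codon choice, then splits the CDS at the canonical boundaries and inserts
GT..AG introns with random interiors. Defaults: 2 exon-1 codons, introns of
1500/900 bp, a 110-residue C-terminal domain, 200/100 bp flanks.

The generator guarantees that reconstruction is *well-posed*: the region
upstream of exon 2 contains exactly one ATG (the true start; pre-homeodomain
residues avoid Met and NGT codons so no decoy start or phase-1 donor hides in
exon 1), and intron 1 opens GT-TAA so that read-through from the true start
hits an in-frame stop immediately. Generation retries deterministically until
these properties hold. Real genomic sequence offers no such guarantee — decoy
ATG/GT signals are common, which is precisely why N-terminal exons of real
loci are uncertain. Passing the 100%-exact-recovery suite therefore shows the
reconstruction logic is correct under the canonical architecture, not that
real-genome exon-1 calls are always unambiguous.

What the synthetic data deliberately omits: mutation along a phylogeny (family
alignments use star-tree independent substitution), recombination, sequencing
error, non-canonical splice sites, and linkage between variants.

## Cohorts and constraint

`simulate_cohort` plants biallelic coding SNVs: each CDS base becomes a
segregating site with probability `site_density` (default `min(0.5, 20 ×
per_base_variant_rate)`), and each individual carries a planted site with
probability `rate / site_density`, split het:hom 2:1 by default. The expected
number of sites carried per individual is therefore exactly `cds_length ×
rate`, split into nonsynonymous and synonymous classes by `nonsyn_fraction`;
closed-form expectations are recorded as ground truth. Because sites are
shared across a cohort, the variance of a cohort-mean burden has a
between-site component — the calibration tests use the full variance, and the
regression power study uses `site_density = 0.5` with 300 individuals,
emulating the many-rare-variants regime of large human cohorts where
per-gene averages concentrate.

Consequence annotation translates the affected codon before and after the
change (synonymous / missense / nonsense / stop-loss; indels by length mod 3;
the first/last two intron bases are splice donor/acceptor context). Nonsense
counts as nonsynonymous in #N: it is a protein-changing substitution; class
distinctions matter only at triage. A carried site counts once per individual
regardless of zygosity (the hom-only view is a separate switch, mirroring the
two zygosity panels of cohort burden plots); allele-dosage counting is not the
default. Burden regression is ordinary least squares **through the origin**
(expected substitution count is proportional to CDS width); an intercept mode
is provided because published burden-vs-width trend lines do not always state
their form. Negative residuals mark constraint.

Variant triage: nonsense, frameshift and splice-donor variants are always
candidate function-impairing alleles. A missense variant is a candidate only
if it triggers an enabled criterion — alternate residue unseen at the aligned
column in other species, position among the homeodomain specificity residues
(2, 3, 5, 47, 50, 51, 54, 58), or position inside a 9aaTAD match — **and** is
not evolutionarily accepted (i.e. the alternate residue occurs in another
species at that column). "Common" means maximum allele frequency > 1% in any
cohort, max-aggregated across cohorts. The shipped rule set approximates
published expert triage and every criterion is independently toggleable.

## Homeodomain analytics

Coordinate mapping is a fixed offset: homeodomain residue 1 of full-length
human LEUTX is protein residue 8 (anchored by the K57A ↔ K50A
correspondence), so e.g. protein position 61 is homeodomain position 54.
Residue 50 of the recognition helix types the domain (K50 factors such as
LEUTX and OTX2 prefer TAATCC; Q50, R50 and N50 differ).

Conservation symbols use the Gonnet PAM 250 matrix with Clustal-style
thresholds: `*` for a normalized column score of 1, `:` above 0.5, `.` at or
below. The aggregation behind such symbols is rarely stated; this package uses
the **minimum pairwise** normalized score `s(a,b)/max(s(a,a), s(b,b))`,
clamped to [0,1], so a single divergent taxon downgrades a column —
deterministic and conservative. Columns containing a gap print a blank and are
excluded from identity denominators.

Percent identity divides identical pairs by comparable columns; gap handling
is explicit because published integer identities depend on it: the default
excludes columns gapped in either row, and a `mismatch` mode counts
gap-vs-residue columns in the denominator. Values round half-up when integer
output is requested. Consensus lines are MView-style: a residue that reaches
the level (default 90%) prints itself, else the first physicochemical class
(shipped table, most specific first) reaching the level prints its symbol,
else `.`.

Codon reachability enumerates all ordered sense-codon pairs differing at one
base and classifies each change as a transition (A↔G, C↔T) or transversion;
transitions being mutationally more frequent, `reachable_by_transition_only`
flags substitutions like Ala→Val (four paths, all second-position C→T). The
brute-force enumeration over 61 × 9 single-base mutations is the test oracle.
The combination screen tabulates residue pairs at two homeodomain positions
(default 47/54) across taxa and lists combinations of observed marginal
residues never seen jointly — the screen that exposes the missing I47-V54
pairing.

## PEST and 9aaTAD

PEST candidates are maximal stretches between positively charged residues
(R/K/H) or sequence termini, of at least `window` residues (default 10);
validity requires ≥1 P, ≥1 D/E and ≥1 S/T. The score is
`0.55 × DEPST_mass% − 0.5 × hydrophobicity`, where the DEPST mass is corrected
by one equivalent each of P, D/E and S/T before taking the mass percent, and
hydrophobicity is the mole-fraction mean of Kyte–Doolittle values rescaled to
[0, 90] (`10·kd + 45`). Valid regions at or above the threshold (default 5.0)
are "potential", below it "poor" — low-scoring but valid regions are still
biologically reportable. Two ambiguities in the published description are
resolved as follows and shipped as data: masses are average residue masses
(water excluded), and when both members of a correction pair are present the
lighter residue (D over E, S over T) is subtracted. The window-10/threshold-5
defaults are the common tool defaults, assumed rather than asserted to be any
particular study's setting.

9aaTAD matching is pure pattern application: every 9-residue window is tested
against per-position allowed-residue sets. Two tables ship ("less" and "more"
stringent), written from the commonly cited 9aaTAD consensus — polar/acidic
opener, hydrophobic core, no proline or positive charge in core positions —
and are editable without touching the engine. Binding-motif scanning is exact
string matching of the motif (default TAATCC) and its reverse complement on
the plus strand; `N` never matches; coordinates are plus-strand half-open.

## Reporter statistics

RNL (Renilla-normalized luminescence) is firefly counts divided by Renilla
counts, always recomputed from the raw channels. Fold changes are formed per
batch — with-TF over without-TF on the same promoter, or insert-bearing over
empty promoter under the same TF — and summarized by the arithmetic mean of
per-batch ratios (geometric mean by flag); published per-batch displays do not
state a pooling rule. Significance uses a two-sided Welch t-test by default
("t-test" alone does not specify the pooled form; Student's and batch-paired
variants are flags). The synthetic generator plants multiplicative log-normal
noise per well, so the with/without ratio is unbiased up to the
`exp(sd²)`-order log-normal term, which the calibration tests account for;
type-I error of the default test at the simulated null is within Monte-Carlo
error of the nominal 5% at 1000 replicates.

## Numerical conventions

Coordinates are 0-based half-open everywhere inside the package; 1-based
conventions appear only at the GFF3/VCF boundary and in protein/homeodomain
numbering (1-based by field convention). All randomness flows through named
`numpy` Generator streams derived from the user seed, so sub-generators are
reproducible in isolation and identical seeds give byte-identical outputs.
Problem sizes used by the test suite — 100 reconstruction loci, 10,000
annotation SNVs, 100 regression replicates of 50 genes × 300 individuals,
1000 reporter null replicates — were chosen so the full enumeration- and
simulation-based checks complete in well under a minute on one CPU.

## Known limitations

* Exon-1 recovery relies on canonical signals only; real loci with decoy
  upstream ATG/GT signals may yield a plausible but wrong short exon 1, as
  flagged above.
* Compensating or stop-adjacent frameshifts are undercounted without
  orthologous alignment; classification is conservative (toward "intact").
* Synteny, used by curators to disambiguate paralogs, is not modeled.
* The 9aaTAD tables are a consensus adaptation, not a reproduction of any
  specific server's internal patterns.
* No dN/dS or phylogenetic rate modeling: burden constraint is within-species
  and regression-based only.
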