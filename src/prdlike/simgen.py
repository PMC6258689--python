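"""Synthetic inputs with known ground truth for every downstream stage.

Four generators are provided: canonical three-exon PRD-LIKE loci (with optional
planted corruptions), diploid cohorts with a controlled synonymous to
nonsynonymous variant mix, protein family alignments with planted conserved
columns, and dual-luciferase reporter tables with known activation effects and
multiplicative batch noise.

Loci follow the canonical Leutx-style architecture: a short first exon (two
codons by default) with a phase-1 GT donor, a second exon starting 14 nt
upstream of the homeobox, a phase-0 intron between homeodomain codons 46 and
47, and a third exon carrying the rest of the homeodomain plus a C-terminal
domain up to the stop codon.  Generated loci are identifiable by construction:
the upstream region contains exactly one ATG (the true start codon), intron 1
opens with GT followed immediately by an in-frame TAA so that read-through is
blocked, and intron interiors carry no decoy start codons.  This makes exact
exon recovery a well-posed criterion for the reconstruction code.

All randomness flows through named streams derived from the user seed, so each
generator is reproducible in isolation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .genemodel import Disruption, GeneModel, reverse_complement

STOP_CODONS = ("TAA", "TAG", "TGA")
AA20 = "ACDEFGHIKLMNPQRSTVWY"
DEFAULT_HOMEODOMAIN = "EKRPRTAFSSEQLARLKREFNENRYLTERRRQQLSSELGLNEAQIKIWFKNKRAKIKKST"

_CODONS_FOR = {}
for codon, aa in standard_dna_table.forward_table.items():
    _CODONS_FOR.setdefault(aa, []).append(codon)
for aa in _CODONS_FOR:
    _CODONS_FOR[aa].sort()
SENSE_CODONS = sorted(standard_dna_table.forward_table)


def stream(seed: int, name: str) -> np.random.Generator:
    """Named pseudo-random stream derived from the user seed."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


def _random_dna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _scrub_atg(rng, s: str) -> str:
    """Replace every ATG occurrence until none remain (decoy-free introns)."""
    s = list(s)
    while True:
        text = "".join(s)
        i = text.find("ATG")
        if i < 0:
            return text
        s[i + 1] = rng.choice(["A", "C", "G"])


def translate(dna: str) -> str:
    dna = dna[: len(dna) - len(dna) % 3]
    return str(Seq(dna).translate())


# ---------------------------------------------------------------------------
# locus


@dataclass
class LocusSpec:
    """Parameters of one canonical three-exon locus.

    exon2 length is fixed by the architecture (homeobox offset + 46 codons);
    pass ``exon2_len`` only to assert it.  ``exon3_len`` must keep the coding
    sequence in frame and hold homeodomain codons 47-60 plus a stop.
    """

    exon1_codons: int = 2
    intron1_len: int = 1500
    exon2_len: int | None = None
    intron2_len: int = 900
    exon3_len: int = 375
    hd_offset_in_exon2: int = 14
    flank5: int = 200
    flank3: int = 100
    homeodomain: str = DEFAULT_HOMEODOMAIN
    seed: int = 0

    def __post_init__(self):
        if self.exon1_codons < 1:
            raise ValueError("exon1 must encode at least one codon (ATG)")
        if self.intron1_len < 60 or self.intron2_len < 60:
            raise ValueError("introns must be at least 60 bp")
        if self.hd_offset_in_exon2 < 2 or (self.hd_offset_in_exon2 - 2) % 3:
            raise ValueError("hd offset must place the homeobox in frame (phase-1 donor)")
        expected_e2 = self.hd_offset_in_exon2 + 3 * 46
        if self.exon2_len is None:
            self.exon2_len = expected_e2
        elif self.exon2_len != expected_e2:
            raise ValueError(
                f"exon2_len must equal hd_offset + 138 = {expected_e2} "
                "(intron 2 between homeodomain codons 46 and 47, phase 0)"
            )
        if self.exon3_len < 3 * 14 + 3 or self.exon3_len % 3:
            raise ValueError("exon3_len must be a positive multiple of 3 holding HD codons 47-60 and a stop")
        if len(self.homeodomain) != 60:
            raise ValueError("homeodomain must be 60 residues")
        if self.flank5 < 10 or self.flank3 < 0:
            raise ValueError("flank lengths invalid")


@dataclass
class LocusResult:
    contig: str
    model: GeneModel
    protein: str
    spec: LocusSpec


def _reverse_translate(rng, protein: str, forbid_gt_offset1: bool = False) -> str:
    out = []
    for aa in protein:
        options = _CODONS_FOR[aa]
        if forbid_gt_offset1:
            safe = [c for c in options if c[1:3] != "GT"]
            options = safe or options
        out.append(options[rng.integers(len(options))])
    return "".join(out)


def simulate_locus(spec: LocusSpec) -> LocusResult:
    """Generate a contig holding one intact canonical locus plus ground truth.

    Retries generation (deterministically, from derived streams) until the
    region upstream of exon 2 contains the start codon as its only ATG, which
    together with the decoy-free introns makes reconstruction unambiguous.
    """
    for attempt in range(200):
        result = _build_locus(spec, stream(spec.seed, f"locus.{attempt}"))
        e2s = result.model.exons[1][0]
        upstream = result.contig[:e2s]
        if upstream.count("ATG") == 1 and upstream.find("ATG") == result.model.exons[0][0]:
            return result
    raise RuntimeError("could not generate an identifiable locus")


def _build_locus(spec: LocusSpec, rng) -> LocusResult:
    c1 = spec.exon1_codons
    n_pre = c1 + 1 + (spec.hd_offset_in_exon2 - 2) // 3  # residues before the homeodomain
    n_cterm = (spec.exon3_len - 3 * 14 - 3) // 3

    aa_no_m = AA20.replace("M", "")
    protein = (
        "M"
        + "".join(rng.choice(list(aa_no_m), size=n_pre - 1))
        + spec.homeodomain
        + "".join(rng.choice(list(AA20), size=n_cterm))
    )
    # pre-homeodomain codons avoid NGT codons so no decoy phase-1 donor sits
    # inside exon 1, and avoid M so the start codon is the unique upstream ATG
    cds = (
        _reverse_translate(rng, protein[: n_pre], forbid_gt_offset1=True)
        + _reverse_translate(rng, protein[n_pre:])
        + STOP_CODONS[rng.integers(3)]
    )

    e1_len = 3 * c1 + 1
    exon1 = cds[:e1_len]
    exon2 = cds[e1_len : e1_len + spec.exon2_len]
    exon3 = cds[e1_len + spec.exon2_len :]
    assert len(exon3) == spec.exon3_len

    # intron 1 opens GT + in-frame TAA (blocks read-through); interiors ATG-free
    intron1 = "GT" + "TAA" + _scrub_atg(rng, _random_dna(rng, spec.intron1_len - 7)) + "AG"
    intron2 = "GT" + _scrub_atg(rng, _random_dna(rng, spec.intron2_len - 4)) + "AG"
    flank5 = _scrub_atg(rng, _random_dna(rng, spec.flank5))
    flank3 = _random_dna(rng, spec.flank3)

    s1 = len(flank5)
    e1 = (s1, s1 + e1_len)
    s2 = e1[1] + spec.intron1_len
    e2 = (s2, s2 + spec.exon2_len)
    s3 = e2[1] + spec.intron2_len
    e3 = (s3, s3 + spec.exon3_len)
    contig = flank5 + exon1 + intron1 + exon2 + intron2 + exon3 + flank3
    hd_start = s2 + spec.hd_offset_in_exon2
    model = GeneModel(
        contig_id=f"synthetic_locus_{spec.seed}",
        strand="+",
        exons=[e1, e2, e3],
        intron_phases=[1, 0],
        homeobox_interval=(hd_start, s3 + 3 * 14),
        status="intact",
    )
    assert translate(model.spliced(contig))[:-1] == protein
    return LocusResult(contig, model, protein, spec)


# ---------------------------------------------------------------------------
# corruption


@dataclass
class CorruptionSpec:
    """One planted disruption.

    ``op``: frameshift_insert | frameshift_delete | premature_stop |
    intron_loss | none.  ``position`` is a contig coordinate for indels/stops;
    for intron_loss it is the intron index (0 or 1) or -1 for all introns.
    ``count`` is the number of bases inserted/deleted (frameshifts).
    """

    op: str = "none"
    position: int = 0
    count: int = 1

    def __post_init__(self):
        ops = {"frameshift_insert", "frameshift_delete", "premature_stop", "intron_loss", "none"}
        if self.op not in ops:
            raise ValueError(f"unknown corruption op {self.op!r}")


@dataclass
class CorruptedLocus:
    contig: str
    model: GeneModel  # truth model with coordinates adjusted for the corruption
    labels: list[Disruption]


def hd_codon_coordinate(model: GeneModel, codon: int) -> int:
    """Genomic start of homeodomain codon ``codon`` (1-based, 1..60)."""
    if not 1 <= codon <= 60:
        raise ValueError("homeodomain codon must be in 1..60")
    hd_start = model.homeobox_interval[0]
    if codon <= 46 or len(model.exons) < 3:
        return hd_start + 3 * (codon - 1)
    return model.exons[-1][0] + 3 * (codon - 47)


def _shift_model(model: GeneModel, at: int, delta: int) -> GeneModel:
    def mv(x):
        return x + delta if x >= at else x

    return GeneModel(
        model.contig_id, model.strand,
        [(mv(a), mv(b)) for a, b in model.exons],
        list(model.intron_phases),
        tuple(mv(x) for x in model.homeobox_interval) if model.homeobox_interval else None,
        model.status, model.has_intron1, model.has_intron2,
    )


def corrupt_locus(contig: str, truth: GeneModel, spec: CorruptionSpec,
                  seed: int = 0) -> CorruptedLocus:
    """Apply one planted disruption, returning the new contig, the truth model
    with adjusted coordinates, and labels recording what was planted."""
    rng = stream(seed, "corrupt")
    if spec.op == "none":
        return CorruptedLocus(contig, truth, [])

    if spec.op == "intron_loss":
        n_introns = len(truth.introns)
        if spec.position != -1 and not 0 <= spec.position < n_introns:
            raise ValueError("intron index outside locus")
        drop_idx = list(range(n_introns)) if spec.position == -1 else [spec.position]
        model, out = truth, contig
        labels = []
        for idx in sorted(drop_idx, reverse=True):
            a, b = model.introns[idx]
            out = out[:a] + out[b:]
            exons = model.exons
            merged = exons[:idx] + [(exons[idx][0], exons[idx + 1][1])] + exons[idx + 2:]
            phases = [p for j, p in enumerate(model.intron_phases) if j != idx]
            model = _shift_model(
                GeneModel(model.contig_id, model.strand, merged, phases,
                          model.homeobox_interval, model.status,
                          model.has_intron1, model.has_intron2),
                b, -(b - a),
            )
            labels.append(Disruption("intronless", a))
        dropped = set(drop_idx)
        model = GeneModel(model.contig_id, model.strand, model.exons,
                          model.intron_phases, model.homeobox_interval, model.status,
                          has_intron1=truth.has_intron1 and 0 not in dropped,
                          has_intron2=truth.has_intron2 and (n_introns - 1) not in dropped)
        return CorruptedLocus(out, model, labels)

    pos, n = spec.position, spec.count
    if not 0 <= pos < len(contig):
        raise ValueError("position outside locus")

    if spec.op == "frameshift_insert":
        ins = _random_dna(rng, n)
        out = contig[:pos] + ins + contig[pos:]
        model = _shift_model(truth, pos, n)
        return CorruptedLocus(out, model, [Disruption("frameshift", pos)])

    if spec.op == "frameshift_delete":
        out = contig[:pos] + contig[pos + n :]
        model = _shift_model(truth, pos + n, -n)
        return CorruptedLocus(out, model, [Disruption("frameshift", pos)])

    # premature_stop: overwrite the codon starting at `pos` with a stop codon
    if pos + 3 > len(contig):
        raise ValueError("position outside locus")
    stop = STOP_CODONS[rng.integers(3)]
    out = contig[:pos] + stop + contig[pos + 3 :]
    return CorruptedLocus(out, truth, [Disruption("internal_stop", pos)])


# ---------------------------------------------------------------------------
# cohort


@dataclass
class CohortSpec:
    """Diploid cohort with planted biallelic coding SNVs.

    Each CDS base becomes a segregating site with probability ``site_density``
    (default ``min(0.5, 20 x per_base_variant_rate)``); carriers are drawn per
    individual so that the expected number of variant sites carried per
    individual and gene is ``cds_length x per_base_variant_rate``, split into
    nonsynonymous and synonymous classes by ``nonsyn_fraction``.
    """

    n_individuals: int
    genes: list[tuple[str, int]]
    per_base_variant_rate: float
    nonsyn_fraction: float = 0.5
    het_hom_ratio: float = 2.0
    site_density: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals < 1 or not self.genes:
            raise ValueError("need at least one individual and one gene")
        for g, L in self.genes:
            if L <= 0 or L % 3:
                raise ValueError(f"cds_length of {g} must be a positive multiple of 3")
        if not 0 <= self.per_base_variant_rate <= 1:
            raise ValueError("per_base_variant_rate must be in [0,1]")
        if not 0 <= self.nonsyn_fraction <= 1:
            raise ValueError("nonsyn_fraction must be in [0,1]")
        if self.het_hom_ratio < 0:
            raise ValueError("het_hom_ratio must be >= 0")
        if self.site_density is None:
            self.site_density = min(0.5, max(20 * self.per_base_variant_rate, 1e-9))
        if not 0 < self.site_density <= 1 or self.site_density < self.per_base_variant_rate:
            raise ValueError("site_density must be in (0,1] and >= per_base_variant_rate")


@dataclass
class CohortResult:
    variants: pd.DataFrame  # gene_id, cds_pos (1-based), ref, alt, class_truth
    genotypes: np.ndarray  # individuals x variants; 0/1/2
    cds: dict[str, str]  # gene_id -> CDS sequence
    truth: pd.DataFrame  # per-gene expected per-individual #N and #S


def _random_cds(rng, length: int) -> str:
    codons = [SENSE_CODONS[i] for i in rng.integers(len(SENSE_CODONS), size=length // 3)]
    return "".join(codons)


def _snv_candidates(cds: str):
    """All single-base variants of a CDS, split by consequence class."""
    syn, nonsyn = [], []
    for i, ref in enumerate(cds):
        ci = i // 3
        codon = cds[3 * ci : 3 * ci + 3]
        off = i % 3
        aa = standard_dna_table.forward_table[codon]
        for alt in "ACGT":
            if alt == ref:
                continue
            mut = codon[:off] + alt + codon[off + 1 :]
            if mut in STOP_CODONS:
                nonsyn.append((i + 1, ref, alt))
            elif standard_dna_table.forward_table[mut] == aa:
                syn.append((i + 1, ref, alt))
            else:
                nonsyn.append((i + 1, ref, alt))
    return syn, nonsyn


def simulate_cohort(spec: CohortSpec) -> CohortResult:
    rng = stream(spec.seed, "cohort")
    rows = []
    cds_by_gene = {}
    truth_rows = []
    for gene_id, length in spec.genes:
        cds = _random_cds(stream(spec.seed, f"cohort.cds.{gene_id}"), length)
        cds_by_gene[gene_id] = cds
        syn_cand, nonsyn_cand = _snv_candidates(cds)
        n_nonsyn = rng.binomial(length, spec.site_density * spec.nonsyn_fraction)
        n_syn = rng.binomial(length, spec.site_density * (1 - spec.nonsyn_fraction))
        used = set()
        for n_sites, cand, label in (
            (n_nonsyn, nonsyn_cand, "nonsynonymous"),
            (n_syn, syn_cand, "synonymous"),
        ):
            pool = [c for c in cand if c[0] not in used]
            positions = {}
            for pos, ref, alt in pool:
                positions.setdefault(pos, []).append((pos, ref, alt))
            pos_list = sorted(positions)
            take = min(n_sites, len(pos_list))
            chosen = rng.choice(len(pos_list), size=take, replace=False)
            for k in chosen:
                opts = positions[pos_list[k]]
                pos, ref, alt = opts[rng.integers(len(opts))]
                used.add(pos)
                rows.append((gene_id, pos, ref, alt, label))
        truth_rows.append(
            (
                gene_id,
                length,
                length * spec.per_base_variant_rate * spec.nonsyn_fraction,
                length * spec.per_base_variant_rate * (1 - spec.nonsyn_fraction),
            )
        )
    variants = pd.DataFrame(rows, columns=["gene_id", "cds_pos", "ref", "alt", "class_truth"])
    variants = variants.sort_values(["gene_id", "cds_pos"], ignore_index=True)

    carrier_p = spec.per_base_variant_rate / spec.site_density
    p_hom = carrier_p / (1.0 + spec.het_hom_ratio)
    p_het = carrier_p - p_hom
    u = rng.random((spec.n_individuals, len(variants)))
    genotypes = np.zeros((spec.n_individuals, len(variants)), dtype=np.int8)
    genotypes[u < p_het + p_hom] = 1
    genotypes[u < p_hom] = 2
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "cds_width", "expected_N", "expected_S"])
    return CohortResult(variants, genotypes, cds_by_gene, truth)


# ---------------------------------------------------------------------------
# family alignment


def simulate_family_alignment(
    n_taxa: int,
    conserved_columns,
    substitution_rate: float,
    seed: int = 0,
    n_columns: int | None = None,
    base_row: str | None = None,
    residue_overrides: dict[int, dict[int, str]] | None = None,
):
    """Star-tree protein family: masked columns identical, others mutate
    independently per taxon at ``substitution_rate``.  ``residue_overrides``
    maps taxon index -> {0-based column -> residue} (e.g. to plant a residue at
    homeodomain position 50 per taxon)."""
    from .hdanalysis import Alignment

    mask = np.asarray(conserved_columns, dtype=bool)
    if mask.size == 0:
        raise ValueError("conserved-column mask must be non-empty")
    if n_taxa < 2:
        raise ValueError("need at least two taxa")
    n_columns = n_columns or mask.size
    if mask.size != n_columns:
        raise ValueError("mask length must equal column count")
    rng = stream(seed, "family")
    if base_row is None:
        base_row = "".join(rng.choice(list(AA20), size=n_columns))
    rows = []
    for t in range(n_taxa):
        seq = list(base_row)
        mutate = (~mask) & (rng.random(n_columns) < substitution_rate)
        for j in np.nonzero(mutate)[0]:
            choices = AA20.replace(base_row[j], "")
            seq[j] = choices[rng.integers(len(choices))]
        for j, aa in (residue_overrides or {}).get(t, {}).items():
            seq[j] = aa
        rows.append((f"taxon_{t:03d}", "".join(seq)))
    return Alignment(rows)


# ---------------------------------------------------------------------------
# reporter


@dataclass
class ReporterSpec:
    """Dual-luciferase layout: every (tf | no-tf, construct, batch) well gets
    firefly and renilla counts; log-scale batch noise is multiplicative."""

    constructs: list[str] = field(default_factory=lambda: ["plain", "4x11bp"])
    tfs: list[str] = field(default_factory=lambda: ["LEUTX"])
    true_fold_change: dict[tuple[str, str], float] = field(default_factory=dict)
    batch_sd: float = 0.1
    n_batches: int = 3
    baseline_rnl: float = 0.1
    renilla_base: float = 10000.0
    seed: int = 0

    def __post_init__(self):
        if self.n_batches < 2:
            raise ValueError("need at least two batches")
        if any(v <= 0 for v in self.true_fold_change.values()):
            raise ValueError("fold changes must be positive")
        if self.batch_sd < 0:
            raise ValueError("batch_sd must be >= 0")


def simulate_reporter(spec: ReporterSpec) -> pd.DataFrame:
    rng = stream(spec.seed, "reporter")
    rows = []
    for construct in spec.constructs:
        for tf in ["-"] + list(spec.tfs):
            fold = 1.0 if tf == "-" else spec.true_fold_change.get((tf, construct), 1.0)
            for batch in range(1, spec.n_batches + 1):
                ren = spec.renilla_base * np.exp(rng.normal(0, spec.batch_sd))
                rnl = spec.baseline_rnl * fold * np.exp(rng.normal(0, spec.batch_sd))
                rows.append((tf, construct, batch, ren * rnl, ren))
    return pd.DataFrame(rows, columns=["tf", "promoter", "batch", "firefly", "renilla"])
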