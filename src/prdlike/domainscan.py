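"""Sequence-feature scans: PEST regions, 9aaTAD motifs, DNA binding motifs.

PEST sequences (proline/glutamate/aspartate-serine/threonine-rich stretches
between positively charged flanks) mark proteins for rapid degradation; they
are scored here with the epestfind formula: candidate stretches of at least
``window`` residues between R/K/H flanks (or sequence termini) are valid when
they contain at least one P, one D or E and one S or T, and score

    score = 0.55 * DEPST_mass_percent_corrected - 0.5 * hydrophobicity_index

where the corrected DEPST mass subtracts one equivalent each of P, D/E and
S/T, and the hydrophobicity index is the mole-fraction-weighted mean of
Kyte-Doolittle hydropathy values linearly rescaled to [0, 90].

9aaTAD motifs (nine-residue transactivation modules of mixed acidic and
hydrophobic character) are matched against per-position residue-class
constraint tables shipped as data; the engine is pattern-agnostic.

DNA binding-motif scanning reports exact matches of a motif (default TAATCC,
the K50-type PRD-LIKE target) on both strands, with plus-strand half-open
coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

from .genemodel import reverse_complement

POSITIVE_FLANKS = set("RKH")
STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


def _load_pest_tables():
    raw = json.loads(resources.files("prdlike").joinpath("data","pest_tables.json").read_text())
    mass = raw["residue_mass"]
    hv = {aa: 10.0 * kd + 45.0 for aa, kd in raw["kyte_doolittle"].items()}
    return mass, hv


# ---------------------------------------------------------------------------
# PEST


@dataclass
class PestParams:
    window: int = 10
    threshold: float = 5.0
    depst_weight: float = 0.55
    hydro_weight: float = 0.5

    def __post_init__(self):
        if self.window < 2:
            raise ValueError("window must be >= 2")
        if self.depst_weight <= 0 or self.hydro_weight <= 0:
            raise ValueError("weights must be positive")


@dataclass
class PestRegion:
    start: int  # 0-based, half-open, candidate stretch between flanks
    end: int
    score: float
    valid: bool
    classification: str  # potential | poor | invalid


def pest_score(peptide: str, params: PestParams | None = None) -> float:
    """The epestfind-style score of one candidate stretch."""
    params = params or PestParams()
    mass, hv = _load_pest_tables()
    total = sum(mass[a] for a in peptide)
    depst = sum(mass[a] for a in peptide if a in "DEPST")
    # one equivalent each of P, D/E and S/T (the lighter residue of each pair
    # present is subtracted; see methods note)
    if "P" in peptide:
        depst -= mass["P"]
    if "D" in peptide or "E" in peptide:
        depst -= mass["D"] if "D" in peptide else mass["E"]
    if "S" in peptide or "T" in peptide:
        depst -= mass["S"] if "S" in peptide else mass["T"]
    depst_pct = 100.0 * depst / total
    hydro = sum(hv[a] for a in peptide) / len(peptide)
    return params.depst_weight * depst_pct - params.hydro_weight * hydro


def find_pest_regions(protein: str, params: PestParams | None = None) -> list[PestRegion]:
    """All candidate PEST stretches of a protein, scored and classified.

    Candidates are maximal runs between positively charged residues (R/K/H) or
    sequence termini, of length >= window.  Validity requires at least one P,
    one of D/E and one of S/T; valid regions scoring at or above the threshold
    are 'potential', below it 'poor'.
    """
    params = params or PestParams()
    for i, aa in enumerate(protein):
        if aa not in STANDARD_AA:
            raise ValueError(f"non-standard residue {aa!r} at position {i + 1}")
    regions: list[PestRegion] = []
    start = 0
    boundaries = [i for i, aa in enumerate(protein) if aa in POSITIVE_FLANKS]
    edges = [-1] + boundaries + [len(protein)]
    for a, b in zip(edges, edges[1:]):
        s, e = a + 1, b  # the stretch strictly between flanks
        if e - s < params.window:
            continue
        pep = protein[s:e]
        valid = ("P" in pep) and any(c in pep for c in "DE") and any(c in pep for c in "ST")
        score = pest_score(pep, params)
        if not valid:
            cls = "invalid"
        elif score >= params.threshold:
            cls = "potential"
        else:
            cls = "poor"
        regions.append(PestRegion(s, e, score, valid, cls))
    return regions


# ---------------------------------------------------------------------------
# 9aaTAD


@dataclass
class TadPattern:
    pattern_id: str
    stringency: str
    positions: list[str]  # 9 allowed-residue strings

    def __post_init__(self):
        if len(self.positions) != 9:
            raise ValueError("a 9aaTAD pattern spans exactly 9 positions")

    def matches(self, nine_mer: str) -> bool:
        return len(nine_mer) == 9 and all(
            aa in allowed for aa, allowed in zip(nine_mer, self.positions)
        )


@dataclass
class TadMatch:
    start: int  # 0-based protein coordinate
    nine_mer: str
    pattern_id: str


def default_tad_patterns() -> list[TadPattern]:
    raw = json.loads(resources.files("prdlike").joinpath("data","tad_patterns.json").read_text())
    return [TadPattern(p["id"], p["stringency"], p["positions"]) for p in raw["patterns"]]


def find_9aatad(protein: str, patterns: list[TadPattern] | None = None) -> list[TadMatch]:
    """Every 9-residue window tested against every pattern; overlapping
    matches are all reported."""
    patterns = patterns if patterns is not None else default_tad_patterns()
    if not patterns:
        raise ValueError("pattern set must be non-empty")
    out = []
    for i in range(len(protein) - 8):
        nine = protein[i : i + 9]
        for pat in patterns:
            if pat.matches(nine):
                out.append(TadMatch(i, nine, pat.pattern_id))
    return out


# ---------------------------------------------------------------------------
# DNA binding motif


@dataclass
class MotifHit:
    position: int  # plus-strand start, 0-based half-open
    strand: str  # '+' or '-'
    motif: str


def scan_binding_motif(dna: str, motif: str = "TAATCC") -> list[MotifHit]:
    """Exact-match scan of a motif on both strands of a DNA sequence.

    Hit positions refer to the plus strand, half-open.  'N' bases never match.
    """
    dna = dna.upper()
    if set(dna) - set("ACGTN"):
        raise ValueError("DNA must contain only A/C/G/T/N")
    hits = []
    targets = [(motif.upper(), "+"), (reverse_complement(motif.upper()), "-")]
    for target, strand in targets:
        i = dna.find(target)
        while i >= 0:
            hits.append(MotifHit(i, strand, motif.upper()))
            i = dna.find(target, i + 1)
    # palindromic motifs: one physical site, keep one record per position
    seen = set()
    uniq = []
    for h in sorted(hits, key=lambda h: (h.position, h.strand)):
        if (h.position, h.strand) in seen:
            continue
        seen.add((h.position, h.strand))
        uniq.append(h)
    return uniq
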