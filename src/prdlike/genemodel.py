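"""Canonical three-exon PRD-LIKE gene models: scanning, reconstruction, classification.

PRD-LIKE homeobox genes of the Leutx/Argfx group share a canonical structure:
a short first exon (often just two codons) ending in a phase-1 GT donor, a
second exon that begins 14 nt upstream of the homeobox and carries homeodomain
codons 1-46, a phase-0 intron between homeodomain codons 46 and 47 (a typical
PRD-LIKE splice position), and a third exon with the rest of the homeodomain
and the C-terminal domain.  This module locates homeodomains in genomic contigs
by six-frame profile scanning, rebuilds the canonical exon structure around the
hit, splices and translates the model, and classifies the locus as intact,
retro-pseudogene (intronless) or disrupted pseudogene (multiple stop/frameshift
lesions).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

HD_LEN = 60

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(dna: str) -> str:
    return dna.translate(_COMPLEMENT)[::-1]


def default_hd_profile() -> str:
    """The shipped 60-column K50-type homeodomain consensus profile."""
    text = resources.files("prdlike").joinpath("data","hd_profile.txt").read_text()
    lines = [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    profile = lines[0]
    if len(profile) != HD_LEN:
        raise ValueError("homeodomain profile must have 60 columns")
    return profile


def load_matrix(name: str = "BLOSUM62"):
    return substitution_matrices.load(name)


# ---------------------------------------------------------------------------
# domain types


@dataclass
class CanonicalStructure:
    """Parameters of the canonical PRD-LIKE gene architecture."""

    exon2_upstream_of_homeobox: int = 14
    intron2_codon_boundary: int = 46  # intron 2 sits after this homeodomain codon
    intron1_phase: int = 1
    intron2_phase: int = 0
    donor_dinucleotide: str = "GT"
    acceptor_dinucleotide: str = "AG"
    # search windows / limits
    exon1_search_window: int = 20000
    max_intron2: int = 5000
    min_intron: int = 40
    max_exon1_codons: int = 50

    def __post_init__(self):
        if self.intron1_phase not in (0, 1, 2) or self.intron2_phase not in (0, 1, 2):
            raise ValueError("splice phases must be 0, 1 or 2")
        if not 1 <= self.intron2_codon_boundary <= HD_LEN:
            raise ValueError("intron2 codon boundary must lie within the homeodomain")


@dataclass
class Disruption:
    kind: str  # internal_stop | frameshift | missing_splice_site | intronless
    coordinate: int | None = None  # protein codon (1-based) for stops, else locus coord


@dataclass
class GeneModel:
    contig_id: str
    strand: str = "+"
    exons: list[tuple[int, int]] = field(default_factory=list)  # 0-based half-open
    intron_phases: list[int] = field(default_factory=list)
    homeobox_interval: tuple[int, int] | None = None
    status: str = "intact"  # intact | pseudogene_retro | pseudogene_disrupted | fragment
    has_intron1: bool = True
    has_intron2: bool = True

    def __post_init__(self):
        for (a, b), (c, d) in zip(self.exons, self.exons[1:]):
            if not (a < b <= c < d):
                raise ValueError("exons must be ordered and non-overlapping")

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [(e1[1], e2[0]) for e1, e2 in zip(self.exons, self.exons[1:])]

    def spliced(self, contig: str) -> str:
        if self.exons and self.exons[-1][1] > len(contig):
            raise ValueError("exon interval outside contig")
        return "".join(contig[a:b] for a, b in self.exons)


@dataclass
class HdAnchor:
    contig_id: str
    frame: int
    strand: str
    genomic_interval: tuple[int, int]
    score: float
    matched_profile_span: tuple[int, int]  # half-open profile column range

    @property
    def span(self) -> int:
        c0, c1 = self.matched_profile_span
        return c1 - c0


# ---------------------------------------------------------------------------
# scanning


def _translate_frames(contig: str):
    """Yield (frame, strand, protein) for the six reading frames."""
    for strand in "+-":
        seq = contig if strand == "+" else reverse_complement(contig)
        for frame in range(3):
            sub = seq[frame:]
            sub = sub[: len(sub) - len(sub) % 3]
            if not sub:
                continue
            prot = str(Seq(sub).translate())
            yield frame, strand, prot


def _best_segments(values: np.ndarray, valid: np.ndarray, min_len: int):
    """Per row of `values`, the best-scoring contiguous segment of >= min_len
    valid cells.  Returns (score, start_col, end_col) arrays."""
    NEG = -1e6
    v = np.where(valid, values, NEG)
    n, w = v.shape
    prefix = np.zeros((n, w + 1))
    np.cumsum(v, axis=1, out=prefix[:, 1:])
    best = np.full(n, NEG)
    best_j = np.zeros(n, dtype=int)
    best_i = np.zeros(n, dtype=int)
    run_min = np.full(n, np.inf)
    run_arg = np.zeros(n, dtype=int)
    for j in range(min_len, w + 1):
        cand = prefix[:, j - min_len]
        upd = cand < run_min
        run_min[upd] = cand[upd]
        run_arg[upd] = j - min_len
        score = prefix[:, j] - run_min
        upd = score > best
        best[upd] = score[upd]
        best_j[upd] = j
        best_i[upd] = run_arg[upd]
    return best, best_i, best_j


def scan_homeodomain(
    contig: str,
    profile: str | None = None,
    matrix=None,
    threshold: float = 100.0,
    min_span: int = 15,
    contig_id: str = "contig",
) -> list[HdAnchor]:
    """Scan all six reading frames for (possibly partial) homeodomain hits.

    Scoring is a position-specific sum over a substitution matrix along each
    profile-vs-translation diagonal; no gaps are allowed inside the window
    (homeodomains are fixed-length).  Partial hits down to ``min_span`` profile
    columns are reported, so a homeodomain split by the canonical codon-46/47
    intron still yields its exon-2 portion as an anchor.  Anchors are sorted by
    score descending, ties leftmost and plus strand first; overlapping hits on
    the same strand are reduced to the best one.
    """
    if not contig:
        raise ValueError("empty contig")
    profile = profile or default_hd_profile()
    if len(profile) != HD_LEN:
        raise ValueError("profile must have 60 columns")
    matrix = matrix if matrix is not None else load_matrix()

    alphabet = "".join(matrix.alphabet)
    lut = np.asarray(matrix)
    aa_index = {aa: i for i, aa in enumerate(alphabet)}
    x_idx = aa_index.get("X", 0)
    prof_idx = np.array([aa_index.get(a, x_idx) for a in profile])

    anchors: list[HdAnchor] = []
    L = len(contig)
    for frame, strand, prot in _translate_frames(contig):
        lt = len(prot)
        if lt == 0:
            continue
        t_idx = np.array([aa_index.get(a, x_idx) for a in prot])
        scores = lut[t_idx[:, None], prof_idx[None, :]]  # (lt, 60)
        n_diag = lt + HD_LEN - 1
        diag = np.zeros((n_diag, HD_LEN))
        valid = np.zeros((n_diag, HD_LEN), dtype=bool)
        p = np.repeat(np.arange(lt), HD_LEN)
        c = np.tile(np.arange(HD_LEN), lt)
        rows = p - c + (HD_LEN - 1)
        diag[rows, c] = scores.ravel()
        valid[rows, c] = True
        best, c0, c1 = _best_segments(diag, valid, min_span)
        for k in np.nonzero(best >= threshold)[0]:
            cc0, cc1 = int(c0[k]), int(c1[k])
            p0 = int(k) - (HD_LEN - 1) + cc0  # protein start of matched span
            nt0 = frame + 3 * p0
            nt1 = frame + 3 * (p0 + (cc1 - cc0))
            if strand == "-":
                nt0, nt1 = L - nt1, L - nt0
            anchors.append(
                HdAnchor(contig_id, frame, strand, (nt0, nt1), float(best[k]), (cc0, cc1))
            )

    anchors.sort(key=lambda a: (-a.score, a.strand != "+", a.genomic_interval[0]))
    kept: list[HdAnchor] = []
    for a in anchors:
        if any(
            k.strand == a.strand
            and a.genomic_interval[0] < k.genomic_interval[1]
            and k.genomic_interval[0] < a.genomic_interval[1]
            for k in kept
        ):
            continue
        kept.append(a)
    return kept


# ---------------------------------------------------------------------------
# reconstruction


def _profile_scores(matrix, profile: str, text: str, offset: int) -> float:
    alphabet = matrix.alphabet
    total = 0.0
    for i, aa in enumerate(text):
        a = profile[offset + i] if profile[offset + i] in alphabet else "X"
        b = aa if aa in alphabet else "X"
        total += matrix[a, b]
    return total


def _self_score(matrix, profile: str, c0: int, c1: int) -> float:
    return sum(matrix[a, a] for a in profile[c0:c1] if a in matrix.alphabet)


def _find_exon1(contig: str, exon2_start: int, canon: CanonicalStructure):
    """Search upstream of exon 2 for an ATG-initiated short exon ending in a
    phase-1 GT donor.  Candidates are tried nearest-first (shortest intron 1);
    for a given donor the nearest in-frame ATG wins.  Returns (exon1, intron_ok)
    or None."""
    if exon2_start < 2 or contig[exon2_start - 2 : exon2_start] != canon.acceptor_dinucleotide:
        return None
    lo = max(0, exon2_start - 2 - canon.exon1_search_window)
    for g in range(exon2_start - canon.min_intron, lo - 1, -1):
        if contig[g : g + 2] != canon.donor_dinucleotide:
            continue
        for k in range(1, canon.max_exon1_codons + 1):
            a = g - (3 * k + 1)
            if a < 0:
                break
            if contig[a : a + 3] != "ATG":
                continue
            # no in-frame stop between start codon and donor
            body = contig[a:g]
            codons = [body[i : i + 3] for i in range(0, len(body) - 2, 3)]
            if any(c in ("TAA", "TAG", "TGA") for c in codons):
                break
            return (a, g)
    return None


def reconstruct_gene(
    contig: str,
    anchor: HdAnchor,
    canon: CanonicalStructure | None = None,
    profile: str | None = None,
    matrix=None,
    min_continuation_fraction: float = 0.5,
) -> GeneModel:
    """Rebuild the canonical three-exon model around a homeodomain anchor.

    The anchor must cover the start of the homeodomain (profile column 1).  If
    the anchor stops at the codon-46/47 boundary, a GT..AG intron is searched
    whose acceptor restores homeodomain codons 47-60 in phase 0 (best-scoring
    acceptor wins, ties to the shortest intron).  Exon 2 is set to begin 14 nt
    upstream of the homeobox, exon 1 is located by scanning upstream for a
    phase-1 GT donor preceded by a short ATG-initiated coding stretch, and
    exon 3 runs to the first in-frame stop.  Parts that cannot be resolved
    leave ``status='fragment'``.
    """
    canon = canon or CanonicalStructure()
    profile = profile or default_hd_profile()
    matrix = matrix if matrix is not None else load_matrix()
    if anchor.strand == "-":
        contig = reverse_complement(contig)
        a0, a1 = anchor.genomic_interval
        anchor = HdAnchor(
            anchor.contig_id, anchor.frame, "+",
            (len(contig) - a1, len(contig) - a0), anchor.score, anchor.matched_profile_span,
        )
    c0, c1 = anchor.matched_profile_span
    g0, g1 = anchor.genomic_interval
    if g1 > len(contig) or contig[g0:g1] == "":
        raise ValueError("anchor absent from contig")
    if c0 != 0:
        return GeneModel(anchor.contig_id, anchor.strand, [(g0, g1)],
                         homeobox_interval=(g0, g1), status="fragment")
    if "N" in contig[max(0, g0 - canon.exon1_search_window): min(len(contig), g1 + canon.max_intron2)]:
        return GeneModel(anchor.contig_id, anchor.strand, [(g0, g1)],
                         homeobox_interval=(g0, g1), status="fragment")

    hd_start = g0
    boundary = hd_start + 3 * canon.intron2_codon_boundary  # genomic end of codon 46
    tail_cols = HD_LEN - canon.intron2_codon_boundary       # 14 codons
    tail_self = _self_score(matrix, profile, canon.intron2_codon_boundary, HD_LEN)

    # Decide between an intact codon-46/47 intron and a contiguous homeobox by
    # scoring homeodomain codons 47-60 under both hypotheses.
    def tail_score_at(q: int) -> float | None:
        tail_nt = contig[q : q + 3 * tail_cols]
        if len(tail_nt) < 3 * tail_cols:
            return None
        return _profile_scores(matrix, profile, str(Seq(tail_nt).translate()),
                               canon.intron2_codon_boundary)

    min_tail = min_continuation_fraction * tail_self
    contiguous = tail_score_at(boundary)
    has_intron2 = True
    if contiguous is not None and contiguous >= min_tail:
        has_intron2 = False
        exon3_cds_start = boundary
    elif contig[boundary : boundary + 2] == canon.donor_dinucleotide:
        best = None
        for q in range(boundary + canon.min_intron,
                       min(len(contig) - 2, boundary + canon.max_intron2) + 1):
            if contig[q - 2 : q] != canon.acceptor_dinucleotide:
                continue
            s = tail_score_at(q)
            if s is not None and (best is None or s > best[0]):
                best = (s, q)
        if best is None or best[0] < min_tail:
            return GeneModel(anchor.contig_id, "+", [(g0, boundary)],
                             homeobox_interval=(g0, boundary), status="fragment")
        exon3_cds_start = best[1]
    else:
        return GeneModel(anchor.contig_id, "+", [(g0, boundary)],
                         homeobox_interval=(g0, boundary), status="fragment")

    exon2_start = hd_start - canon.exon2_upstream_of_homeobox

    # exon 3 extends to the first in-frame stop codon
    pos = exon3_cds_start + 3 * tail_cols
    exon3_end = None
    while pos + 3 <= len(contig):
        if contig[pos : pos + 3] in ("TAA", "TAG", "TGA"):
            exon3_end = pos + 3
            break
        pos += 3
    if exon3_end is None:
        return GeneModel(anchor.contig_id, "+", [(exon2_start, boundary)],
                         homeobox_interval=(g0, g1), status="fragment")
    hd_end = exon3_cds_start + 3 * tail_cols if has_intron2 else boundary + 3 * tail_cols

    if not has_intron2:
        # look for a contiguous upstream ORF (retrocopy-style) before trying
        # intron 1; walk codon-by-codon in the homeodomain reading frame
        upstream = None
        pos = hd_start
        while pos - 3 >= 0 and hd_start - pos <= 3 * (canon.max_exon1_codons + 6):
            codon = contig[pos - 3 : pos]
            if codon in ("TAA", "TAG", "TGA"):
                break
            pos -= 3
            if codon == "ATG":
                upstream = pos
                break
        if upstream is not None:
            return GeneModel(anchor.contig_id, "+", [(upstream, exon3_end)],
                             homeobox_interval=(hd_start, hd_end), status="intact",
                             has_intron1=False, has_intron2=False)
        found = _find_exon1(contig, exon2_start, canon)
        if found is None:
            return GeneModel(anchor.contig_id, "+", [(exon2_start, exon3_end)],
                             homeobox_interval=(hd_start, hd_end), status="fragment",
                             has_intron1=False, has_intron2=False)
        e1s, e1e = found
        return GeneModel(anchor.contig_id, "+", [(e1s, e1e), (exon2_start, exon3_end)],
                         intron_phases=[canon.intron1_phase],
                         homeobox_interval=(hd_start, hd_end), status="intact",
                         has_intron1=True, has_intron2=False)

    found = _find_exon1(contig, exon2_start, canon)
    if found is None:
        return GeneModel(anchor.contig_id, "+", [(exon2_start, boundary), (exon3_cds_start, exon3_end)],
                         intron_phases=[canon.intron2_phase],
                         homeobox_interval=(hd_start, hd_end), status="fragment",
                         has_intron1=False)
    e1s, e1e = found
    return GeneModel(
        anchor.contig_id, "+",
        [(e1s, e1e), (exon2_start, boundary), (exon3_cds_start, exon3_end)],
        intron_phases=[canon.intron1_phase, canon.intron2_phase],
        homeobox_interval=(hd_start, hd_end), status="intact",
    )


# ---------------------------------------------------------------------------
# translation and classification


def splice_and_translate(contig: str, model: GeneModel, code: int = 1):
    """Splice the model's exons, translate from the first ATG of exon 1 and
    report sequence-level disruptions.

    Internal stop codons are reported (translation continues through them) so
    that lesions can be counted.  A spliced length that is not a multiple of 3
    yields a single ``frameshift`` disruption; internal stops are then regarded
    as symptoms of the shifted frame and are not reported separately.
    """
    cds = model.spliced(contig)
    start = cds.find("ATG")
    if start < 0:
        return "", [Disruption("missing_splice_site", None)]
    cds = cds[start:]
    disruptions: list[Disruption] = []
    frameshift = len(cds) % 3 != 0
    cds_trim = cds[: len(cds) - len(cds) % 3]
    prot = str(Seq(cds_trim).translate(table=code))
    if prot.endswith("*"):
        prot = prot[:-1]
    if frameshift:
        disruptions.append(Disruption("frameshift", None))
    else:
        for i, aa in enumerate(prot):
            if aa == "*":
                disruptions.append(Disruption("internal_stop", i + 1))
    return prot, disruptions


def classify_locus(model: GeneModel, disruptions: list[Disruption],
                   max_tolerated: int = 1) -> str:
    """Classify a locus from its structure and sequence lesions.

    An intronless homeobox (the canonical codon-46/47 intron absent) marks a
    retrotransposed pseudogene.  Two or more stop/frameshift lesions mark a
    disrupted pseudogene; a single lesion is tolerated (sequencing errors),
    matching the requirement of *multiple* errors for a pseudogene call.
    """
    if model.status == "fragment":
        return "fragment"
    if not model.has_intron2:
        return "pseudogene_retro"
    n_lesions = sum(d.kind in ("internal_stop", "frameshift") for d in disruptions)
    if n_lesions > max_tolerated:
        return "pseudogene_disrupted"
    return "intact"


def structural_disruptions(model: GeneModel) -> list[Disruption]:
    """Structure-level disruptions implied by the model itself."""
    out = []
    if not model.has_intron2:
        out.append(Disruption("intronless", model.exons[0][0] if model.exons else None))
    return out
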