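"""Homeodomain-centric alignment analytics.

Coordinate mapping between full-length protein and homeodomain numbering,
residue-50 typing (K50/Q50/R50/N50 factors differ in TAATCC-motif preference),
Clustal-style conservation symbols under the Gonnet PAM 250 matrix, MView-style
90% consensus lines, pairwise percent identity with explicit gap handling,
specificity-residue combination screens (e.g. positions 47/54), and
single-nucleotide codon reachability classified into transitions and
transversions.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import standard_dna_table

SPECIFICITY_POSITIONS = (2, 3, 5, 47, 50, 51, 54, 58)
GAP_CHARS = "-."
TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
STOP_CODONS = ("TAA", "TAG", "TGA")


# ---------------------------------------------------------------------------
# containers


@dataclass
class Alignment:
    """Aligned protein sequences: list of (taxon_id, row with '-' gaps)."""

    rows: list[tuple[str, str]]

    def __post_init__(self):
        if not self.rows:
            raise ValueError("alignment needs at least one row")
        n = len(self.rows[0][1])
        if any(len(s) != n for _, s in self.rows):
            raise ValueError("alignment rows must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def column(self, j: int) -> str:
        return "".join(s[j] for _, s in self.rows)

    def row(self, taxon_id: str) -> str:
        for tid, s in self.rows:
            if tid == taxon_id:
                return s
        raise KeyError(taxon_id)

    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        from Bio import SeqIO

        return cls([(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")])

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for tid, s in self.rows:
                fh.write(f">{tid}\n{s}\n")


@dataclass
class HomeodomainAnnotation:
    """Homeodomain placement within a full-length protein.

    ``hd_start_in_protein`` is the 1-based protein position of homeodomain
    residue 1 (8 for full-length human LEUTX, fixed by the K57A <-> K50A
    correspondence)."""

    taxon_id: str
    hd_start_in_protein: int
    hd_sequence: str
    specificity_positions: tuple[int, ...] = SPECIFICITY_POSITIONS

    def __post_init__(self):
        if not 1 <= len(self.hd_sequence) <= 60:
            raise ValueError("homeodomain sequence must be 1-60 residues")

    @property
    def residue50(self) -> str | None:
        if len(self.hd_sequence) < 50:
            return None
        return self.hd_sequence[49]


@dataclass
class ConservationScheme:
    matrix_id: str = "GONNET1992"
    full_threshold: float = 1.0  # '*'
    partial_threshold: float = 0.5  # ':' above, '.' at or below
    consensus_level: float = 0.9

    def __post_init__(self):
        if not self.partial_threshold < self.full_threshold:
            raise ValueError("thresholds must be ordered")


@dataclass
class CodonPath:
    codon_from: str
    codon_to: str
    changed_position: int  # 1-3
    substitution_class: str  # transition | transversion


@dataclass
class CombinationScreen:
    positions: tuple[int, int]
    contingency: dict[tuple[str, str], int]
    absent_pairs: list[tuple[str, str]]


# ---------------------------------------------------------------------------
# coordinate mapping and typing


def map_coordinates(annotation: HomeodomainAnnotation, pos: int, direction: str) -> int:
    """Map between full-length protein and homeodomain numbering (both 1-based).

    protein_pos = hd_pos + (hd_start_in_protein - 1); the inverse is exact.
    ``direction`` is 'protein_to_hd' or 'hd_to_protein'.
    """
    offset = annotation.hd_start_in_protein - 1
    if direction in ("protein_to_hd", "protein->hd"):
        hd = pos - offset
        if not 1 <= hd <= 60:
            raise ValueError(f"protein position {pos} falls outside the homeodomain")
        return hd
    if direction in ("hd_to_protein", "hd->protein"):
        if not 1 <= pos <= 60:
            raise ValueError("homeodomain position must be in 1..60")
        return pos + offset
    raise ValueError(f"unknown direction {direction!r}")


def classify_hd_type(annotation: HomeodomainAnnotation) -> str:
    """Type a homeodomain by its position-50 residue (K50/Q50/R50/N50/other)."""
    r50 = annotation.residue50
    if r50 is None or r50 in GAP_CHARS or r50 == "X":
        warnings.warn(f"{annotation.taxon_id}: homeodomain position 50 unresolved")
        return "other"
    return f"{r50}50" if r50 in "KQRN" else "other"


# ---------------------------------------------------------------------------
# conservation / consensus / identity


def _load_classes():
    raw = json.loads(resources.files("prdlike").joinpath("data","mview_classes.json").read_text())
    return [(sym, set(members)) for sym, members in raw["classes"]]


def column_conservation(alignment: Alignment, scheme: ConservationScheme | None = None) -> str:
    """One symbol per column: '*' identical, ':' strongly similar, '.' weak,
    ' ' for columns containing a gap.

    A column's score is the minimum pairwise normalized substitution score
    s(a,b)/max(s(a,a), s(b,b)), clamped to [0,1], so one divergent taxon
    downgrades the column.
    """
    if alignment.n_rows < 2:
        raise ValueError("need at least two rows")
    scheme = scheme or ConservationScheme()
    matrix = substitution_matrices.load(scheme.matrix_id)
    out = []
    for j in range(alignment.n_columns):
        col = alignment.column(j)
        if any(c in GAP_CHARS for c in col):
            out.append(" ")
            continue
        score = 1.0
        for a, b in itertools.combinations(set(col), 2):
            aa = a if a in matrix.alphabet else "X"
            bb = b if b in matrix.alphabet else "X"
            denom = max(matrix[aa, aa], matrix[bb, bb])
            s = matrix[aa, bb] / denom if denom > 0 else 0.0
            score = min(score, max(0.0, min(1.0, s)))
        if score >= scheme.full_threshold - 1e-9:
            out.append("*")
        elif score > scheme.partial_threshold:
            out.append(":")
        else:
            out.append(".")
    return "".join(out)


def consensus(alignment: Alignment, scheme: ConservationScheme | None = None) -> str:
    """MView-style consensus at the configured level (default 90%).

    Per column: the residue itself if it reaches the level; otherwise the
    symbol of the first physicochemical class (shipped table, most specific
    first) whose members jointly reach the level; otherwise '.'.
    """
    if alignment.n_rows < 2:
        raise ValueError("need at least two rows")
    scheme = scheme or ConservationScheme()
    classes = _load_classes()
    n = alignment.n_rows
    out = []
    for j in range(alignment.n_columns):
        col = alignment.column(j)
        counts: dict[str, int] = {}
        for c in col:
            counts[c] = counts.get(c, 0) + 1
        best_res = max((c for c in counts if c not in GAP_CHARS), key=counts.get, default=None)
        if best_res is not None and counts[best_res] / n >= scheme.consensus_level:
            out.append(best_res)
            continue
        for sym, members in classes:
            freq = sum(v for c, v in counts.items() if c in members) / n
            if freq >= scheme.consensus_level:
                out.append(sym)
                break
        else:
            out.append(".")
    return "".join(out)


def percent_identity(seq_a: str, seq_b: str, gap_mode: str = "exclude") -> float:
    """Percent identity of two aligned rows.

    gap_mode='exclude' (default): denominator counts only columns where
    neither row has a gap.  gap_mode='mismatch': gap-vs-residue columns count
    in the denominator as mismatches (columns gapped in both rows are always
    ignored).
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned (equal length)")
    ident = comparable = 0
    for a, b in zip(seq_a, seq_b):
        ga, gb = a in GAP_CHARS, b in GAP_CHARS
        if ga and gb:
            continue
        if gap_mode == "exclude" and (ga or gb):
            continue
        comparable += 1
        if not ga and not gb and a == b:
            ident += 1
    if comparable == 0:
        raise ValueError("no comparable columns")
    return 100.0 * ident / comparable


def round_half_up(x: float) -> int:
    """Half-up integer rounding, reproducing printed integer identities."""
    return int(np.floor(x + 0.5))


def identity_matrix(alignment: Alignment, gap_mode: str = "exclude") -> pd.DataFrame:
    ids = [tid for tid, _ in alignment.rows]
    mat = pd.DataFrame(100.0, index=ids, columns=ids)
    for (ta, sa), (tb, sb) in itertools.combinations(alignment.rows, 2):
        v = percent_identity(sa, sb, gap_mode=gap_mode)
        mat.loc[ta, tb] = mat.loc[tb, ta] = v
    return mat


# ---------------------------------------------------------------------------
# codon reachability


def _codons_for(aa: str) -> list[str]:
    codons = sorted(c for c, a in standard_dna_table.forward_table.items() if a == aa)
    if aa == "*" or not codons:
        raise ValueError(f"not a standard amino acid: {aa!r}")
    return codons


def codon_paths(aa_from: str, aa_to: str):
    """All single-base sense-codon changes from one amino acid to another.

    Returns (paths, summary): every ordered codon pair differing at exactly
    one position, classified as transition (A<->G, C<->T) or transversion, and
    a summary with ``reachable_by_single_change`` and
    ``reachable_by_transition_only`` flags.
    """
    paths: list[CodonPath] = []
    for cf in _codons_for(aa_from):
        for ct in _codons_for(aa_to):
            diff = [i for i in range(3) if cf[i] != ct[i]]
            if len(diff) != 1:
                continue
            i = diff[0]
            cls = "transition" if (cf[i], ct[i]) in TRANSITIONS else "transversion"
            paths.append(CodonPath(cf, ct, i + 1, cls))
    n_ts = sum(p.substitution_class == "transition" for p in paths)
    summary = {
        "reachable_by_single_change": bool(paths),
        "reachable_by_transition": n_ts > 0,
        "reachable_by_transition_only": bool(paths) and n_ts == len(paths),
        "n_transition": n_ts,
        "n_transversion": len(paths) - n_ts,
    }
    return paths, summary


# ---------------------------------------------------------------------------
# specificity-residue combination screen


def combination_screen(
    annotations: list[HomeodomainAnnotation], positions: tuple[int, int] = (47, 54)
) -> CombinationScreen:
    """Contingency table of residue pairs at two homeodomain positions across
    taxa, and the combinations of observed marginal residues never seen
    jointly (e.g. the missing I47-V54 pairing)."""
    p1, p2 = positions
    contingency: dict[tuple[str, str], int] = {}
    for ann in annotations:
        if len(ann.hd_sequence) < max(p1, p2):
            continue
        a, b = ann.hd_sequence[p1 - 1], ann.hd_sequence[p2 - 1]
        if a in GAP_CHARS or b in GAP_CHARS or "X" in (a, b):
            continue
        contingency[(a, b)] = contingency.get((a, b), 0) + 1
    seen1 = sorted({a for a, _ in contingency})
    seen2 = sorted({b for _, b in contingency})
    absent = [(a, b) for a in seen1 for b in seen2 if (a, b) not in contingency]
    return CombinationScreen(positions, contingency, absent)


def annotate_alignment_row(
    alignment: Alignment, taxon_id: str, hd_column_start: int, hd_start_in_protein: int | None = None
) -> HomeodomainAnnotation:
    """Build a HomeodomainAnnotation from an alignment row given the 0-based
    alignment column where the homeodomain starts."""
    row = alignment.row(taxon_id)
    ungapped_before = sum(1 for c in row[:hd_column_start] if c not in GAP_CHARS)
    hd = row[hd_column_start : hd_column_start + 60]
    return HomeodomainAnnotation(
        taxon_id,
        hd_start_in_protein if hd_start_in_protein is not None else ungapped_before + 1,
        hd,
    )
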