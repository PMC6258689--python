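"""Population-genetic constraint analysis of coding variation.

Codon-aware consequence annotation of variants against a CDS model,
per-individual nonsynonymous/synonymous burden counting (optionally restricted
to homozygous genotypes), through-origin regression of average burden on CDS
width (a gene lying below the genome-wide trend, i.e. with a negative
residual, is constrained), and rule-based triage of variants into potential
loss-of-function candidates using phylogenetic acceptance, homeodomain
specificity positions and transactivation-motif overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

NONSYNONYMOUS = {"missense", "nonsense", "stop_loss"}
STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass
class CdsModel:
    gene_id: str
    cds_sequence: str  # length divisible by 3; terminal stop codon allowed
    strand: str = "+"
    intron_after: tuple[int, ...] = ()  # CDS positions (1-based) followed by an intron

    def __post_init__(self):
        self.cds_sequence = self.cds_sequence.upper()
        if len(self.cds_sequence) % 3:
            raise ValueError("CDS length must be divisible by 3")
        prot = str(Seq(self.cds_sequence).translate())
        if "*" in prot[:-1]:
            raise ValueError("CDS must not contain internal stop codons")

    @property
    def cds_width(self) -> int:
        return len(self.cds_sequence)


@dataclass
class VariantRecord:
    gene_id: str
    cds_position: int | None  # 1-based; None for pure splice-context variants
    ref: str
    alt: str
    consequence: str
    protein_change: str | None = None
    frequencies: dict[str, float] = field(default_factory=dict)

    @property
    def max_af(self) -> float:
        return max(self.frequencies.values(), default=0.0)


def annotate_variant(
    cds: CdsModel,
    position: int | None,
    ref: str,
    alt: str,
    splice: tuple[int, int] | None = None,
    frequencies: dict[str, float] | None = None,
) -> VariantRecord:
    """Annotate one variant against a CDS model.

    ``splice=(intron_index, offset)`` marks intronic context instead of a CDS
    position: offsets +1/+2 are the donor GT, -2/-1 the acceptor AG.  SNVs are
    classified by translating the affected codon before and after; indels by
    length mod 3.  Protein changes are reported as p.RefPosAlt.
    """
    ref, alt = ref.upper(), alt.upper()
    freqs = frequencies or {}
    if splice is not None:
        _, offset = splice
        if offset in (1, 2):
            cons = "splice_donor"
        elif offset in (-1, -2):
            cons = "splice_acceptor"
        else:
            raise ValueError("splice offset must be +1/+2 (donor) or -1/-2 (acceptor)")
        return VariantRecord(cds.gene_id, None, ref, alt, cons, None, freqs)

    if position is None or not 1 <= position <= cds.cds_width:
        raise ValueError("position outside CDS and outside splice context")
    i = position - 1
    if cds.cds_sequence[i : i + len(ref)] != ref:
        raise ValueError(
            f"reference mismatch at CDS position {position}: "
            f"expected {cds.cds_sequence[i:i + len(ref)]!r}, got {ref!r}"
        )

    if len(ref) != len(alt):
        delta = abs(len(ref) - len(alt))
        cons = "frameshift" if delta % 3 else "inframe_indel"
        codon_no = i // 3 + 1
        return VariantRecord(cds.gene_id, position, ref, alt, cons,
                             f"p.{_aa_at(cds, codon_no)}{codon_no}fs" if cons == "frameshift" else None,
                             freqs)

    if len(ref) != 1:
        raise ValueError("multi-base substitutions must be decomposed to SNVs")
    ci = i // 3
    codon = cds.cds_sequence[3 * ci : 3 * ci + 3]
    off = i % 3
    mutated = codon[:off] + alt + codon[off + 1 :]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(mutated).translate())
    if aa_ref == "*":
        cons = "synonymous" if aa_alt == "*" else "stop_loss"
    elif aa_alt == "*":
        cons = "nonsense"
    elif aa_ref == aa_alt:
        cons = "synonymous"
    else:
        cons = "missense"
    pchange = f"p.{aa_ref}{ci + 1}{aa_alt}"
    return VariantRecord(cds.gene_id, position, ref, alt, cons, pchange, freqs)


def _aa_at(cds: CdsModel, codon_no: int) -> str:
    codon = cds.cds_sequence[3 * (codon_no - 1) : 3 * codon_no]
    return str(Seq(codon).translate())


# ---------------------------------------------------------------------------
# burdens


def per_individual_burden(
    consequences,
    genotypes: np.ndarray,
    zygosity_class: str = "any",
) -> pd.DataFrame:
    """Count variant sites carried per individual, split into #N / #S / #other.

    ``consequences`` is a sequence of consequence strings (one per variant
    column); ``genotypes`` is individuals x variants with 0 hom-ref, 1 het,
    2 hom-alt and -1 missing (missing sites are excluded per individual).
    A carried site counts once regardless of zygosity for class='any';
    class='hom_only' counts genotype==2 sites only.  Nonsynonymous means
    missense, nonsense or stop_loss; indel and splice consequences go to
    #other.
    """
    cons = list(consequences)
    gt = np.asarray(genotypes)
    if gt.ndim != 2 or gt.shape[1] != len(cons):
        raise ValueError("genotype matrix does not match the variant table")
    if zygosity_class == "any":
        carried = gt >= 1
    elif zygosity_class == "hom_only":
        carried = gt == 2
    else:
        raise ValueError("zygosity_class must be 'any' or 'hom_only'")
    is_n = np.array([c in NONSYNONYMOUS for c in cons])
    is_s = np.array([c == "synonymous" for c in cons])
    is_other = ~(is_n | is_s)
    return pd.DataFrame(
        {
            "N": carried[:, is_n].sum(axis=1) if is_n.any() else np.zeros(gt.shape[0], int),
            "S": carried[:, is_s].sum(axis=1) if is_s.any() else np.zeros(gt.shape[0], int),
            "other": carried[:, is_other].sum(axis=1) if is_other.any() else np.zeros(gt.shape[0], int),
        },
        index=pd.RangeIndex(gt.shape[0], name="individual"),
    )


def burden_regression(widths, averages, fit_intercept: bool = False):
    """Regress average per-individual burden on CDS width.

    Default is ordinary least squares through the origin (expected variant
    count is proportional to CDS width): slope = sum(xy)/sum(x^2).  Returns
    (slope, intercept, residuals) with residual = observed - predicted; a
    negative residual marks a gene more constrained than the genome-wide
    trend.
    """
    x = np.asarray(widths, dtype=float)
    y = np.asarray(averages, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two genes")
    if np.all(x == 0):
        raise ValueError("all CDS widths are zero")
    if fit_intercept:
        design = np.column_stack([x, np.ones_like(x)])
        (slope, intercept), *_ = np.linalg.lstsq(design, y, rcond=None)
    else:
        slope = float(np.sum(x * y) / np.sum(x * x))
        intercept = 0.0
    residuals = y - (slope * x + intercept)
    return float(slope), float(intercept), residuals


# ---------------------------------------------------------------------------
# triage


@dataclass
class TriageRuleSet:
    flag_classes: tuple[str, ...] = ("nonsense", "frameshift", "splice_donor")
    use_phylogenetic: bool = True  # missense criterion (a): alt unseen across species
    use_specificity: bool = True  # (b): homeodomain specificity position
    use_tad: bool = True  # (c): inside a 9aaTAD match
    common_af: float = 0.01


def triage_variants(
    variants: list[VariantRecord],
    ortholog_residues: dict[int, set[str]] | None = None,
    specificity_protein_positions: set[int] | None = None,
    tad_intervals: list[tuple[int, int]] | None = None,
    rules: TriageRuleSet | None = None,
) -> pd.DataFrame:
    """Flag variants as impairing candidates / common / evolutionarily accepted.

    ``ortholog_residues`` maps 1-based protein positions to residues observed
    at the aligned column in other species; ``tad_intervals`` are 1-based
    inclusive protein ranges of transactivation-motif matches.  Nonsense,
    frameshift and splice-donor variants are always impairing candidates;
    a missense variant is a candidate only if it triggers an enabled criterion
    and its alternate residue is not evolutionarily accepted.
    """
    rules = rules or TriageRuleSet()
    ortholog_residues = ortholog_residues or {}
    specificity_protein_positions = specificity_protein_positions or set()
    tad_intervals = tad_intervals or []
    rows = []
    for v in variants:
        impairing = common = accepted = False
        warning = ""
        common = v.max_af > rules.common_af
        if v.consequence in rules.flag_classes:
            impairing = True
        elif v.consequence == "missense":
            ppos = (v.cds_position - 1) // 3 + 1 if v.cds_position else None
            alt_aa = v.protein_change[-1] if v.protein_change else None
            if ppos is None or alt_aa is None:
                warning = "unmappable position"
            else:
                observed = ortholog_residues.get(ppos, set())
                accepted = alt_aa in observed
                hit = (
                    (rules.use_phylogenetic and not accepted and ppos in ortholog_residues)
                    or (rules.use_specificity and ppos in specificity_protein_positions)
                    or (rules.use_tad and any(a <= ppos <= b for a, b in tad_intervals))
                )
                impairing = hit and not accepted
        rows.append(
            {
                "gene_id": v.gene_id,
                "hgvs_p": v.protein_change,
                "consequence": v.consequence,
                "max_af": v.max_af,
                "impairing_candidate": impairing,
                "common": common,
                "evolutionarily_accepted": accepted,
                "warning": warning,
            }
        )
    return pd.DataFrame(rows)
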