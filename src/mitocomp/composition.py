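"""Base composition, AT/GC content and strand skews.

AT skew = (A - T)/(A + T) and GC skew = (G - C)/(G + C) summarize the
strand asymmetry of base composition.  Spider mitogenomes are strongly
AT-rich and, on the majority (J) strand, typically show a negative AT skew
(T preferred over A) and a positive GC skew (G preferred over C).

Composition is reported for the full genome, for the concatenated PCGs and
their three codon positions, for the concatenated tRNAs and rRNAs, for the
control region and per PCG.  ``N`` sites are excluded from every
denominator.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .genome_io import AnnotatedMitogenome, extract_gene_sequence


def at_skew(a: float, t: float) -> float:
    """(A - T)/(A + T); accepts counts, fractions or percentages."""
    if a + t == 0:
        return math.nan
    return (a - t) / (a + t)


def gc_skew(g: float, c: float) -> float:
    """(G - C)/(G + C); accepts counts, fractions or percentages."""
    if g + c == 0:
        return math.nan
    return (g - c) / (g + c)


@dataclass(frozen=True)
class CompositionReport:
    """Base counts, AT/GC content and skews for one region."""

    region_label: str
    a: int
    t: int
    g: int
    c: int

    @property
    def total(self) -> int:
        return self.a + self.t + self.g + self.c

    @property
    def at_content(self) -> float:
        return (self.a + self.t) / self.total if self.total else math.nan

    @property
    def gc_content(self) -> float:
        return (self.g + self.c) / self.total if self.total else math.nan

    @property
    def at_skew(self) -> float:
        return at_skew(self.a, self.t)

    @property
    def gc_skew(self) -> float:
        return gc_skew(self.g, self.c)


def base_composition(seq: str, region_label: str = "") -> CompositionReport:
    """Count bases and derive contents/skews; N sites are ignored."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    return CompositionReport(
        region_label=region_label,
        a=seq.count("A"), t=seq.count("T"), g=seq.count("G"), c=seq.count("C"),
    )


def _codon_position_seqs(pcg_seqs: list[str]) -> tuple[str, str, str]:
    """Split concatenated PCGs into the three codon-position subsequences.

    Each gene is read in its own orientation from frame 0; the trailing
    incomplete codon (a 1-2 nt truncated stop) carries no full codon
    positions and is dropped.
    """
    p1, p2, p3 = [], [], []
    for seq in pcg_seqs:
        n = len(seq) - len(seq) % 3
        p1.append(seq[0:n:3])
        p2.append(seq[1:n:3])
        p3.append(seq[2:n:3])
    return "".join(p1), "".join(p2), "".join(p3)


def region_composition(genome: AnnotatedMitogenome) -> pd.DataFrame:
    """Composition table over the standard regions of one mitogenome.

    Rows: full mitogenome (J strand), concatenated PCGs and codon positions
    1/2/3, concatenated tRNAs, concatenated rRNAs, control region, and one
    row per PCG.  Regions with no features are omitted.
    """
    reports: list[CompositionReport] = [
        base_composition(genome.sequence, "full_mitogenome")
    ]
    pcgs = sorted(genome.features_of_type("PCG"), key=lambda f: f.name)
    if pcgs:
        seqs = [extract_gene_sequence(genome, f.name) for f in pcgs]
        reports.append(base_composition("".join(seqs), "PCGs"))
        for i, sub in enumerate(_codon_position_seqs(seqs), start=1):
            reports.append(base_composition(sub, f"PCGs_pos{i}"))
    for ftype, label in (("tRNA", "tRNAs"), ("rRNA", "rRNAs")):
        feats = genome.features_of_type(ftype)
        if feats:
            cat = "".join(extract_gene_sequence(genome, f.name) for f in feats)
            reports.append(base_composition(cat, label))
    try:
        reports.append(base_composition(extract_gene_sequence(genome, "CR"), "CR"))
    except KeyError:
        from .genome_io import logger

        logger.warning("W-CR-MISSING %s: control-region composition row "
                       "omitted", genome.identifier)
    for f, seq in zip(pcgs, [extract_gene_sequence(genome, f.name) for f in pcgs]):
        reports.append(base_composition(seq, f.name))

    return pd.DataFrame(
        {
            "genome": genome.identifier,
            "region": r.region_label,
            "A": r.a, "T": r.t, "G": r.g, "C": r.c,
            "AT_pct": round(100 * r.at_content, 1),
            "GC_pct": round(100 * r.gc_content, 1),
            "AT_skew": round(r.at_skew, 3),
            "GC_skew": round(r.gc_skew, 3),
        }
        for r in reports
    )
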