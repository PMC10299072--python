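"""Codon-usage bias statistics under the invertebrate mitochondrial code.

The invertebrate mitochondrial code (translation table 5) has 62 sense
codons (stops TAA/TAG only; AGA/AGG code for Ser, ATA for Met, TGA for
Trp), partitioning into 12 two-fold, 6 four-fold, one six-fold (Leu) and
one eight-fold (Ser) synonymous family.  This module computes:

* relative synonymous codon usage, RSCU_ij = x_ij * k_i / n_i, the observed
  count of codon j of amino acid i relative to uniform usage within its
  k_i-fold family;
* Wright's effective number of codons (ENC), generalized to an arbitrary
  family partition: per family the homozygosity estimator
  F = (n * sum p_j^2 - 1)/(n - 1), averaged within each family-size class,
  and ENC = sum_k n_k / Fbar_k, bounded by [20, 62] for table 5;
* the null ENC-GC3 curve ENC*(s) = 2 + s + 29/(s^2 + (1-s)^2) expected
  under mutation pressure alone;
* positional GC content (GC1, GC2, GC3, GC12) pooled over codons;
* the neutrality regression of GC12 on GC3 across genomes, whose slope b
  partitions codon-composition evolution into a mutational share (b) and a
  selective share (1 - b).

The family partition is derived from the translation table at run time,
never hard-coded, so other mitochondrial codes work unchanged.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats

from Bio.Data import CodonTable

_BASES = "TCAG"


class CodonUsageError(ValueError):
    pass


@lru_cache(maxsize=None)
def genetic_code(table_id: int = 5) -> dict[str, str]:
    """Codon -> amino-acid map (sense codons only) for an NCBI table id."""
    try:
        table = CodonTable.unambiguous_dna_by_id[table_id]
    except KeyError as exc:
        raise CodonUsageError(f"unsupported translation table {table_id}") from exc
    return dict(table.forward_table)


@lru_cache(maxsize=None)
def synonymous_families(table_id: int = 5) -> dict[str, tuple[str, ...]]:
    """Amino acid -> tuple of its synonymous codons, from the table."""
    fams: dict[str, list[str]] = {}
    for codon, aa in genetic_code(table_id).items():
        fams.setdefault(aa, []).append(codon)
    return {aa: tuple(sorted(cs)) for aa, cs in sorted(fams.items())}


@dataclass
class CodonUsageTable:
    """Codon counts and family structure for a set of CDS sequences."""

    table_id: int
    counts: dict[str, int]          # per sense codon
    stop_codons: int                # tallied separately
    skipped_codons: int             # codons containing N

    @property
    def families(self) -> dict[str, tuple[str, ...]]:
        return synonymous_families(self.table_id)

    def family_totals(self) -> dict[str, int]:
        return {aa: sum(self.counts[c] for c in codons)
                for aa, codons in self.families.items()}

    @property
    def total_codons(self) -> int:
        return sum(self.counts.values())

    def used_codon_count(self) -> int:
        """Number of distinct sense codons observed ("available codons";
        62 when every sense codon occurs at least once)."""
        return sum(1 for v in self.counts.values() if v > 0)


def count_codons(cds_sequences: list[str], table_id: int = 5) -> CodonUsageTable:
    """Count complete in-frame codons over the sense-codon table.

    Each sequence is read in frame 0 of its own orientation; the trailing
    incomplete codon is dropped; stop codons and codons containing N are
    tallied separately, outside the sense table.
    """
    code = genetic_code(table_id)
    stops = set(CodonTable.unambiguous_dna_by_id[table_id].stop_codons)
    counts = {codon: 0 for codon in code}
    n_stop = n_skip = 0
    for seq in cds_sequences:
        seq = seq.upper().replace("U", "T")
        for i in range(0, len(seq) - len(seq) % 3, 3):
            codon = seq[i : i + 3]
            if codon in counts:
                counts[codon] += 1
            elif codon in stops:
                n_stop += 1
            else:
                n_skip += 1
    return CodonUsageTable(table_id=table_id, counts=counts,
                           stop_codons=n_stop, skipped_codons=n_skip)


def rscu(table: CodonUsageTable) -> dict[str, float]:
    """RSCU per sense codon; NaN for codons of unused families."""
    out: dict[str, float] = {}
    totals = table.family_totals()
    for aa, codons in table.families.items():
        n_i, k = totals[aa], len(codons)
        for c in codons:
            out[c] = table.counts[c] * k / n_i if n_i else math.nan
    return out


def enc(table: CodonUsageTable, *, min_codons: int = 100) -> tuple[float, bool]:
    """Wright's effective number of codons, generalized to the table's
    family partition.

    Returns ``(enc, reliable)``; ``reliable`` is False when fewer than
    ``min_codons`` sense codons were counted.  Families observed once or
    not at all contribute no homozygosity estimate; a family-size class
    with no defined mean imputes it from the 1/k-scaled average of the
    defined classes; the result is capped at the number of sense codons.
    """
    totals = table.family_totals()
    f_by_size: dict[int, list[float]] = {}
    n_by_size: dict[int, int] = {}
    for aa, codons in table.families.items():
        k = len(codons)
        n_by_size[k] = n_by_size.get(k, 0) + 1
        n_i = totals[aa]
        if n_i < 2:
            continue
        p_sq = sum((table.counts[c] / n_i) ** 2 for c in codons)
        f = (n_i * p_sq - 1) / (n_i - 1)
        if f > 0:
            f_by_size.setdefault(k, []).append(f)

    fbar: dict[int, float] = {k: float(np.mean(v)) for k, v in f_by_size.items()}
    if not fbar:
        return math.nan, False
    for k in n_by_size:
        if k not in fbar:
            # impute from defined classes assuming F scales like 1/k
            fbar[k] = np.mean([f * kk for kk, f in fbar.items()]) / k
    value = sum(n_k / fbar[k] for k, n_k in n_by_size.items())
    n_sense = sum(k * n_k for k, n_k in n_by_size.items())
    return min(value, float(n_sense)), table.total_codons >= min_codons


def enc_expected(s: float) -> float:
    """Null ENC at GC3 = s under mutation pressure alone (Wright's curve)."""
    if not 0.0 <= s <= 1.0:
        raise ValueError("GC3 must lie in [0, 1]")
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) ** 2)


@dataclass(frozen=True)
class CodonBiasSummary:
    """Per-genome codon-bias summary: ENC and positional GC fractions."""

    enc: float
    enc_reliable: bool
    gc1: float
    gc2: float
    gc3: float

    @property
    def gc12(self) -> float:
        return (self.gc1 + self.gc2) / 2.0


def positional_gc(cds_sequences: list[str], table_id: int = 5) -> tuple[float, float, float]:
    """(GC1, GC2, GC3) pooled over all complete sense codons.

    GC3 is taken over all third positions of sense codons, not restricted
    to synonymously variable sites.  Stop codons and N-containing codons
    are excluded.
    """
    code = genetic_code(table_id)
    gc = [0, 0, 0]
    n = 0
    for seq in cds_sequences:
        seq = seq.upper().replace("U", "T")
        for i in range(0, len(seq) - len(seq) % 3, 3):
            codon = seq[i : i + 3]
            if codon not in code:
                continue
            n += 1
            for p in range(3):
                if codon[p] in "GC":
                    gc[p] += 1
    if n == 0:
        return math.nan, math.nan, math.nan
    return gc[0] / n, gc[1] / n, gc[2] / n


def bias_summary(cds_sequences: list[str], table_id: int = 5) -> CodonBiasSummary:
    table = count_codons(cds_sequences, table_id)
    value, reliable = enc(table)
    gc1, gc2, gc3 = positional_gc(cds_sequences, table_id)
    return CodonBiasSummary(enc=value, enc_reliable=reliable,
                            gc1=gc1, gc2=gc2, gc3=gc3)


@dataclass(frozen=True)
class NeutralityFit:
    """OLS fit of GC12 on GC3 across genomes.

    The slope estimates the share of codon-composition evolution driven by
    mutational pressure; 1 - slope the share driven by selection.
    """

    slope: float
    intercept: float
    r: float
    p_value: float
    n: int

    @property
    def mutation_share(self) -> float:
        return self.slope

    @property
    def selection_share(self) -> float:
        return 1.0 - self.slope

    @property
    def mutation_share_pct(self) -> float:
        return 100.0 * self.mutation_share

    @property
    def selection_share_pct(self) -> float:
        return 100.0 * self.selection_share


def neutrality_fit(points: list[tuple[float, float]]) -> NeutralityFit:
    """Fit GC12 = a + b*GC3 by ordinary least squares over genomes.

    ``points`` are (gc3, gc12) pairs, one per genome; at least 3 are
    required and GC3 must vary.
    """
    if len(points) < 3:
        raise CodonUsageError("neutrality fit needs at least 3 genomes")
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if np.allclose(x, x[0]):
        raise CodonUsageError("degenerate neutrality fit: GC3 has no variance")
    res = stats.linregress(x, y)
    return NeutralityFit(slope=float(res.slope), intercept=float(res.intercept),
                         r=float(res.rvalue), p_value=float(res.pvalue),
                         n=len(points))


def shares_from_slope(slope: float) -> tuple[float, float]:
    """(selection %, mutation %) implied by a neutrality-plot slope."""
    return 100.0 * (1.0 - slope), 100.0 * slope
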