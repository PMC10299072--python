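"""Nucleotide diversity, pairwise divergence, Ka/Ks and neighbor joining.

Operates on per-gene multiple alignments (codon-aware for PCGs).  Provides:

* nucleotide diversity Pi — the mean proportion of differing sites over all
  unordered sequence pairs — overall and in sliding windows (default 100 bp
  windows, 25 bp step, the DnaSP-style profile);
* pairwise distances under nested substitution models: p distance, JC69,
  K2P, TN93, and a pooled-composite TN93 variant in which the rate
  parameters (transition/transversion partition and base frequencies) are
  estimated once from counts pooled over all pairs and then applied to each
  pair — a composite-likelihood-style estimator;
* Ka/Ks by the Nei-Gojobori (1986) counting method under the invertebrate
  mitochondrial code, with equal-weight averaging over minimal mutational
  pathways for multi-hit codons and Jukes-Cantor correction of pN/pS;
* a deterministic neighbor-joining tree from any distance matrix.

Sites containing gaps or N are removed before comparison, either across all
taxa ("complete" deletion, the default for Pi) or per pair ("pairwise").
Distances whose logarithm argument is non-positive are reported as NaN and
flagged saturated, never clamped.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codon_usage import genetic_code
from Bio.Data import CodonTable


class AlignmentError(ValueError):
    pass


@dataclass
class AlignmentSet:
    """An equal-length multiple alignment of one gene across taxa."""

    gene: str
    taxa: list[str]
    sequences: list[str]
    codon_aware: bool = False

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.sequences):
            raise AlignmentError("taxa/sequence count mismatch")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise AlignmentError("aligned sequences must have equal length")
        self.sequences = [s.upper() for s in self.sequences]
        if self.codon_aware and self.length % 3:
            raise AlignmentError("codon-aware alignment length not divisible by 3")

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def window(self, start: int, end: int) -> "AlignmentSet":
        return AlignmentSet(self.gene, self.taxa,
                            [s[start:end] for s in self.sequences], False)


def read_fasta_alignment(path, gene: str = "", codon_aware: bool = False) -> AlignmentSet:
    from Bio import SeqIO

    taxa, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        taxa.append(rec.id)
        seqs.append(str(rec.seq))
    return AlignmentSet(gene or str(path), taxa, seqs, codon_aware)


_GOOD = frozenset("ACGT")


def _complete_columns(aln: AlignmentSet) -> list[int]:
    return [j for j in range(aln.length)
            if all(s[j] in _GOOD for s in aln.sequences)]


def _pair_diff(s1: str, s2: str, columns=None) -> tuple[int, int]:
    """(differences, compared sites) over columns where both bases are ACGT."""
    it = ((s1[j], s2[j]) for j in columns) if columns is not None else zip(s1, s2)
    diff = comp = 0
    for a, b in it:
        if a in _GOOD and b in _GOOD:
            comp += 1
            if a != b:
                diff += 1
    return diff, comp


# ---------------------------------------------------------------------------
# nucleotide diversity
# ---------------------------------------------------------------------------

def nucleotide_diversity(aln: AlignmentSet, *, deletion: str = "complete") -> float:
    """Pi: mean pairwise difference proportion over all unordered pairs.

    ``deletion``: "complete" removes columns with any gap/N across all taxa
    before comparing; "pairwise" removes them per pair.  NaN when no
    comparable sites remain.
    """
    if aln.n_taxa < 2:
        raise AlignmentError("nucleotide diversity needs at least 2 taxa")
    columns = _complete_columns(aln) if deletion == "complete" else None
    props = []
    for s1, s2 in itertools.combinations(aln.sequences, 2):
        diff, comp = _pair_diff(s1, s2, columns)
        if comp:
            props.append(diff / comp)
    return float(np.mean(props)) if props else math.nan


@dataclass
class WindowDiversity:
    """Sliding-window Pi profile plus the per-gene overall value."""

    gene: str
    window: int
    step: int
    starts: list[int]
    midpoints: list[float]
    pi: list[float]
    overall_pi: float
    tail_window: bool = False  # final window did not fall on a step multiple

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.gene, "window_start": self.starts,
                             "midpoint": self.midpoints, "pi": self.pi})


def sliding_window_pi(aln: AlignmentSet, window: int = 100, step: int = 25,
                      *, deletion: str = "complete") -> WindowDiversity:
    """DnaSP-style sliding-window Pi (defaults 100 bp / 25 bp)."""
    if window < 2 or step < 1:
        raise AlignmentError("window must be >= 2 and step >= 1")
    if aln.length < window:
        raise AlignmentError("alignment shorter than one window")
    starts = list(range(0, aln.length - window + 1, step))
    tail = False
    if starts[-1] != aln.length - window:
        starts.append(aln.length - window)
        tail = True
    pis = [nucleotide_diversity(aln.window(s, s + window), deletion=deletion)
           for s in starts]
    return WindowDiversity(
        gene=aln.gene, window=window, step=step, starts=starts,
        midpoints=[s + window / 2 for s in starts], pi=pis,
        overall_pi=nucleotide_diversity(aln, deletion=deletion),
        tail_window=tail,
    )


# ---------------------------------------------------------------------------
# pairwise distances
# ---------------------------------------------------------------------------

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")

DISTANCE_MODELS = ("p", "JC69", "K2P", "TN93", "MCL-composite")


def _pair_partition(s1: str, s2: str) -> tuple[int, int, int, int]:
    """(A<->G transitions, C<->T transitions, transversions, compared sites)."""
    p1 = p2 = q = comp = 0
    for a, b in zip(s1, s2):
        if a not in _GOOD or b not in _GOOD:
            continue
        comp += 1
        if a == b:
            continue
        if {a, b} <= _PURINES:
            p1 += 1
        elif {a, b} <= _PYRIMIDINES:
            p2 += 1
        else:
            q += 1
    return p1, p2, q, comp


def _jc69(p: float) -> float:
    arg = 1.0 - 4.0 * p / 3.0
    return -0.75 * math.log(arg) if arg > 0 else math.nan


def _k2p(P: float, Q: float) -> float:
    a1, a2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if a1 <= 0 or a2 <= 0:
        return math.nan
    return -0.5 * math.log(a1) - 0.25 * math.log(a2)


def _tn93(P1: float, P2: float, Q: float, freqs: dict[str, float]) -> float:
    gA, gC, gG, gT = freqs["A"], freqs["C"], freqs["G"], freqs["T"]
    gR, gY = gA + gG, gC + gT
    if min(gA, gC, gG, gT) <= 0:
        return math.nan
    k1 = 2.0 * gA * gG / gR
    k2 = 2.0 * gT * gC / gY
    k3 = 2.0 * (gR * gY - gA * gG * gY / gR - gT * gC * gR / gY)
    w1 = 1.0 - P1 / k1 - Q / (2.0 * gR)
    w2 = 1.0 - P2 / k2 - Q / (2.0 * gY)
    w3 = 1.0 - Q / (2.0 * gR * gY)
    if w1 <= 0 or w2 <= 0 or w3 <= 0:
        return math.nan
    return -k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3)


def _base_freqs(sequences: list[str]) -> dict[str, float]:
    counts = {b: 0 for b in "ACGT"}
    for s in sequences:
        for b in "ACGT":
            counts[b] += s.count(b)
    total = sum(counts.values())
    return {b: counts[b] / total for b in "ACGT"}


def pairwise_distance(aln: AlignmentSet, model: str = "MCL-composite") -> pd.DataFrame:
    """Symmetric distance matrix under ``model`` (see DISTANCE_MODELS).

    For "MCL-composite" the transition/transversion partition and base
    frequencies are estimated once from substitution counts pooled over all
    pairs, and the TN93 closed form is then applied to each pair with its
    observed total difference split in the pooled proportions.  Saturated
    pairs (log argument <= 0) are NaN.
    """
    if model not in DISTANCE_MODELS:
        raise AlignmentError(f"unknown distance model {model!r}")
    if aln.n_taxa < 2:
        raise AlignmentError("need at least 2 taxa")
    n = aln.n_taxa
    mat = np.zeros((n, n))
    pairs = list(itertools.combinations(range(n), 2))

    if model == "MCL-composite":
        freqs = _base_freqs(aln.sequences)
        tot = np.zeros(3)
        for i, j in pairs:
            p1, p2, q, comp = _pair_partition(aln.sequences[i], aln.sequences[j])
            if comp:
                tot += (p1, p2, q)
        share = tot / tot.sum() if tot.sum() > 0 else np.array([0.25, 0.25, 0.5])

    for i, j in pairs:
        s1, s2 = aln.sequences[i], aln.sequences[j]
        p1, p2, q, comp = _pair_partition(s1, s2)
        if comp == 0:
            d = math.nan
        else:
            p = (p1 + p2 + q) / comp
            if model == "p":
                d = p
            elif model == "JC69":
                d = _jc69(p)
            elif model == "K2P":
                d = _k2p((p1 + p2) / comp, q / comp)
            elif model == "TN93":
                d = _tn93(p1 / comp, p2 / comp, q / comp, _base_freqs([s1, s2]))
            else:  # MCL-composite: pooled rates, per-pair total divergence
                d = _tn93(p * share[0], p * share[1], p * share[2], freqs)
        mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=aln.taxa, columns=aln.taxa)


def mean_pairwise(matrix: pd.DataFrame, *, skip_saturated: bool = True) -> float:
    """Mean of the upper triangle; NaN entries (saturated pairs) skipped or,
    if ``skip_saturated`` is False, propagated."""
    vals = matrix.values[np.triu_indices(len(matrix), k=1)]
    return float(np.nanmean(vals)) if skip_saturated else float(np.mean(vals))


# ---------------------------------------------------------------------------
# NG86 Ka/Ks
# ---------------------------------------------------------------------------

class CodingSequenceError(ValueError):
    pass


@dataclass(frozen=True)
class KaKsResult:
    ka: float
    ks: float
    ratio: float | None  # None when Ks == 0 (undefined)
    s_sites: float
    n_sites: float
    s_diffs: float
    n_diffs: float


def _codon_sites(codon: str, code: dict[str, str]) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) site counts for one codon.

    At each position the three possible changes are classified; changes to
    stop codons are excluded from the denominator, so the two fractions at
    a position always sum to 1 and S + N = 3 per codon.
    """
    s = 0.0
    aa = code[codon]
    for pos in range(3):
        syn = tot = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt not in code:  # stop codon
                continue
            tot += 1
            if code[alt] == aa:
                syn += 1
        if tot:
            s += syn / tot
    return s, 3.0 - s


def _pathway_diffs(c1: str, c2: str, code: dict[str, str]) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons, averaged
    with equal weight over all minimal mutational pathways that avoid stop
    codons."""
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(positions):
        cur = c1
        sd = nd = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt not in code:
                ok = False
                break
            if code[nxt] == code[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            results.append((sd, nd))
    if not results:
        # every pathway passes through a stop; count all steps nonsynonymous
        return 0.0, float(len(positions))
    arr = np.array(results, dtype=float)
    return float(arr[:, 0].mean()), float(arr[:, 1].mean())


def ng86_kaks(seq1: str, seq2: str, table_id: int = 5) -> KaKsResult:
    """Nei-Gojobori (1986) Ka/Ks for one aligned coding-sequence pair.

    Both sequences are read in frame 0; codons with gaps or N in either
    sequence are skipped; a terminal stop codon is dropped; an internal
    stop raises :class:`CodingSequenceError` naming the codon.  pN and pS
    are Jukes-Cantor corrected; the ratio is None when Ks = 0.
    """
    if len(seq1) != len(seq2):
        raise AlignmentError("sequences must be aligned (equal length)")
    code = genetic_code(table_id)
    stops = set(CodonTable.unambiguous_dna_by_id[table_id].stop_codons)
    seq1, seq2 = seq1.upper(), seq2.upper()
    L = len(seq1) - len(seq1) % 3
    n_codons = L // 3
    S = N = Sd = Nd = 0.0
    for idx in range(n_codons):
        c1, c2 = seq1[idx * 3 : idx * 3 + 3], seq2[idx * 3 : idx * 3 + 3]
        if c1 in stops or c2 in stops:
            if idx == n_codons - 1:
                continue  # annotated terminal stop
            raise CodingSequenceError(f"stop codon in frame at codon {idx + 1}")
        if not (set(c1) <= _GOOD and set(c2) <= _GOOD):
            continue
        s1, n1 = _codon_sites(c1, code)
        s2, n2 = _codon_sites(c2, code)
        S += (s1 + s2) / 2.0
        N += (n1 + n2) / 2.0
        sd, nd = _pathway_diffs(c1, c2, code)
        Sd += sd
        Nd += nd
    pS = Sd / S if S else math.nan
    pN = Nd / N if N else math.nan
    ks, ka = _jc69(pS), _jc69(pN)
    ratio = None if (ks != ks or ks == 0.0) else ka / ks
    return KaKsResult(ka=ka, ks=ks, ratio=ratio, s_sites=S, n_sites=N,
                      s_diffs=Sd, n_diffs=Nd)


def kaks_matrix(aln: AlignmentSet, table_id: int = 5) -> pd.DataFrame:
    """Long-form Ka/Ks table over all unordered taxon pairs of one gene."""
    rows = []
    for i, j in itertools.combinations(range(aln.n_taxa), 2):
        res = ng86_kaks(aln.sequences[i], aln.sequences[j], table_id)
        rows.append({"gene": aln.gene, "taxon1": aln.taxa[i],
                     "taxon2": aln.taxa[j], "Ka": res.ka, "Ks": res.ks,
                     "KaKs": math.nan if res.ratio is None else res.ratio})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(matrix: pd.DataFrame) -> str:
    """Neighbor-joining tree (Newick text) from a symmetric distance matrix.

    Negative branch lengths are clamped to 0; Q-criterion ties break
    deterministically by taxon-label order.
    """
    d = matrix.values.astype(float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, equal_nan=True):
        raise AlignmentError("distance matrix must be square and symmetric")
    labels = [str(t) for t in matrix.index]
    nodes = list(labels)
    dist = {(a, b): d[i, j] for i, a in enumerate(labels) for j, b in enumerate(labels)}

    def get(a, b):
        return dist[(a, b)] if a != b else 0.0

    newick = {t: t for t in nodes}
    while len(nodes) > 2:
        r = len(nodes)
        net = {t: sum(get(t, u) for u in nodes) for t in nodes}
        best = None
        for a, b in itertools.combinations(sorted(nodes), 2):
            q = (r - 2) * get(a, b) - net[a] - net[b]
            if best is None or q < best[0] - 1e-12:
                best = (q, a, b)
        _, a, b = best
        va = 0.5 * get(a, b) + (net[a] - net[b]) / (2 * (r - 2))
        vb = get(a, b) - va
        va, vb = max(va, 0.0), max(vb, 0.0)
        new = f"({newick[a]}:{va:.6f},{newick[b]}:{vb:.6f})"
        nodes = [t for t in nodes if t not in (a, b)]
        for t in nodes:
            dt = 0.5 * (get(a, t) + get(b, t) - get(a, b))
            dist[(new, t)] = dist[(t, new)] = max(dt, 0.0)
        newick[new] = new
        nodes.append(new)
    if len(nodes) == 1:
        return f"{newick[nodes[0]]};"
    a, b = sorted(nodes)
    d_ab = max(get(a, b), 0.0)
    if newick[a].startswith("(") or newick[b].startswith("("):
        comp, other = (a, b) if newick[a].startswith("(") else (b, a)
        return f"({newick[comp][1:-1]},{newick[other]}:{d_ab:.6f});"
    return f"({newick[a]}:{d_ab / 2:.6f},{newick[b]}:{d_ab / 2:.6f});"


def write_phylip(matrix: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(matrix)}\n")
        for name, row in matrix.iterrows():
            fh.write(f"{str(name)[:10]:<12s}" +
                     " ".join(f"{v:.6f}" for v in row.values) + "\n")
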