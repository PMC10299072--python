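"""Gene-order extraction, rearrangement detection and TDRL event bounds.

Mitochondrial gene rearrangements in spiders are thought to arise by
tandem duplication followed by random loss (TDRL): a block of genes is
duplicated in tandem and one copy of each gene is subsequently lost.  A
TDRL event can change gene positions but never gene orientation.  The
survivors of the first copy (in order) are followed by the survivors of
the second copy (in order), so one event applied to a sequence with r
ascending runs yields at most 2r runs, and an order whose permutation has
r maximal ascending runs (relative to the reference, over the best
circular relinearization) needs exactly ceil(log2 r) events.  In
particular a single event can produce exactly the permutations with at
most one descent inside the duplicated window.

Orders are signed circular sequences of the 37 genes plus the control
region, linearized at a configurable anchor (default cox1).  Rearrangement
calls against a reference order are derived from the longest common
circular subsequence; a moved block of tRNAs that does not cross a PCG or
rRNA is a local "shuffle", one that does is a "translocation", a moved
PCG/rRNA is a "PCG-move", and any strand flip is an "inversion" (which no
number of TDRL events can explain).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Literal

from .genome_io import AnnotatedMitogenome

Kind = Literal["tRNA-shuffle", "tRNA-translocation", "PCG-move", "inversion"]


class GeneOrderError(ValueError):
    pass


@dataclass(frozen=True)
class GeneOrderPermutation:
    """Signed circular order of genes: (name, strand) pairs plus provenance."""

    genes: tuple[tuple[str, str], ...]
    genome_id: str = ""

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.genes)

    def rotated(self, k: int) -> "GeneOrderPermutation":
        k %= len(self.genes)
        return GeneOrderPermutation(self.genes[k:] + self.genes[:k], self.genome_id)

    def rotated_to(self, anchor: str) -> "GeneOrderPermutation":
        try:
            k = self.names.index(anchor)
        except ValueError as exc:
            raise GeneOrderError(f"anchor gene {anchor!r} not in order") from exc
        return self.rotated(k)

    def circular_equal(self, other: "GeneOrderPermutation") -> bool:
        if len(self.genes) != len(other.genes):
            return False
        return any(self.rotated(k).genes == other.genes
                   for k in range(len(self.genes)))


@dataclass(frozen=True)
class RearrangementCall:
    """One moved block relative to the reference order."""

    moved_genes: tuple[str, ...]
    source_flanks: tuple[str, str]   # neighbors in the reference
    dest_flanks: tuple[str, str]     # neighbors in the observed order
    kind: Kind
    tdrl_events: int | None          # None = not TDRL-explainable (inversion)


def load_reference_order() -> GeneOrderPermutation:
    """The packaged common jumping-spider gene order (linearized at cox1)."""
    text = (resources.files("mitocomp") / "data" / "reference_order.tsv").read_text()
    genes = []
    for line in text.splitlines()[1:]:
        if line.strip():
            name, _ftype, strand = line.split("\t")
            genes.append((name, strand))
    return GeneOrderPermutation(tuple(genes), "reference")


def extract_gene_order(genome: AnnotatedMitogenome, anchor: str = "cox1") -> GeneOrderPermutation:
    """Gene order read along the J strand, rotated to start at ``anchor``."""
    feats = sorted(genome.features, key=lambda f: f.start)
    order = GeneOrderPermutation(tuple((f.name, f.strand) for f in feats),
                                 genome.identifier)
    return order.rotated_to(anchor)


# ---------------------------------------------------------------------------
# TDRL event bound
# ---------------------------------------------------------------------------

def _ascending_runs(seq: list[int]) -> int:
    """Number of maximal ascending runs (descent count + 1)."""
    return 1 + sum(seq[i] > seq[i + 1] for i in range(len(seq) - 1))


def _min_circular_runs(perm: list[int], stop_at: int = 1) -> int:
    """Minimal ascending-run count over all relinearizations of a circular
    permutation.

    Both the cut point of the observed sequence and the cut point of the
    reference numbering are free; a TDRL event acts on the circle, so the
    bound must not depend on where either circle was opened.  Search stops
    early once ``stop_at`` is reached (the bound cannot improve past it).
    """
    n = len(perm)
    best = n
    for a in range(n):
        rot = perm[a:] + perm[:a]
        for b in range(n):
            best = min(best, _ascending_runs([(v - b) % n for v in rot]))
            if best <= stop_at:
                return best
    return best


def tdrl_event_bound(order: GeneOrderPermutation,
                     reference: GeneOrderPermutation) -> int | None:
    """Minimal number of TDRL events separating two circular gene orders.

    Returns None when any gene changed strand (TDRL cannot invert genes).
    The control region is excluded from the permutation.  The bound is
    ceil(log2 r) with r the minimal number of maximal ascending runs over
    circular relinearizations; r <= 2 iff a single event suffices (it is
    then a window split into two ordered survivor sets), and each further
    event can at most double the run count.
    """
    ref = [(g, s) for g, s in reference.genes if g != "CR"]
    obs = [(g, s) for g, s in order.genes if g != "CR"]
    ref_names = [g for g, _ in ref]
    if sorted(g for g, _ in obs) != sorted(ref_names):
        raise GeneOrderError("gene sets differ; cannot compare orders")
    strands = dict(ref)
    if any(strands[g] != s for g, s in obs):
        return None
    index = {g: i for i, (g, _) in enumerate(ref)}
    perm = [index[g] for g, _ in obs]
    n = len(perm)
    if any(perm[a:] + perm[:a] == list(range(n)) for a in range(n)):
        return 0  # circularly identical
    r = _min_circular_runs(perm, stop_at=2)
    return math.ceil(math.log2(r))


# ---------------------------------------------------------------------------
# rearrangement calls
# ---------------------------------------------------------------------------

def _lcs_keep(a: list[str], b: list[str]) -> list[str]:
    """Elements of one longest common subsequence of a and b (deterministic)."""
    n, m = len(a), len(b)
    dp = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n - 1, -1, -1):
        for j in range(m - 1, -1, -1):
            dp[i][j] = (dp[i + 1][j + 1] + 1 if a[i] == b[j]
                        else max(dp[i + 1][j], dp[i][j + 1]))
    keep, i, j = [], 0, 0
    while i < n and j < m:
        if a[i] == b[j] and dp[i][j] == dp[i + 1][j + 1] + 1:
            keep.append(a[i])
            i += 1
            j += 1
        elif dp[i + 1][j] >= dp[i][j + 1]:
            i += 1
        else:
            j += 1
    return keep


def _blocks(moved: set[str], observed: list[str]) -> list[list[str]]:
    """Group moved genes into maximal runs consecutive in the observed order."""
    blocks, cur = [], []
    for g in observed:
        if g in moved:
            cur.append(g)
        elif cur:
            blocks.append(cur)
            cur = []
    if cur:
        blocks.append(cur)
    return blocks


def compare_orders(order: GeneOrderPermutation,
                   reference: GeneOrderPermutation) -> list[RearrangementCall]:
    """Rearrangement calls for ``order`` against ``reference``.

    Empty when the signed circular orders are equal.  Moved blocks are the
    genes excluded from the best longest common circular subsequence,
    grouped by adjacency in the observed order; each block is classified
    and given a per-block TDRL event bound (the bound for applying that
    block's move alone to the reference).
    """
    set_o, set_r = set(order.names), set(reference.names)
    if set_o != set_r:
        raise GeneOrderError(
            f"gene sets differ: only in order={sorted(set_o - set_r)}, "
            f"only in reference={sorted(set_r - set_o)}")
    if order.circular_equal(reference):
        return []

    ref_names = list(reference.names)
    best_keep: list[str] = []
    best_rot = order
    for k in range(len(order.genes)):
        rot = order.rotated(k)
        keep = _lcs_keep(list(rot.names), ref_names)
        if len(keep) > len(best_keep):
            best_keep, best_rot = keep, rot
    obs_names = list(best_rot.names)
    moved = set(obs_names) - set(best_keep)
    ref_strand = dict(reference.genes)
    obs_strand = dict(best_rot.genes)
    ref_idx = {g: i for i, g in enumerate(ref_names)}
    n_ref = len(ref_names)

    calls = []
    for block in _blocks(moved, obs_names):
        i0 = obs_names.index(block[0])
        i1 = obs_names.index(block[-1])
        dest = (obs_names[(i0 - 1) % len(obs_names)],
                obs_names[(i1 + 1) % len(obs_names)])
        src_lo = min(ref_idx[g] for g in block)
        src_hi = max(ref_idx[g] for g in block)
        source = (ref_names[(src_lo - 1) % n_ref], ref_names[(src_hi + 1) % n_ref])

        flipped = any(obs_strand[g] != ref_strand[g] for g in block)
        types = {(_gene_type(g)) for g in block}
        if flipped:
            kind: Kind = "inversion"
        elif types & {"PCG", "rRNA"}:
            kind = "PCG-move"
        else:
            crossed = _crossed_genes(block, dest, ref_idx, ref_names)
            kind = ("tRNA-translocation"
                    if any(_gene_type(g) in ("PCG", "rRNA") for g in crossed)
                    else "tRNA-shuffle")
        events = None
        if not flipped:
            events = tdrl_event_bound(_apply_single_move(reference, block, dest),
                                      reference)
        calls.append(RearrangementCall(
            moved_genes=tuple(block), source_flanks=source, dest_flanks=dest,
            kind=kind, tdrl_events=events))

    # genes inverted in place (strand flip without a positional move)
    in_calls = {g for c in calls for g in c.moved_genes}
    flipped_only = {g for g in obs_names
                    if obs_strand[g] != ref_strand[g] and g not in in_calls}
    for block in _blocks(flipped_only, obs_names):
        i0 = obs_names.index(block[0])
        i1 = obs_names.index(block[-1])
        dest = (obs_names[(i0 - 1) % len(obs_names)],
                obs_names[(i1 + 1) % len(obs_names)])
        src_lo = min(ref_idx[g] for g in block)
        src_hi = max(ref_idx[g] for g in block)
        calls.append(RearrangementCall(
            moved_genes=tuple(block),
            source_flanks=(ref_names[(src_lo - 1) % n_ref],
                           ref_names[(src_hi + 1) % n_ref]),
            dest_flanks=dest, kind="inversion", tdrl_events=None))
    return calls


def _gene_type(name: str) -> str:
    from .genome_io import PCG_NAMES, RRNA_NAMES

    if name in PCG_NAMES:
        return "PCG"
    if name in RRNA_NAMES:
        return "rRNA"
    if name == "CR":
        return "CR"
    return "tRNA"


def _crossed_genes(block: list[str], dest: tuple[str, str],
                   ref_idx: dict[str, int], ref_names: list[str]) -> list[str]:
    """Genes the block passed over: those strictly between its reference
    position and its destination gap, along the shorter arc."""
    n = len(ref_names)
    src_lo = min(ref_idx[g] for g in block)
    src_hi = max(ref_idx[g] for g in block)
    d_prev = ref_idx.get(dest[0], src_lo)
    in_block = set(block)
    # arc going forward from the block to the gap after dest[0], and the
    # arc going backward; the move crossed the genes on the shorter arc
    fwd = [ref_names[i % n] for i in range(src_hi + 1, src_hi + 1 + ((d_prev - src_hi) % n))]
    bwd = [ref_names[i % n] for i in range(d_prev + 1, d_prev + 1 + ((src_lo - d_prev - 1) % n))]
    fwd = [g for g in fwd if g not in in_block]
    bwd = [g for g in bwd if g not in in_block]
    return fwd if len(fwd) <= len(bwd) else bwd


def _apply_single_move(reference: GeneOrderPermutation, block: list[str],
                       dest: tuple[str, str]) -> GeneOrderPermutation:
    """Reference order with only this block relocated to its destination gap."""
    strand = dict(reference.genes)
    remaining = [g for g in reference.names if g not in set(block)]
    try:
        at = remaining.index(dest[0]) + 1
    except ValueError:
        at = len(remaining)
    new_names = remaining[:at] + list(block) + remaining[at:]
    return GeneOrderPermutation(tuple((g, strand[g]) for g in new_names),
                                reference.genome_id + "+move")


def format_order_alignment(order: GeneOrderPermutation,
                           reference: GeneOrderPermutation) -> str:
    """Two-row text diagram of an order against the reference; moved genes
    are bracketed in the observed row."""
    calls = compare_orders(order, reference)
    moved = {g for c in calls for g in c.moved_genes}
    obs = order.rotated_to(reference.names[0]) if reference.names[0] in order.names else order
    top = " ".join(reference.names)
    bottom = " ".join(f"[{g}]" if g in moved else g for g in obs.names)
    return f"ref: {top}\nobs: {bottom}\n"
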