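"""Synthetic annotated mitogenomes with known, tunable parameters.

Every analysis in this package can be exercised without downloads: the
generator emits a circular annotated genome with the structure of a
jumping-spider mitogenome — 13 PCGs (9 on the J strand, 4 on the N
strand), 22 tRNAs, 2 rRNAs and a control region between trnQ and trnM —
whose statistical properties are set by an explicit spec:

* full-genome base composition (AT content, AT skew, GC skew on the J
  strand), hit by generating the non-coding regions from an exact base
  multiset that compensates the realized composition of the coding genes;
* codon usage with a tunable third-position GC (GC3) and a usage
  concentration exponent that controls the effective number of codons;
  first/second-position GC (GC12) can be targeted independently, which is
  what couples GC12 to GC3 across a generated genome set and gives the
  neutrality plot a known slope;
* gene order equal to the packaged reference transformed by an explicit
  list of TDRL events;
* a control-region tandem repeat with chosen motif period, copy number and
  partial copies;
* divergence of a genome set under a codon model with target Ka/Ks ratio
  omega (imposed by acceptance/rejection of proposed nonsynonymous
  changes) and transition/transversion preference kappa.

Defaults mirror the composition and structure reported for salticid
mitogenomes: AT content 0.73, AT skew -0.15, GC skew 0.36, GC3 0.15.
All randomness flows from a single integer seed; a fixed spec and seed
give byte-identical GenBank output.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np

from .codon_usage import genetic_code, synonymous_families
from .gene_order import GeneOrderPermutation, load_reference_order
from .genome_io import (
    PCG_NAMES,
    AnnotatedMitogenome,
    GeneFeature,
    extract_gene_sequence,
    reverse_complement,
)

# typical salticid-like gene sizes; PCG values are sense-codon counts
# (start codon included, stop excluded)
PCG_CODONS = {
    "atp6": 221, "atp8": 52, "cox1": 514, "cox2": 227, "cox3": 261,
    "cytb": 366, "nad1": 311, "nad2": 336, "nad3": 116, "nad4": 445,
    "nad4L": 93, "nad5": 533, "nad6": 154,
}
RRNA_LENGTHS = {"rrnL": 1050, "rrnS": 690}
TRNA_LENGTH_RANGE = (62, 70)

# AT-rich amino-acid profile typical of arthropod mitochondria (Leu/Ile/
# Met/Phe-heavy), and a GC-rich counter-profile used to steer GC12
_AA_PROFILE_AT = {
    "L": 0.17, "I": 0.12, "M": 0.065, "F": 0.11, "S": 0.08, "N": 0.055,
    "K": 0.055, "Y": 0.04, "G": 0.03, "V": 0.04, "T": 0.04, "A": 0.03,
    "P": 0.025, "W": 0.02, "E": 0.03, "D": 0.03, "Q": 0.015, "H": 0.015,
    "R": 0.01, "C": 0.01,
}
_AA_PROFILE_GC = {
    "L": 0.06, "I": 0.03, "M": 0.03, "F": 0.03, "S": 0.08, "N": 0.02,
    "K": 0.02, "Y": 0.02, "G": 0.14, "V": 0.08, "T": 0.08, "A": 0.16,
    "P": 0.12, "W": 0.02, "E": 0.02, "D": 0.02, "Q": 0.02, "H": 0.02,
    "R": 0.12, "C": 0.01,
}
# normalized so the GC12 expectation is exactly linear in the profile mix
_AA_PROFILE_AT = {k: v / sum(_AA_PROFILE_AT.values())
                  for k, v in _AA_PROFILE_AT.items()}
_AA_PROFILE_GC = {k: v / sum(_AA_PROFILE_GC.values())
                  for k, v in _AA_PROFILE_GC.items()}

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


class SyntheticSpecError(ValueError):
    pass


@dataclass(frozen=True)
class TdrlEvent:
    """One tandem-duplication-random-loss event on a reference window.

    The genes at reference-order positions ``[start, end)`` are duplicated
    in tandem; ``keep_first[i]`` says whether gene i of the window survives
    in the first copy (True) or the second (False).  The result within the
    window is the kept-first genes in order followed by the kept-second
    genes in order.
    """

    start: int
    end: int
    keep_first: tuple[bool, ...]

    def apply(self, order: GeneOrderPermutation) -> GeneOrderPermutation:
        if self.end - self.start != len(self.keep_first):
            raise SyntheticSpecError("keep_first length must match the window")
        genes = list(order.genes)
        window = genes[self.start : self.end]
        first = [g for g, k in zip(window, self.keep_first) if k]
        second = [g for g, k in zip(window, self.keep_first) if not k]
        return GeneOrderPermutation(
            tuple(genes[: self.start] + first + second + genes[self.end :]),
            order.genome_id,
        )


@dataclass(frozen=True)
class RepeatSpec:
    """Control-region tandem array: period, full copies and partials."""

    period: int = 24
    full_copies: int = 5
    lead_partial: int = 22
    trail_partial: int = 9
    motif: str | None = None  # random AT-rich motif when None

    @property
    def array_length(self) -> int:
        return self.lead_partial + self.full_copies * self.period + self.trail_partial


@dataclass(frozen=True)
class DivergenceSpec:
    """Codon-model divergence of a genome set.

    ``branch_length`` is the expected number of accepted substitutions per
    nucleotide site from the root to each tip (star tree).
    """

    n_taxa: int = 13
    branch_length: float = 0.08
    omega: float = 0.1
    kappa: float = 2.0

    def __post_init__(self) -> None:
        if self.omega < 0:
            raise SyntheticSpecError("omega must be >= 0")
        if self.branch_length < 0:
            raise SyntheticSpecError("branch_length must be >= 0")


@dataclass(frozen=True)
class SyntheticSpec:
    """Full parameterization of one synthetic mitogenome."""

    seed: int = 0
    identifier: str = "SYN0001"
    taxon: str = "Synthetus exemplaris"
    at_content: float = 0.73
    at_skew: float = -0.15
    gc_skew: float = 0.36
    gc3: float = 0.15
    gc12: float | None = None       # steer GC12 via amino-acid profile mix
    usage_concentration: float = 1.0
    cr_length: int = 800
    tdrl_events: tuple[TdrlEvent, ...] = ()
    repeat: RepeatSpec | None = RepeatSpec()
    truncated_stops: dict = field(
        default_factory=lambda: {"cox2": "T", "cox3": "T", "nad5": "T", "nad6": "TA"}
    )
    divergence: DivergenceSpec = DivergenceSpec()

    def __post_init__(self) -> None:
        for name, v in (("at_content", self.at_content), ("gc3", self.gc3)):
            if not 0.0 <= v <= 1.0:
                raise SyntheticSpecError(f"{name} must lie in [0, 1]")
        for name, v in (("at_skew", self.at_skew), ("gc_skew", self.gc_skew)):
            if not -1.0 <= v <= 1.0:
                raise SyntheticSpecError(f"{name} must lie in [-1, 1]")
        if self.repeat is not None and self.repeat.array_length > self.cr_length - 40:
            raise SyntheticSpecError("repeat array does not fit in the control region")


# ---------------------------------------------------------------------------
# codon distribution with target GC3 / GC12 / concentration
# ---------------------------------------------------------------------------

_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


def _third_base_targets(gc3: float, at_skew: float, gc_skew: float) -> dict[str, float]:
    """Target third-position base fractions on the J strand."""
    at = 1.0 - gc3
    return {"A": at * (1 + at_skew) / 2, "T": at * (1 - at_skew) / 2,
            "G": gc3 * (1 + gc_skew) / 2, "C": gc3 * (1 - gc_skew) / 2}


def _family_codon_weights(gc3: float, concentration: float, at_skew: float,
                          gc_skew: float, strand: str,
                          table_id: int = 5) -> dict[str, np.ndarray]:
    """Within-family codon probabilities.

    Third positions follow the J-strand target composition (GC3 plus the
    strand skews): genes read on the N strand use complemented weights so
    both strands present the same J-side composition, emulating
    strand-asymmetric mutation pressure.  The concentration exponent
    sharpens the within-family preference (higher -> lower ENC).
    """
    targets = _third_base_targets(gc3, at_skew, gc_skew)
    out = {}
    for aa, codons in synonymous_families(table_id).items():
        w = np.array([
            np.prod([targets[b] if strand == "J" else targets[_COMP[b]]
                     for b in c])
            for c in codons
        ])
        w = w ** concentration
        out[aa] = w / w.sum()
    return out


def _mixed_profile(lam: float) -> dict[str, float]:
    return {aa: (1 - lam) * _AA_PROFILE_AT[aa] + lam * _AA_PROFILE_GC[aa]
            for aa in _AA_PROFILE_AT}


def _codon_distribution(profile: dict[str, float], gc3: float,
                        concentration: float, strand: str = "J",
                        at_skew: float = 0.0, gc_skew: float = 0.0,
                        table_id: int = 5) -> dict[str, float]:
    total = sum(profile.values())
    weights = _family_codon_weights(gc3, concentration, at_skew, gc_skew,
                                    strand, table_id)
    dist = {}
    for aa, codons in synonymous_families(table_id).items():
        p_aa = profile.get(aa, 0.0) / total
        for c, w in zip(codons, weights[aa]):
            dist[c] = p_aa * w
    return dist


def _strand_codon_weights() -> tuple[float, float]:
    """Fractions of PCG codons encoded on the J and N strands."""
    strands = dict(load_reference_order().genes)
    j = sum(n for g, n in PCG_CODONS.items() if strands[g] == "J")
    n = sum(n for g, n in PCG_CODONS.items() if strands[g] == "N")
    return j / (j + n), n / (j + n)


def pooled_codon_distribution(profile: dict[str, float], gc3: float,
                              concentration: float, at_skew: float,
                              gc_skew: float, table_id: int = 5) -> dict[str, float]:
    """Expected codon distribution pooled over all 13 PCGs (both strands),
    as seen by reading-orientation codon-usage statistics."""
    wj, wn = _strand_codon_weights()
    dj = _codon_distribution(profile, gc3, concentration, "J", at_skew, gc_skew, table_id)
    dn = _codon_distribution(profile, gc3, concentration, "N", at_skew, gc_skew, table_id)
    return {c: wj * dj[c] + wn * dn[c] for c in dj}


def expected_positional_gc(dist: dict[str, float]) -> tuple[float, float, float]:
    gc = [0.0, 0.0, 0.0]
    for codon, p in dist.items():
        for pos in range(3):
            if codon[pos] in "GC":
                gc[pos] += p
    return tuple(gc)  # type: ignore[return-value]


def expected_enc(dist: dict[str, float], table_id: int = 5) -> float:
    """Large-sample ENC implied by a codon distribution (F -> sum p^2)."""
    fams = synonymous_families(table_id)
    f_by_size: dict[int, list[float]] = {}
    n_by_size: dict[int, int] = {}
    for aa, codons in fams.items():
        k = len(codons)
        n_by_size[k] = n_by_size.get(k, 0) + 1
        tot = sum(dist[c] for c in codons)
        if tot > 0:
            f = sum((dist[c] / tot) ** 2 for c in codons)
            f_by_size.setdefault(k, []).append(f)
    return sum(n_k / float(np.mean(f_by_size[k])) for k, n_k in n_by_size.items())


def profile_for_gc12(gc3: float, concentration: float, gc12_target: float,
                     at_skew: float = 0.0, gc_skew: float = 0.0,
                     table_id: int = 5) -> dict[str, float]:
    """Amino-acid profile (a mix of the AT- and GC-rich profiles) whose
    expected pooled GC12 equals ``gc12_target`` at the given GC3 and
    concentration.

    Expected GC12 is linear in the mixing coefficient, so the solve is
    exact; targets outside the two profiles' range raise."""
    e0 = _expected_gc12(pooled_codon_distribution(
        _AA_PROFILE_AT, gc3, concentration, at_skew, gc_skew, table_id))
    e1 = _expected_gc12(pooled_codon_distribution(
        _AA_PROFILE_GC, gc3, concentration, at_skew, gc_skew, table_id))
    lam = (gc12_target - e0) / (e1 - e0)
    if not 0.0 <= lam <= 1.0:
        raise SyntheticSpecError(
            f"GC12 target {gc12_target:.3f} outside achievable range "
            f"[{min(e0, e1):.3f}, {max(e0, e1):.3f}]")
    return _mixed_profile(lam)


def _expected_gc12(dist: dict[str, float]) -> float:
    g1, g2, _ = expected_positional_gc(dist)
    return (g1 + g2) / 2.0


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------

_STARTS = ("ATG", "ATA", "ATT", "TTG")


def _sample_cds(name: str, n_codons: int, dist: dict[str, float],
                rng: np.random.Generator, stop: str) -> str:
    codons = list(dist.keys())
    probs = np.array(list(dist.values()))
    probs = probs / probs.sum()
    body = rng.choice(len(codons), size=n_codons - 1, p=probs)
    start = _STARTS[rng.integers(len(_STARTS))]
    return start + "".join(codons[i] for i in body) + stop


def _base_counts(seq: str) -> np.ndarray:
    return np.array([seq.count(b) for b in "ACGT"], dtype=float)


def _exact_multiset(needed: np.ndarray, length: int, rng: np.random.Generator) -> list[str]:
    """A shuffled base list of ``length`` with counts as close as possible
    to the (possibly fractional) ``needed`` counts."""
    needed = np.maximum(needed, 0.0)
    needed = needed / needed.sum() * length
    counts = np.floor(needed).astype(int)
    rem = length - counts.sum()
    order = np.argsort(-(needed - counts))
    for i in range(rem):
        counts[order[i % 4]] += 1
    bases = [b for b, c in zip("ACGT", counts) for _ in range(c)]
    perm = rng.permutation(length)
    return [bases[i] for i in perm]


def generate_mitogenome(spec: SyntheticSpec) -> AnnotatedMitogenome:
    """Generate one annotated circular mitogenome from the spec."""
    rng = np.random.default_rng(spec.seed)
    order = load_reference_order()
    for ev in spec.tdrl_events:
        ev = ev  # events are applied in sequence on the current order
        order = ev.apply(order)

    profile = (_AA_PROFILE_AT if spec.gc12 is None else
               profile_for_gc12(spec.gc3, spec.usage_concentration, spec.gc12,
                                spec.at_skew, spec.gc_skew))
    strand = dict(order.genes)
    dists = {
        s: _codon_distribution(profile, spec.gc3, spec.usage_concentration,
                               s, spec.at_skew, spec.gc_skew)
        for s in ("J", "N")
    }

    # 1. protein-coding genes (reading orientation)
    cds: dict[str, str] = {}
    for name in sorted(PCG_CODONS):
        stop = spec.truncated_stops.get(name, "TAA")
        cds[name] = _sample_cds(name, PCG_CODONS[name], dists[strand[name]],
                                rng, stop)
    coding_counts = np.zeros(4)
    for name, seq in cds.items():
        placed = reverse_complement(seq) if strand[name] == "N" else seq
        coding_counts += _base_counts(placed)

    # 2. non-coding lengths
    trna_names = [g for g, _ in order.genes if g.startswith("trn")]
    trna_lengths = {name: int(rng.integers(*TRNA_LENGTH_RANGE, endpoint=True))
                    for name in sorted(trna_names)}
    noncoding_total = (sum(trna_lengths.values()) + sum(RRNA_LENGTHS.values())
                       + spec.cr_length)
    total_len = int(coding_counts.sum()) + noncoding_total

    # 3. repeat array (sampled from AT-rich probabilities), then an exact
    #    compensating multiset for everything else non-coding
    at, gc = spec.at_content, 1.0 - spec.at_content
    target = np.array([
        at * (1 + spec.at_skew) / 2, gc * (1 - spec.gc_skew) / 2,
        gc * (1 + spec.gc_skew) / 2, at * (1 - spec.at_skew) / 2,
    ]) * total_len  # A, C, G, T

    array = ""
    if spec.repeat is not None:
        r = spec.repeat
        motif = r.motif
        if motif is None:
            probs = np.maximum(target / target.sum(), 0.02)
            probs /= probs.sum()
            motif = "".join(rng.choice(list("ACGT"), size=r.period, p=probs))
        if len(motif) != r.period:
            raise SyntheticSpecError("motif length must equal the repeat period")
        array = motif[-r.lead_partial:] if r.lead_partial else ""
        array += motif * r.full_copies
        array += motif[: r.trail_partial]

    remaining = noncoding_total - len(array)
    needed = target - coding_counts - _base_counts(array)
    pool = _exact_multiset(needed, remaining, rng)

    def take(n: int) -> str:
        nonlocal pool
        out, pool = pool[:n], pool[n:]
        return "".join(out)

    noncoding: dict[str, str] = {}
    for name in sorted(trna_names):
        noncoding[name] = take(trna_lengths[name])
    for name in sorted(RRNA_LENGTHS):
        noncoding[name] = take(RRNA_LENGTHS[name])

    flank_total = spec.cr_length - len(array)
    lead_flank, tail_flank = take(flank_total // 2), take(flank_total - flank_total // 2)
    if spec.repeat is not None and array:
        r = spec.repeat
        prev_char = motif[(r.period - r.lead_partial - 1) % r.period]
        next_char = motif[r.trail_partial % r.period]
        lead_flank = _break_boundary(lead_flank, -1, prev_char)
        tail_flank = _break_boundary(tail_flank, 0, next_char)
    noncoding["CR"] = lead_flank + array + tail_flank

    # 4. assemble along the gene order
    seq_parts: list[str] = []
    features: list[GeneFeature] = []
    pos = 0
    from .genome_io import RRNA_NAMES, TRNA_NAMES

    for name, s in order.genes:
        if name in PCG_NAMES:
            segment = cds[name] if s == "J" else reverse_complement(cds[name])
            ftype = "PCG"
        else:
            segment = noncoding[name]
            ftype = ("tRNA" if name in TRNA_NAMES
                     else "rRNA" if name in RRNA_NAMES else "CR")
        features.append(GeneFeature(name=name, ftype=ftype, start=pos,
                                    end=pos + len(segment), strand=s))
        seq_parts.append(segment)
        pos += len(segment)

    return AnnotatedMitogenome(
        identifier=spec.identifier, sequence="".join(seq_parts),
        features=features, circular=True, taxon=spec.taxon,
    )


def _break_boundary(flank: str, idx: int, avoid: str) -> str:
    """Make the flank base adjacent to the repeat array differ from the
    perfect-continuation base, so partial copies end where specified."""
    if not flank or flank[idx] != avoid:
        return flank
    alt = "ACGT"[("ACGT".index(avoid) + 1) % 4]
    chars = list(flank)
    chars[idx] = alt
    return "".join(chars)


def generate_genome_grid(seed: int = 0, n: int = 13,
                         gc3_range: tuple[float, float] = (0.06, 0.215),
                         coupling: float = 0.249,
                         intercept: float = 0.273) -> list[AnnotatedMitogenome]:
    """A genome set spanning a GC3 grid with GC12 coupled to GC3.

    Each genome targets GC12 = intercept + coupling * GC3, so the
    neutrality regression fitted to the set has a known generating slope
    (``coupling``).  Defaults span the GC3/GC12 ranges observed in salticid
    mitogenomes.
    """
    genomes = []
    for i, g3 in enumerate(np.linspace(*gc3_range, n)):
        spec = SyntheticSpec(
            seed=seed * 1000 + i, identifier=f"SYNGRID{i:02d}",
            gc3=float(g3), gc12=float(intercept + coupling * g3),
        )
        genomes.append(generate_mitogenome(spec))
    return genomes


# ---------------------------------------------------------------------------
# divergence simulation
# ---------------------------------------------------------------------------

def evolve_codon_sequence(seq: str, t: float, omega: float, kappa: float,
                          rng: np.random.Generator, table_id: int = 5) -> str:
    """Evolve a coding sequence by ``t`` expected accepted substitutions per
    nucleotide site under the acceptance/rejection codon model.

    Proposals pick a uniform site and a kappa-weighted alternative base;
    proposals creating a stop codon are discarded; synonymous proposals are
    accepted at relative rate 1 and nonsynonymous at rate ``omega`` (for
    omega > 1 the synonymous rate is scaled down instead).  The trailing
    incomplete codon, if any, is never touched.
    """
    code = genetic_code(table_id)
    n_codons = len(seq) // 3
    L = n_codons * 3
    if L == 0 or t == 0:
        return seq
    chars = list(seq)
    n_events = rng.poisson(t * L)
    p_syn = min(1.0, 1.0 / omega) if omega > 0 else 1.0
    p_non = min(1.0, omega)
    accepted = 0
    while accepted < n_events:
        site = int(rng.integers(L))
        old = chars[site]
        if old not in "ACGT":
            continue
        probs = np.array([kappa if b == _TRANSITION[old] else 1.0
                          for b in "ACGT" if b != old])
        alts = [b for b in "ACGT" if b != old]
        new = alts[rng.choice(3, p=probs / probs.sum())]
        c0 = site - site % 3
        codon = "".join(chars[c0 : c0 + 3])
        if codon not in code:
            continue
        new_codon = codon[: site % 3] + new + codon[site % 3 + 1 :]
        if new_codon not in code:
            continue  # stop codons are never created
        p_accept = p_syn if code[new_codon] == code[codon] else p_non
        if rng.random() < p_accept:
            chars[site] = new
            accepted += 1
    return "".join(chars)


def evolve_nucleotide_sequence(seq: str, t: float, kappa: float,
                               rng: np.random.Generator) -> str:
    """Evolve a non-coding sequence: ``t`` expected substitutions per site,
    transitions favored by kappa, all proposals accepted."""
    L = len(seq)
    if L == 0 or t == 0:
        return seq
    chars = list(seq)
    for _ in range(rng.poisson(t * L)):
        site = int(rng.integers(L))
        old = chars[site]
        if old not in "ACGT":
            continue
        probs = np.array([kappa if b == _TRANSITION[old] else 1.0
                          for b in "ACGT" if b != old])
        alts = [b for b in "ACGT" if b != old]
        chars[site] = alts[rng.choice(3, p=probs / probs.sum())]
    return "".join(chars)


def evolve_set(root: AnnotatedMitogenome, spec: SyntheticSpec):
    """Evolve a genome set from ``root`` along a star tree.

    Returns ``(genomes, alignments)`` where ``alignments`` maps each PCG
    name to a gap-free codon-aware :class:`~mitocomp.divergence.AlignmentSet`
    over the tips (stop codons and truncated tails excluded).
    """
    from .divergence import AlignmentSet

    div = spec.divergence
    rng = np.random.default_rng(np.random.default_rng(spec.seed).integers(2**31))
    genomes: list[AnnotatedMitogenome] = []
    per_gene: dict[str, list[str]] = {name: [] for name in sorted(PCG_CODONS)}
    taxa: list[str] = []

    for i in range(div.n_taxa):
        label = f"{root.identifier}_t{i + 1:02d}"
        taxa.append(label)
        chars = list(root.sequence)
        for f in root.features:
            segment = extract_gene_sequence(root, f.name)
            if f.ftype == "PCG":
                codon_region = segment[: len(segment) - len(segment) % 3]
                tail = segment[len(codon_region):]
                evolved = evolve_codon_sequence(
                    codon_region, div.branch_length, div.omega, div.kappa, rng
                ) + tail
                n_cod = len(codon_region) // 3
                drop = 3 if codon_region[-3:] in ("TAA", "TAG") else 0
                per_gene[f.name].append(evolved[: n_cod * 3 - drop])
            else:
                evolved = evolve_nucleotide_sequence(
                    segment, div.branch_length, div.kappa, rng)
            placed = reverse_complement(evolved) if f.strand == "N" else evolved
            if f.end <= f.start:  # origin-spanning
                head = len(root.sequence) - f.start
                chars[f.start :] = placed[:head]
                chars[: f.end] = placed[head:]
            else:
                chars[f.start : f.end] = placed
        genomes.append(AnnotatedMitogenome(
            identifier=label, sequence="".join(chars),
            features=list(root.features), circular=True, taxon=root.taxon,
        ))

    alignments = {
        name: AlignmentSet(name, list(taxa), seqs, codon_aware=True)
        for name, seqs in per_gene.items()
    }
    return genomes, alignments
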