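"""Reading, writing and interrogation of annotated mitochondrial genomes.

Animal mitogenomes are small circular molecules (in spiders ~14-15 kb)
carrying 13 protein-coding genes (PCGs), 22 tRNAs, 2 rRNAs and one large
non-coding control region (CR).  Genes sit on both strands: the majority
strand (J) and the minority strand (N).  This module parses GenBank flat
files into a light-weight annotated-genome container, normalizes the
heterogeneous gene names found in public records to canonical symbols,
extracts gene sequences in their own reading orientation on a circular
coordinate system, and validates PCG start/stop codons (mitochondrial stop
codons may be truncated to ``T``/``TA`` and completed by polyadenylation).

Internally all coordinates are 0-based half-open on the linearized J
strand; GenBank's 1-based inclusive convention exists only at the I/O
boundary.  A feature with ``end <= start`` spans the origin of the circle
and is interpreted modulo the genome length.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("mitocomp")

FeatureType = Literal["PCG", "tRNA", "rRNA", "CR"]

PCG_NAMES = frozenset(
    ["atp6", "atp8", "cox1", "cox2", "cox3", "cytb",
     "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6"]
)
TRNA_NAMES = frozenset(
    ["trnA", "trnR", "trnN", "trnD", "trnC", "trnQ", "trnE", "trnG", "trnH",
     "trnI", "trnK", "trnM", "trnF", "trnP", "trnT", "trnW", "trnY", "trnV",
     "trnL1", "trnL2", "trnS1", "trnS2"]
)
RRNA_NAMES = frozenset(["rrnS", "rrnL"])

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_BASES = frozenset("ACGTN")


class MitogenomeError(Exception):
    """Base class for genome I/O problems."""


class FormatError(MitogenomeError):
    """The file could not be parsed as the expected format."""


class AnnotationError(MitogenomeError):
    """The annotation is internally inconsistent (e.g. duplicate genes)."""


class CoordinateError(MitogenomeError):
    """A feature lies outside the sequence bounds."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneFeature:
    """A typed, stranded gene interval on the J strand of a circular genome.

    ``start``/``end`` are 0-based half-open; ``end <= start`` marks an
    origin-spanning feature.  ``strand`` is ``"J"`` (majority) or ``"N"``
    (minority; the gene is read as the reverse complement).
    ``codon_offset`` is the 0..2 reading-frame offset and is nonzero only
    for PCGs (GenBank ``/codon_start`` minus one).
    """

    name: str
    ftype: FeatureType
    start: int
    end: int
    strand: Literal["J", "N"] = "J"
    codon_offset: int = 0

    def length(self, genome_length: int) -> int:
        span = (self.end - self.start) % genome_length
        return span if span else genome_length


@dataclass
class AnnotatedMitogenome:
    """A circular mitogenome: J-strand sequence plus typed gene features."""

    identifier: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)
    circular: bool = True
    taxon: str = ""
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError("empty sequence")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise FormatError(
                f"{self.identifier}: ambiguity codes other than N are not "
                f"supported: {sorted(bad)}"
            )
        seen: set[str] = set()
        for f in self.features:
            if f.name in seen:
                raise AnnotationError(f"duplicate canonical gene name {f.name!r}")
            seen.add(f.name)
            if not (0 <= f.start < len(self.sequence)) or not (
                0 <= f.end <= len(self.sequence)
            ):
                raise CoordinateError(
                    f"feature {f.name} [{f.start}, {f.end}) outside "
                    f"[0, {len(self.sequence)})"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def gene_names(self) -> list[str]:
        return [f.name for f in self.features]

    def feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(f"gene {name!r} not annotated in {self.identifier}")

    def features_of_type(self, ftype: FeatureType) -> list[GeneFeature]:
        return [f for f in self.features if f.ftype == ftype]

    def counts_by_type(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for f in self.features:
            out[f.ftype] = out.get(f.ftype, 0) + 1
        return out


@dataclass(frozen=True)
class CodonValidationRow:
    """Start/stop codon report for one PCG."""

    gene: str
    start_codon: str
    stop_codon: str
    start_class: Literal["canonical-ATN", "canonical-TTN", "unconventional"]
    stop_class: Literal["complete", "truncated-T", "truncated-TA"]


# ---------------------------------------------------------------------------
# gene-name normalization (synonym table is package data)
# ---------------------------------------------------------------------------

def _load_synonyms() -> dict[str, str]:
    text = (resources.files("mitocomp") / "data" / "gene_synonyms.tsv").read_text()
    table: dict[str, str] = {}
    for line in text.splitlines()[1:]:
        if line.strip():
            syn, canon = line.split("\t")
            table[syn] = canon
    return table


_SYNONYMS = _load_synonyms()
CANONICAL_NAMES = PCG_NAMES | TRNA_NAMES | RRNA_NAMES | {"CR"}

# tRNA-Leu/Ser records are ambiguous without an isoform tag; these suffixes
# (anticodon or codon-family qualifiers) resolve them.
_ISOFORM_TAGS = {
    "CUN": {"LEU": "trnL1"}, "UUR": {"LEU": "trnL2"},
    "TAG": {"LEU": "trnL1"}, "TAA": {"LEU": "trnL2"},
    "AGN": {"SER": "trnS1"}, "UCN": {"SER": "trnS2"},
    "TCT": {"SER": "trnS1"}, "TGA": {"SER": "trnS2"},
}


def _norm_key(label: str) -> str:
    return "".join(ch for ch in label.upper() if ch.isalnum())


def canonical_gene_name(label: str, *, anticodon: str | None = None) -> str:
    """Map a free-text gene label to its canonical symbol.

    Raises :class:`AnnotationError` when the label is unknown or an
    ambiguous Leu/Ser tRNA cannot be resolved from ``anticodon``.
    """
    if label in CANONICAL_NAMES:
        return label
    key = _norm_key(label)
    if key in _SYNONYMS:
        return _SYNONYMS[key]
    if key in {"TRNL", "TRNALEU", "TRNS", "TRNASER"}:
        aa = "LEU" if "L" in key[:5] else "SER"
        if anticodon:
            tag = _norm_key(anticodon)
            if tag in _ISOFORM_TAGS and aa in _ISOFORM_TAGS[tag]:
                return _ISOFORM_TAGS[tag][aa]
        raise AnnotationError(
            f"ambiguous tRNA label {label!r}: Leu/Ser isoform cannot be resolved"
        )
    raise AnnotationError(f"unknown gene label {label!r}")


def _ftype_of(name: str) -> FeatureType:
    if name in PCG_NAMES:
        return "PCG"
    if name in TRNA_NAMES:
        return "tRNA"
    if name in RRNA_NAMES:
        return "rRNA"
    return "CR"


# ---------------------------------------------------------------------------
# GenBank parsing
# ---------------------------------------------------------------------------

def _feature_label(feat: SeqFeature) -> str | None:
    for q in ("gene", "product", "note"):
        if q in feat.qualifiers:
            return str(feat.qualifiers[q][0])
    return None


def _location_bounds(feat: SeqFeature, length: int) -> tuple[int, int]:
    """Return internal (start, end) handling origin-spanning joins."""
    loc = feat.location
    if isinstance(loc, CompoundLocation):
        parts = sorted(loc.parts, key=lambda p: int(p.start))
        # an origin-spanning join has one part ending at the terminus and
        # one starting at 0
        if len(parts) == 2 and int(parts[0].start) == 0 and int(parts[1].end) == length:
            return int(parts[1].start), int(parts[0].end)
        raise FormatError(f"unsupported compound location {loc}")
    return int(loc.start), int(loc.end)


def parse_genbank(path: str | Path, *, min_cr_length: int = 100) -> AnnotatedMitogenome:
    """Parse a GenBank flat file into an :class:`AnnotatedMitogenome`.

    Gene names are normalized through the packaged synonym table;
    complement-strand features become N-strand features; when no control
    region is annotated, the unannotated gap between ``trnQ`` and ``trnM``
    is labeled CR (its usual location in jumping-spider mitogenomes).
    A CR shorter than ``min_cr_length`` is flagged, not rejected.
    """
    try:
        record = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # Biopython raises assorted ValueError subclasses
        raise FormatError(f"cannot parse {path} as GenBank: {exc}") from exc

    length = len(record.seq)
    features: list[GeneFeature] = []
    for feat in record.features:
        if feat.type not in {"CDS", "tRNA", "rRNA", "D-loop", "misc_feature"}:
            continue
        label = _feature_label(feat)
        if label is None:
            if feat.type == "D-loop":
                label = "CR"
            else:
                continue
        if feat.type == "misc_feature" and _norm_key(label) not in _SYNONYMS:
            continue
        anticodon = None
        if "anticodon" in feat.qualifiers:
            anticodon = str(feat.qualifiers["anticodon"][0]).split(":")[-1].strip("() ")
        elif "(" in label:
            anticodon = label[label.index("(") + 1 :].strip("() ")
        name = canonical_gene_name(label, anticodon=anticodon)
        start, end = _location_bounds(feat, length)
        if not (0 <= start <= length and 0 <= end <= length):
            raise CoordinateError(f"{name}: location outside sequence bounds")
        offset = 0
        if feat.type == "CDS" and "codon_start" in feat.qualifiers:
            offset = int(feat.qualifiers["codon_start"][0]) - 1
        strand = "N" if feat.location.strand == -1 else "J"
        features.append(
            GeneFeature(name=name, ftype=_ftype_of(name), start=start % length,
                        end=end % length if end != length else length,
                        strand=strand, codon_offset=offset)
        )

    genome = AnnotatedMitogenome(
        identifier=record.id or record.name,
        sequence=str(record.seq),
        features=features,
        circular=record.annotations.get("topology", "circular") == "circular",
        taxon=record.annotations.get("organism", ""),
    )
    _ensure_control_region(genome, min_cr_length)
    genome.features.sort(key=lambda f: f.start)
    return genome


def _ensure_control_region(genome: AnnotatedMitogenome, min_cr_length: int) -> None:
    names = set(genome.gene_names)
    if "CR" not in names and {"trnQ", "trnM"} <= names:
        q, m = genome.feature("trnQ"), genome.feature("trnM")
        L = len(genome)
        gap = (m.start - q.end) % L
        if gap > 0:
            genome.features.append(
                GeneFeature("CR", "CR", q.end % L, m.start, "J")
            )
            logger.warning("W-CR-INFERRED %s: control region inferred from "
                           "trnQ..trnM gap (%d bp)", genome.identifier, gap)
    if "CR" in {f.name for f in genome.features}:
        cr = genome.feature("CR")
        if cr.length(len(genome)) < min_cr_length:
            genome.flags.append("CR-short")
            logger.warning("W-CR-SHORT %s: control region shorter than %d bp",
                           genome.identifier, min_cr_length)
    else:
        genome.flags.append("CR-missing")
        logger.warning("W-CR-MISSING %s: no control region annotated or "
                       "inferable", genome.identifier)


# ---------------------------------------------------------------------------
# GenBank / FASTA / TSV writing
# ---------------------------------------------------------------------------

_GB_TYPES = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "CR": "D-loop"}


def to_seqrecord(genome: AnnotatedMitogenome) -> SeqRecord:
    record = SeqRecord(
        Seq(genome.sequence),
        id=genome.identifier,
        name=genome.identifier[:16].replace(".", "_"),
        description=f"{genome.taxon} mitochondrion".strip(),
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if genome.circular else "linear",
            "data_file_division": "INV",
            "date": "01-JAN-2000",  # fixed for byte-identical output
            "organism": genome.taxon,
        },
    )
    L = len(genome)
    record.features.append(
        SeqFeature(SimpleLocation(0, L, 1), type="source",
                   qualifiers={"organism": [genome.taxon or "synthetic"]})
    )
    for f in sorted(genome.features, key=lambda f: f.start):
        strand = -1 if f.strand == "N" else 1
        if f.end <= f.start:  # origin-spanning
            loc = CompoundLocation(
                [SimpleLocation(f.start, L, strand), SimpleLocation(0, f.end, strand)]
            )
        else:
            loc = SimpleLocation(f.start, f.end, strand)
        quals: dict[str, list[str]] = {"gene": [f.name]}
        if f.ftype == "PCG":
            quals["codon_start"] = [str(f.codon_offset + 1)]
            quals["transl_table"] = ["5"]
        record.features.append(SeqFeature(loc, type=_GB_TYPES[f.ftype], qualifiers=quals))
    return record


def write_genbank(genome: AnnotatedMitogenome, path: str | Path) -> None:
    SeqIO.write([to_seqrecord(genome)], str(path), "genbank")


def write_fasta(genome: AnnotatedMitogenome, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.identifier} {genome.taxon}\n")
        seq = genome.sequence
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")


def feature_table(genome: AnnotatedMitogenome):
    """Feature table as a DataFrame (genome, gene, type, start, end, strand, length)."""
    import pandas as pd

    rows = [
        {"genome": genome.identifier, "gene": f.name, "type": f.ftype,
         "start": f.start, "end": f.end, "strand": f.strand,
         "length": f.length(len(genome))}
        for f in genome.features
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sequence extraction on the circle
# ---------------------------------------------------------------------------

def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _span_sequence(genome: AnnotatedMitogenome, start: int, end: int) -> str:
    if end > start:
        return genome.sequence[start:end]
    return genome.sequence[start:] + genome.sequence[:end]


def extract_gene_sequence(genome: AnnotatedMitogenome, name: str) -> str:
    """Gene sequence in its own reading orientation.

    N-strand features are reverse-complemented; origin-spanning features are
    concatenated across the junction; PCG output starts at ``codon_offset``.
    """
    f = genome.feature(name)
    seq = _span_sequence(genome, f.start, f.end)
    if f.strand == "N":
        seq = reverse_complement(seq)
    if f.ftype == "PCG" and f.codon_offset:
        seq = seq[f.codon_offset :]
    return seq


def rotate_to_anchor(genome: AnnotatedMitogenome, anchor: str = "cox1") -> AnnotatedMitogenome:
    """Relinearize the circle so that ``anchor`` starts at position 0."""
    shift = genome.feature(anchor).start
    if shift == 0:
        return genome
    L = len(genome)
    seq = genome.sequence[shift:] + genome.sequence[:shift]
    feats = [
        replace(f, start=(f.start - shift) % L,
                end=(f.end - shift) % L or L)
        for f in genome.features
    ]
    feats.sort(key=lambda f: f.start)
    return AnnotatedMitogenome(
        identifier=genome.identifier, sequence=seq, features=feats,
        circular=genome.circular, taxon=genome.taxon, flags=list(genome.flags),
    )


# ---------------------------------------------------------------------------
# start/stop codon validation
# ---------------------------------------------------------------------------

def _classify_start(codon: str) -> str:
    if codon.startswith("AT"):
        return "canonical-ATN"
    if codon.startswith("TT"):
        return "canonical-TTN"
    return "unconventional"


def validate_pcg_codons(genome: AnnotatedMitogenome) -> list[CodonValidationRow]:
    """One start/stop codon report row per annotated PCG.

    Stops are classified ``truncated-T``/``truncated-TA`` when the in-frame
    length leaves a 1- or 2-nt remainder (the transcript's stop is completed
    to TAA by polyadenylation); starts outside ATN/TTN are unconventional.
    """
    rows = []
    for f in sorted(genome.features_of_type("PCG"), key=lambda f: f.name):
        seq = extract_gene_sequence(genome, f.name)
        rem = len(seq) % 3
        if rem == 1:
            stop, stop_class = seq[-1:], "truncated-T"
        elif rem == 2:
            stop, stop_class = seq[-2:], "truncated-TA"
        else:
            stop, stop_class = seq[-3:], "complete"
        start = seq[:3]
        rows.append(
            CodonValidationRow(gene=f.name, start_codon=start, stop_codon=stop,
                               start_class=_classify_start(start),
                               stop_class=stop_class)
        )
    return rows
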