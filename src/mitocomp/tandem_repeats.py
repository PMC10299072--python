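"""Tandem-repeat detection in control-region sequences.

Control regions of spider mitogenomes often carry tandem arrays of a short
motif, with variable copy number and incomplete (partial) copies at the
array edges.  The detector scans candidate periods, anchors an array at
the first position where two consecutive period-length windows agree, and
grows it against a rolling column-majority consensus.  Copies are accepted
while their identity to the consensus stays above a threshold; partial
leading/trailing copies are then extended base by base.  Hits are scored
with tandem-repeat-finder-style weights (match +2, mismatch -7) and
overlapping hits are resolved by score, then by smaller period.  A
consensus that is itself a perfect repetition of a shorter motif is
reduced to the smallest consistent period, so a 24-bp repeat is never
reported as its 48-bp harmonic.

The reported phase is anchored at the first full-period match, so a
leading partial copy that happens to be an exact motif suffix is absorbed
into a rotated consensus; partial lengths are positional facts about the
chosen phase, not about any particular motif rotation.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass


class RepeatParameterError(ValueError):
    pass


@dataclass(frozen=True)
class RepeatHit:
    """One tandem array: span, period, fractional copy number, consensus."""

    start: int            # 0-based, includes the leading partial copy
    end: int              # half-open, includes the trailing partial copy
    period: int
    copy_number: float    # aligned span / period
    consensus: str
    identity: float       # fraction of aligned bases matching the consensus
    partial_lengths: tuple[int, int]  # (leading, trailing) incomplete copies
    score: int

    @property
    def span(self) -> int:
        return self.end - self.start


def _consensus(copies: list[str]) -> str:
    out = []
    for column in zip(*copies):
        counts = Counter(column)
        # deterministic tie-break: highest count, then alphabetic base
        out.append(min(counts, key=lambda b: (-counts[b], b)))
    return "".join(out)


def _identity(a: str, b: str) -> float:
    if not a:
        return 0.0
    return sum(x == y for x, y in zip(a, b)) / len(a)


def find_tandem_repeats(seq: str, *, min_period: int = 5,
                        max_period: int | None = None,
                        min_copies: float = 1.9, min_identity: float = 0.8,
                        min_score: int = 50,
                        match: int = 2, mismatch: int = -7) -> list[RepeatHit]:
    """Find tandem arrays of period ``min_period..max_period`` in ``seq``.

    Hits need at least ``min_copies`` period-lengths of aligned span,
    ``min_identity`` agreement with the consensus and an alignment score of
    at least ``min_score`` (the tandem-repeat-finder-style floor that keeps
    chance dinucleotide-scale matches in AT-rich sequence out of the
    report).  Returns hits sorted by start position.
    """
    seq = seq.upper()
    L = len(seq)
    if max_period is None:
        max_period = max(min_period, L // 2)
    if min_period > max_period:
        raise RepeatParameterError("min_period exceeds max_period")
    if min_period < 1:
        raise RepeatParameterError("min_period must be >= 1")

    candidates: list[RepeatHit] = []
    for period in range(min_period, max_period + 1):
        s = 0
        while s + 2 * period <= L:
            first, second = seq[s : s + period], seq[s + period : s + 2 * period]
            if _identity(first, second) >= min_identity:
                hit = _grow_array(seq, s, period, min_identity, match, mismatch)
                if (hit.copy_number >= min_copies
                        and hit.identity >= min_identity
                        and hit.score >= min_score):
                    candidates.append(hit)
                s = max(s + 1, hit.end - period)  # resume near the array tail
            else:
                s += 1

    return _resolve_overlaps(candidates, min_period)


def _grow_array(seq: str, s: int, period: int, min_identity: float,
                match: int, mismatch: int) -> RepeatHit:
    # hill-climb the anchor: a seed window overlapping the flank can match
    # one period downstream at just-above-threshold identity, so advance
    # while the two-window agreement strictly improves
    def seed_identity(pos: int) -> float:
        return _identity(seq[pos : pos + period], seq[pos + period : pos + 2 * period])

    while (s + 1 + 2 * period <= len(seq)
           and seed_identity(s + 1) > seed_identity(s)):
        s += 1
    copies = [seq[s : s + period], seq[s + period : s + 2 * period]]
    end = s + 2 * period
    while end + period <= len(seq):
        cons = _consensus(copies)
        nxt = seq[end : end + period]
        if _identity(nxt, cons) < min_identity:
            break
        copies.append(nxt)
        end += period
    cons = _consensus(copies)

    # base-by-base partial extension against the consensus (exact matches)
    lead = 0
    while s - lead - 1 >= 0 and lead < period and seq[s - lead - 1] == cons[period - 1 - lead]:
        lead += 1
    trail = 0
    while end + trail < len(seq) and trail < period and seq[end + trail] == cons[trail]:
        trail += 1

    aligned = sum(_identity(c, cons) for c in copies) * period + lead + trail
    span = (end + trail) - (s - lead)
    n_matches = round(sum(_identity(c, cons) for c in copies) * period) + lead + trail
    n_mismatches = span - n_matches
    return RepeatHit(
        start=s - lead, end=end + trail, period=period,
        copy_number=span / period, consensus=cons,
        identity=aligned / span if span else 0.0,
        partial_lengths=(lead, trail),
        score=n_matches * match + n_mismatches * mismatch,
    )


def _smallest_period(consensus: str) -> int:
    for d in range(1, len(consensus)):
        if len(consensus) % d == 0 and all(
            consensus[i] == consensus[i % d] for i in range(len(consensus))
        ):
            return d
    return len(consensus)


def _reduce_harmonic(hit: RepeatHit) -> RepeatHit:
    d = _smallest_period(hit.consensus)
    if d == hit.period:
        return hit
    return RepeatHit(
        start=hit.start, end=hit.end, period=d,
        copy_number=hit.span / d, consensus=hit.consensus[:d],
        identity=hit.identity, partial_lengths=(hit.partial_lengths[0] % d,
                                                hit.partial_lengths[1] % d),
        score=hit.score,
    )


def _resolve_overlaps(candidates: list[RepeatHit], min_period: int) -> list[RepeatHit]:
    reduced = [_reduce_harmonic(h) for h in candidates]
    reduced.sort(key=lambda h: (-h.score, h.period, h.start))
    accepted: list[RepeatHit] = []
    for hit in reduced:
        overlap = any(
            min(hit.end, a.end) - max(hit.start, a.start) > 0.3 * min(hit.span, a.span)
            for a in accepted
        )
        if not overlap:
            accepted.append(hit)
    accepted.sort(key=lambda h: h.start)
    return accepted


def repeats_table(hits: list[RepeatHit], genome_id: str = ""):
    """Long-form DataFrame of hits (copy number at 1 d.p., as reported)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "genome": genome_id, "start": h.start, "end": h.end,
            "period": h.period, "copies": round(h.copy_number, 1),
            "identity": round(h.identity, 3), "consensus": h.consensus,
            "partial_leading": h.partial_lengths[0],
            "partial_trailing": h.partial_lengths[1],
        }
        for h in hits
    )


def write_bed(hits: list[RepeatHit], name: str, path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(f"{name}\t{h.start}\t{h.end}\t"
                     f"period{h.period}x{h.copy_number:.1f}\t{h.score}\t+\n")
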