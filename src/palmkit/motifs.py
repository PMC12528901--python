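"""Exact discriminative motif discovery.

The question this module answers: which contiguous amino-acid strings are
present in *every* binder sequence and *absent from every* non-binder
sequence?  Such a string is a *discriminative motif*.  The search space is
raw-sequence exact substrings (no alignment columns, no degenerate
positions): the predicate is pure presence/absence, so the full answer is
computable by intersecting k-mer sets of the binders and filtering against
the non-binders, for every k from ``min_len`` up to the point where the
binders share no k-mer at all.

Reporting groups motifs by length, and the headline output is the
*maximal* subset: motifs not contained (as a substring) in any other
reported motif.  Any discriminative motif of length k has all its
discriminative sub-strings trivially re-reported at shorter k; maximality
collapses that redundancy so a family sharing RNYR is reported as one
motif, not four.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .io import LabeledSequenceSet, ProteinRecord

logger = logging.getLogger("palmkit")


@dataclass(frozen=True)
class Motif:
    """A discriminative (or shared) motif with its per-sequence locations.

    ``occurrences`` maps each positive-sequence id to the 1-based start
    positions of the motif in that sequence; it is non-empty for every
    positive.  ``maximal`` is true iff no other motif in the same report
    strictly contains this string.
    """

    string: str
    occurrences: dict[str, tuple[int, ...]]
    maximal: bool = False

    def __len__(self) -> int:
        return len(self.string)


@dataclass(frozen=True)
class MotifReport:
    """All motifs passing the predicate, grouped by length.

    ``mode`` is ``"discriminative"`` (present in all binders, absent from
    all non-binders) or ``"shared"`` (present in all positives, no negative
    constraint).  Motifs are ordered by length descending, then
    lexicographically.
    """

    motifs: tuple[Motif, ...]
    n_positives: int
    n_negatives: int
    min_len: int
    mode: str = "discriminative"

    def by_length(self) -> dict[int, tuple[Motif, ...]]:
        out: dict[int, list[Motif]] = {}
        for m in self.motifs:
            out.setdefault(len(m), []).append(m)
        return {k: tuple(v) for k, v in sorted(out.items(), reverse=True)}

    @property
    def maximal(self) -> tuple[Motif, ...]:
        return tuple(m for m in self.motifs if m.maximal)


def locate_motif(seq: str, motif: str) -> list[int]:
    """All (possibly overlapping) 1-based start positions of *motif* in *seq*."""
    if not motif:
        raise ValueError("motif must be non-empty")
    positions = []
    start = seq.find(motif)
    while start != -1:
        positions.append(start + 1)
        start = seq.find(motif, start + 1)
    return positions


def shared_kmers(positives: Sequence[str], k: int) -> set[str]:
    """k-length substrings occurring in every positive sequence.

    Returns the intersection of the per-sequence k-mer sets.  If *k*
    exceeds the shortest positive the result is empty (with a warning).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if not positives:
        raise ValueError("at least one positive sequence required")
    if k > min(len(s) for s in positives):
        logger.warning("k=%d exceeds shortest positive sequence; empty set", k)
        return set()
    shared = {positives[0][i : i + k] for i in range(len(positives[0]) - k + 1)}
    for seq in positives[1:]:
        if not shared:
            break
        shared &= {seq[i : i + k] for i in range(len(seq) - k + 1)}
    return shared


def _mark_maximal(strings: Iterable[str]) -> dict[str, bool]:
    """True for strings not strictly contained in any other string."""
    strings = list(strings)
    flags = {}
    for s in strings:
        flags[s] = not any(s != t and s in t for t in strings)
    return flags


def _build_report(
    positives: Sequence[ProteinRecord],
    negatives: Sequence[ProteinRecord],
    min_len: int,
    mode: str,
) -> MotifReport:
    pos_seqs = [r.sequence for r in positives]
    neg_seqs = [r.sequence for r in negatives]
    found: list[str] = []
    k = min_len
    max_k = min(len(s) for s in pos_seqs)
    while k <= max_k:
        shared = shared_kmers(pos_seqs, k)
        if not shared:
            break  # no shared k-mer => no shared (k+1)-mer either
        found.extend(m for m in shared if not any(m in s for s in neg_seqs))
        k += 1
    flags = _mark_maximal(found)
    motifs = tuple(
        Motif(
            string=m,
            occurrences={
                r.id: tuple(locate_motif(r.sequence, m)) for r in positives
            },
            maximal=flags[m],
        )
        for m in sorted(found, key=lambda s: (-len(s), s))
    )
    return MotifReport(
        motifs=motifs,
        n_positives=len(positives),
        n_negatives=len(negatives),
        min_len=min_len,
        mode=mode,
    )


def find_discriminative_motifs(
    sset: LabeledSequenceSet, min_len: int = 2
) -> MotifReport:
    """Every substring (length >= *min_len*) present in all binders and
    absent from all non-binders, with positions and maximality flags.

    Records labeled ``excluded`` are ignored on both sides.
    """
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    return _build_report(sset.binders, sset.nonbinders, min_len, "discriminative")


def positives_shared_motifs(
    records: Sequence[ProteinRecord], min_len: int = 2
) -> MotifReport:
    """Motifs shared by *all* given records, with no negative constraint.

    This is the positives-only mode used to compare small accessory-protein
    families (e.g. GOLGA7 against its paralog GOLGA7B, optionally with the
    distant yeast counterpart Erf4) where no non-binding set exists.
    """
    records = list(records)
    if not records:
        raise ValueError("at least one record required")
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    return _build_report(records, (), min_len, "shared")


def maximal_motifs(report: MotifReport) -> list[Motif]:
    """The subset of report motifs not contained in any other report motif."""
    return list(report.maximal)
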