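"""Sequence-tag database search, protein scoring and ranking.

Tags are exact-substring queries against the protein database, searched
in both orientations because a ladder does not declare which terminus
it grew from. Database sequences are collapsed to the tag alphabet
(I/L -> J) and bracketed alternatives become character classes, so a
tag like ``GA[KQ]W`` matches GAKW and GAQW.

Scoring: each distinct matched tag contributes ``max(L - 2, 0)`` points
(L = matched length in residue steps), doubled when the tag matches no
other database protein *and* has at least 5 steps. Short 1-2-step tags
are ubiquitous in any spectrum and score zero; the weight of a tag
grows with its length, and long protein-unique tags — the analogue of
the unique-8-mer argument for database-wide identifiability — dominate.
An identification is flagged unambiguous only when the top protein owns
a unique tag of >= 8 steps.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .mass_core import ResidueTable, Tolerance, default_table
from .spectra_io import ProteinRecord, Spectrum
from .tagging import SequenceTag

#: minimum steps for a tag to earn the uniqueness bonus
UNIQUE_BONUS_MIN_STEPS = 5
#: minimum steps of a unique tag for an unambiguous identification
UNAMBIGUOUS_MIN_STEPS = 8
#: relative score gap under which the top hit is flagged ambiguous
AMBIGUITY_GAP = 0.10


@dataclass(frozen=True)
class TagMatch:
    tag_index: int
    protein: str
    start: int  # 1-based, inclusive, position of the first step residue
    orientation: str  # forward | reverse
    length: int  # matched length in residue steps


@dataclass
class MatchResult:
    protein: str
    score: float
    coverage_percent: int
    matches: list[TagMatch]
    unique_tag_count: int
    ambiguous: bool = False
    unambiguous_identification: bool = False


def _tag_steps(tag: SequenceTag | str) -> list[tuple[str, ...]]:
    if isinstance(tag, SequenceTag):
        return [tuple(s) for s in tag.steps]
    # parse a plain string with optional [..] alternative groups
    steps: list[tuple[str, ...]] = []
    i = 0
    while i < len(tag):
        if tag[i] == "[":
            j = tag.index("]", i)
            steps.append(tuple(sorted(tag[i + 1 : j])))
            i = j + 1
        else:
            steps.append((tag[i],))
            i += 1
    return steps


def _steps_to_regex(steps: Sequence[tuple[str, ...]]) -> str | None:
    """Regex for one orientation; None when a step cannot occur in a
    database sequence (multi-character variant codes never match)."""
    parts = []
    for alts in steps:
        letters = sorted(a for a in alts if len(a) == 1 and a.isalpha())
        if not letters:
            return None
        if len(letters) == 1:
            parts.append(letters[0])
        else:
            parts.append("[" + "".join(letters) + "]")
    return "".join(parts)


def search_tags(
    tags: Sequence[SequenceTag | str],
    db: Sequence[ProteinRecord],
    table: ResidueTable | None = None,
) -> list[TagMatch]:
    """All occurrences of each tag in each database protein.

    Both orientations are searched; overlapping occurrences all count.
    ``start`` indexes the first *step residue* of the tag in the
    protein, whichever orientation matched.
    """
    if not db:
        raise ValueError("protein database is empty")
    table = table or default_table()
    collapsed = {rec.identifier: table.collapse(rec.sequence) for rec in db}
    out: list[TagMatch] = []
    for ti, tag in enumerate(tags):
        steps = _tag_steps(tag)
        L = len(steps)
        if L == 0:
            continue
        fwd = _steps_to_regex(steps)
        rev = _steps_to_regex(steps[::-1])
        palindrome = fwd is not None and fwd == rev
        for rec in db:
            seq = collapsed[rec.identifier]
            if fwd:
                for m in re.finditer(f"(?=({fwd}))", seq):
                    out.append(
                        TagMatch(ti, rec.identifier, m.start() + 1, "forward", L)
                    )
            if rev and not palindrome:
                for m in re.finditer(f"(?=({rev}))", seq):
                    out.append(
                        TagMatch(ti, rec.identifier, m.start() + 1, "reverse", L)
                    )
    return out


def sequence_coverage(
    matched_positions: int | Iterable[int], protein_length: int
) -> int:
    """Percent of residues covered, rounded half-up to an integer.

    Accepts either the count of distinct matched positions or the
    positions themselves (1-based).
    """
    if protein_length <= 0:
        raise ValueError("protein length must be positive")
    if isinstance(matched_positions, int):
        n = matched_positions
    else:
        pos = set(matched_positions)
        if pos and (min(pos) < 1 or max(pos) > protein_length):
            raise ValueError("matched positions outside [1, length]")
        n = len(pos)
    return int(math.floor(100.0 * n / protein_length + 0.5))


def covered_positions(matches: Iterable[TagMatch]) -> set[int]:
    pos: set[int] = set()
    for m in matches:
        pos.update(range(m.start, m.start + m.length))
    return pos


def score_proteins(
    matches: Sequence[TagMatch],
    db: Sequence[ProteinRecord],
    tags: Sequence[SequenceTag | str] | None = None,
) -> list[MatchResult]:
    """Rank database proteins by their matched-tag score.

    Ties break by coverage (desc) then identifier (asc). The top result
    carries an ``ambiguous`` flag when the runner-up scores within 10%
    of it, and ``unambiguous_identification`` when the top protein owns
    a protein-unique tag of >= 8 steps.
    """
    lengths = {rec.identifier: len(rec.sequence) for rec in db}
    by_protein: dict[str, list[TagMatch]] = {}
    tag_proteins: dict[int, set[str]] = {}
    for m in matches:
        by_protein.setdefault(m.protein, []).append(m)
        tag_proteins.setdefault(m.tag_index, set()).add(m.protein)

    results = []
    for protein, ms in by_protein.items():
        distinct: dict[int, TagMatch] = {}
        for m in ms:
            distinct.setdefault(m.tag_index, m)
        score = 0.0
        unique_count = 0
        has_long_unique = False
        for ti, m in distinct.items():
            unique = len(tag_proteins[ti]) == 1
            if unique:
                unique_count += 1
                if m.length >= UNAMBIGUOUS_MIN_STEPS:
                    has_long_unique = True
            weight = 2.0 if (unique and m.length >= UNIQUE_BONUS_MIN_STEPS) else 1.0
            score += max(m.length - 2, 0) * weight
        cov = sequence_coverage(covered_positions(ms), lengths[protein])
        res = MatchResult(
            protein=protein,
            score=score,
            coverage_percent=cov,
            matches=ms,
            unique_tag_count=unique_count,
        )
        res.unambiguous_identification = has_long_unique
        results.append(res)
    results.sort(key=lambda r: (-r.score, -r.coverage_percent, r.protein))
    if len(results) >= 2 and results[0].score > 0:
        gap = (results[0].score - results[1].score) / results[0].score
        results[0].ambiguous = gap < AMBIGUITY_GAP
    return results


def identify_spectrum(
    tags: Sequence[SequenceTag],
    db: Sequence[ProteinRecord],
    table: ResidueTable | None = None,
) -> list[MatchResult]:
    """Search + score in one call."""
    matches = search_tags(tags, db, table)
    return score_proteins(matches, db, tags)


# --- spectrum similarity ----------------------------------------------------


def common_peak_fraction(
    a: Spectrum, b: Spectrum, tol: Tolerance | None = None
) -> tuple[int, int, int]:
    """(n_common, n_total_a, percent): peaks of A with a partner in B.

    Greedy nearest-match pairing in ascending m/z order; each B peak
    can pair with at most one A peak. Percent is rounded half-up.
    """
    tol = tol or Tolerance()
    mz_b = b.mz
    used = np.zeros(len(mz_b), dtype=bool)
    n_common = 0
    for p in a.peaks:
        half = tol.window(p.mz)
        lo = int(np.searchsorted(mz_b, p.mz - half, side="left"))
        hi = int(np.searchsorted(mz_b, p.mz + half, side="right"))
        best = -1
        best_d = np.inf
        for j in range(lo, hi):
            if used[j]:
                continue
            d = abs(mz_b[j] - p.mz)
            if d < best_d:
                best, best_d = j, d
        if best >= 0:
            used[best] = True
            n_common += 1
    n_total = len(a)
    percent = (
        int(math.floor(100.0 * n_common / n_total + 0.5)) if n_total else 0
    )
    return n_common, n_total, percent


def common_peak_percent(n_common: int, n_total: int) -> int:
    """The rounding contract used for reporting common-peak fractions."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return int(math.floor(100.0 * n_common / n_total + 0.5))


# --- database k-mer uniqueness ----------------------------------------------


def kmer_uniqueness(
    db: Sequence[ProteinRecord], k: int, collapse_il: bool = True
) -> float:
    """Fraction of proteins owning >= 1 k-mer found in no other protein.

    Measures database-wide identifiability: if most proteins contain a
    unique k-residue word, a single k-length sequence tag suffices to
    pin a protein down. Proteins shorter than k count as not-unique.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not db:
        raise ValueError("protein database is empty")
    seqs = []
    for rec in db:
        s = rec.sequence
        if collapse_il:
            s = s.replace("I", "J").replace("L", "J")
        seqs.append(s)
    owners: dict[str, int] = {}  # kmer -> protein index, or -1 if shared
    for idx, s in enumerate(seqs):
        for i in range(len(s) - k + 1):
            kmer = s[i : i + k]
            prev = owners.get(kmer)
            if prev is None:
                owners[kmer] = idx
            elif prev != idx:
                owners[kmer] = -1
    has_unique = [False] * len(db)
    for kmer, owner in owners.items():
        if owner >= 0:
            has_unique[owner] = True
    return sum(has_unique) / len(db)


def make_reversed_decoys(db: Sequence[ProteinRecord]) -> list[ProteinRecord]:
    """Reversed-sequence decoys for chance-match estimation."""
    return [
        ProteinRecord(f"decoy_{rec.identifier}", f"reversed {rec.identifier}",
                      rec.sequence[::-1])
        for rec in db
    ]
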