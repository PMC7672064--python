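"""Residue-ladder detection: the de novo sequencing core.

A filtered spectrum is turned into a directed acyclic graph whose nodes
are peaks and whose edges (low m/z -> high m/z) are pairs of peaks
separated by exactly one residue mass within tolerance. Maximal paths
through this graph are sequence tags: peptide subsequences read
directly off the spectrum, with no assumption about which terminus the
ladder grows from.

Tolerance convention: a step qualifies when the observed gap is within
the absolute step window — the ppm tolerance evaluated at a fixed
reference m/z (2 ppm -> +/- 2 mDa; see Tolerance.step_window). Step
ppm errors are reported on that same reference scale, so they are
directly comparable to the tolerance and independent of which adduct
carries the fragments. A step matched by several residues (possible
with near-isobaric variants enabled; K and Q sit 36 mDa apart and
never merge) is rendered as a bracketed alternative, e.g. ``[KQ]``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .mass_core import (
    Adduct,
    IonSeries,
    ResidueTable,
    Terminus,
    Tolerance,
    adduct as get_adduct,
    default_table,
    fragment_mz,
    ion_series,
    ppm_error,
)
from .spectra_io import ProteinRecord, Spectrum

logger = logging.getLogger(__name__)

DEFAULT_MAX_TAGS = 5000
DEFAULT_BRANCH_CAP = 8


@dataclass(frozen=True)
class Edge:
    src: int
    dst: int
    #: residue codes matching the gap, sorted by |ppm|, then alphabetically
    residues: tuple[str, ...]
    #: signed ppm error of the best-matching residue (peak-m/z scale)
    ppm: float

    def label(self) -> str:
        if len(self.residues) == 1:
            return self.residues[0]
        return "[" + "".join(self.residues) + "]"


@dataclass
class ResidueGraph:
    spectrum: Spectrum
    edges: list[Edge]
    #: adjacency: node -> outgoing edges, ordered by |ppm|
    out_edges: dict[int, list[Edge]] = field(default_factory=dict)
    in_degree: dict[int, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.out_edges:
            for e in self.edges:
                self.out_edges.setdefault(e.src, []).append(e)
                self.in_degree[e.dst] = self.in_degree.get(e.dst, 0) + 1
            for es in self.out_edges.values():
                es.sort(key=lambda e: (abs(e.ppm), e.dst))

    @property
    def n_nodes(self) -> int:
        return len(self.spectrum)


@dataclass(frozen=True)
class SequenceTag:
    """A chain of peaks whose consecutive gaps spell residues.

    ``residues`` is the step string (bracketed where ambiguous);
    ``steps`` the per-step label tuples; ``peak_indices`` the supporting
    peaks; ``ppm_errors`` the per-step errors. Orientation relative to
    the protein backbone is unknown at extraction time: a ladder read
    low -> high m/z corresponds to N->C for N-terminal series and C->N
    for C-terminal series.
    """

    residues: str
    steps: tuple[tuple[str, ...], ...]
    peak_indices: tuple[int, ...]
    ppm_errors: tuple[float, ...]

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    @property
    def mean_abs_ppm(self) -> float:
        return float(np.mean(np.abs(self.ppm_errors))) if self.ppm_errors else 0.0


def match_residues(
    delta: float, table: ResidueTable, tol: Tolerance
) -> list[tuple[str, float]]:
    """Residue codes matching an observed gap, with signed ppm errors
    on the step-reference scale (1 ppm = 1 mDa at reference 1000)."""
    from .mass_core import STEP_REFERENCE_MZ

    out = []
    for code, mass in table.items():
        err = 1e6 * (delta - mass) / STEP_REFERENCE_MZ
        if abs(err) <= tol.ppm:
            out.append((code, err))
    out.sort(key=lambda t: (abs(t[1]), t[0]))
    return out


def build_residue_graph(
    s: Spectrum,
    table: ResidueTable | None = None,
    tol: Tolerance | None = None,
) -> ResidueGraph:
    """All qualifying residue-mass edges via a sorted two-pointer sweep.

    For each residue mass the candidate partners of every peak lie in a
    contiguous m/z window, located with binary search — no all-pairs
    scan.
    """
    from .mass_core import STEP_REFERENCE_MZ

    table = table or default_table()
    tol = tol or Tolerance()
    mz = s.mz
    n = len(mz)
    half = tol.step_window()
    pair_matches: dict[tuple[int, int], list[tuple[str, float]]] = {}
    for code, rm in table.items():
        for i in range(n):
            target = mz[i] + rm
            lo = int(np.searchsorted(mz, target - half, side="left"))
            hi = int(np.searchsorted(mz, target + half, side="right"))
            for j in range(lo, hi):
                if j == i:
                    continue
                err = 1e6 * ((mz[j] - mz[i]) - rm) / STEP_REFERENCE_MZ
                if abs(err) <= tol.ppm:
                    pair_matches.setdefault((i, j), []).append((code, err))
    edges = []
    for (i, j), matches in sorted(pair_matches.items()):
        matches.sort(key=lambda t: (abs(t[1]), t[0]))
        edges.append(
            Edge(
                src=i,
                dst=j,
                residues=tuple(c for c, _ in matches),
                ppm=matches[0][1],
            )
        )
    return ResidueGraph(spectrum=s, edges=edges)


def extract_tags(
    g: ResidueGraph,
    min_len: int = 3,
    max_tags: int = DEFAULT_MAX_TAGS,
    branch_cap: int = DEFAULT_BRANCH_CAP,
) -> list[SequenceTag]:
    """Maximal paths through the residue graph as sequence tags.

    A path is maximal when it cannot be extended at either end. Paths
    shorter than ``min_len`` steps are dropped. When more than
    ``max_tags`` maximal paths exist, the best are kept, ordered by
    (length desc, mean |ppm| asc, residue string asc) — deterministic.
    ``branch_cap`` bounds the out-edges explored per node (closest ppm
    first) to keep pathological dense spectra tractable.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    tags: list[SequenceTag] = []
    seen: set[tuple[int, ...]] = set()
    capped = False
    overflow = False
    sources = [
        node
        for node in sorted(g.out_edges)
        if g.in_degree.get(node, 0) == 0
    ]

    budget = max(max_tags * 20, 100000)  # hard cap on enumerated paths

    def dfs(node: int, path_edges: list[Edge]):
        nonlocal capped, overflow
        if len(seen) >= budget:
            overflow = True
            return
        outs = g.out_edges.get(node, [])
        if len(outs) > branch_cap:
            capped = True
            outs = outs[:branch_cap]
        if not outs:  # sink: path is maximal
            key = tuple(e.src for e in path_edges) + (node,)
            if len(path_edges) >= min_len and key not in seen:
                seen.add(key)
                tags.append(_path_to_tag(path_edges))
            return
        for e in outs:
            path_edges.append(e)
            dfs(e.dst, path_edges)
            path_edges.pop()

    for src in sources:
        dfs(src, [])
    if capped:
        logger.info("branch cap %d hit during tag extraction", branch_cap)
    if overflow:
        logger.warning("path enumeration budget hit; tag list truncated")
    tags.sort(key=lambda t: (-t.n_steps, t.mean_abs_ppm, t.residues))
    if len(tags) > max_tags:
        logger.info("keeping best %d of %d maximal tags", max_tags, len(tags))
        tags = tags[:max_tags]
    return tags


def _path_to_tag(path_edges: Sequence[Edge]) -> SequenceTag:
    residues = "".join(e.label() for e in path_edges)
    return SequenceTag(
        residues=residues,
        steps=tuple(e.residues for e in path_edges),
        peak_indices=tuple([path_edges[0].src] + [e.dst for e in path_edges]),
        ppm_errors=tuple(e.ppm for e in path_edges),
    )


def find_tags(
    s: Spectrum,
    table: ResidueTable | None = None,
    tol: Tolerance | None = None,
    min_len: int = 3,
    max_tags: int = DEFAULT_MAX_TAGS,
) -> list[SequenceTag]:
    """Convenience: graph construction plus tag extraction."""
    return extract_tags(
        build_residue_graph(s, table, tol), min_len=min_len, max_tags=max_tags
    )


# --- absolute annotation ---------------------------------------------------


@dataclass(frozen=True)
class IonAnnotation:
    peak_index: int
    series: str
    adduct: str
    #: 1-based inclusive residue window of the fragment in the protein
    start: int
    end: int
    ppm: float


def annotate_tag(
    tag: SequenceTag,
    spectrum: Spectrum,
    protein: ProteinRecord,
    match_start: int,
    orientation: str = "forward",
    series_names: Iterable[str] = ("b", "a", "c", "y", "z+1", "internal-yb", "internal-ya"),
    adduct_names: Iterable[str] = ("+Na", "+H"),
    table: ResidueTable | None = None,
    tol: Tolerance | None = None,
) -> list[IonAnnotation]:
    """Absolute ion-type annotations for a database-matched tag.

    Ladder logic is offset-free — a tag stands on m/z *differences* —
    so a tag may carry no absolute annotation at all (e.g. under a
    uniform calibration shift); that does not invalidate it. Given the
    tag's match position (``match_start``, 1-based, first step residue)
    this enumerates, per supporting peak, every (series, adduct,
    fragment boundary) consistent with the alignment whose theoretical
    m/z matches the peak within tolerance: for N-terminal/internal
    series the fragment ends at the aligned residue and the start is
    free (1 for terminal ions, >1 for internal); for C-terminal series
    the fragment starts at the aligned residue and must run to the C
    terminus.
    """
    table = table or default_table()
    tol = tol or Tolerance()
    seq = table.collapse(protein.sequence)
    n = len(seq)
    L = tag.n_steps
    out: list[IonAnnotation] = []
    for k, peak_idx in enumerate(tag.peak_indices):
        obs = spectrum.peaks[peak_idx].mz
        for sname in series_names:
            series = ion_series(sname)
            for aname in adduct_names:
                for start, end in _candidate_windows(
                    series, k, match_start, orientation, L, n
                ):
                    frag = seq[start - 1 : end]
                    if not frag or "X" in frag:
                        continue
                    theo = fragment_mz(frag, series, aname, table)
                    err = ppm_error(obs, theo)
                    if abs(err) <= tol.ppm:
                        out.append(
                            IonAnnotation(peak_idx, sname, aname, start, end, err)
                        )
    return out


def _candidate_windows(
    series: IonSeries,
    k: int,
    match_start: int,
    orientation: str,
    n_steps: int,
    n_residues: int,
):
    """Fragment windows (1-based inclusive) consistent with peak k of a
    tag aligned at match_start."""
    if orientation == "forward":
        # ladder grows N->C: peak k sits after residue match_start+k-1
        anchor = match_start + k - 1
        if series.terminus == Terminus.N:
            if anchor >= 1:
                yield (1, anchor)
        elif series.terminus == Terminus.INTERNAL:
            if anchor <= n_residues - 1:  # internal excludes the C terminus
                for start in range(2, anchor + 1):
                    yield (start, anchor)
        else:  # C-terminal series read forward would grow the other way
            return
    else:
        # reverse orientation: ladder (low->high m/z) grows C->N, i.e.
        # peak k is a fragment starting at the aligned residue and
        # running to the C terminus (C-terminal series only)
        anchor = match_start + (n_steps - k)
        if series.terminus == Terminus.C:
            if anchor <= n_residues:
                yield (anchor, n_residues)
        elif series.terminus == Terminus.INTERNAL:
            if anchor >= 2:  # internal excludes the N terminus
                for end in range(anchor, n_residues):
                    yield (anchor, end)
        else:
            return
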