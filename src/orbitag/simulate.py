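"""Synthetic GCIB-SIMS protein spectra with ground truth.

Ballistic fragmentation of an undigested protein film produces terminal
(a/b/c prefix, y/z-type suffix) and internal fragment ions, mostly as
sodium adducts in positive polarity. The sequence ladders that make de
novo reading possible exist because a given cleavage product degrades
further by sequential single-residue loss: the spectrum contains whole
*families* of fragments sharing one anchor and differing by one residue
at a time. The generator is built around that mechanism:

* candidate families are the N terminus (one per N-terminal series),
  the C terminus (one per C-terminal series) and, for internal series,
  a seeded random sample of interior anchor positions;
* each family is observed with probability ``sampling_fraction`` times
  the protein's relative abundance; an observed family contributes a
  contiguous run of fragment windows (random run length and placement
  within the admissible 2..max residue lengths), all carrying a single
  adduct drawn from the configured mix — sequential neutral loss does
  not change the cationizing ion;
* every emitted fragment gets an independent multiplicative ppm jitter
  and an exponential intensity; chemical noise is Poisson in count with
  uniform m/z (hence uniform fractional mass) over the mass range.

Randomness is split into independent streams (family selection, adduct
assignment, jitter, noise, intensity) spawned from the single seed, so
that e.g. changing the adduct mix alone does not change which fragment
windows are sampled — the property behind the adduct-invariance checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .mass_core import (
    ResidueTable,
    Terminus,
    default_table,
    fragment_mz,
    ion_series,
)
from .spectra_io import Peak, ProteinRecord, Spectrum

#: mature hen egg-white lysozyme (129 residues; N terminus KVFGRC)
LYSOZYME_CHICKEN = (
    "KVFGRCELAAAMKRHGLDNYRGYSLGNWVCAAKFESNFNTQATNRNTDGSTDYGILQINSRWWCNDGRTPGSRN"
    "LCNIPCSALLSSDITASVNCAKKIVSDGNGMNAWVAWRNRCKGTDVQAWIRGCRL"
)
#: human insulin, B then A chain concatenated into one 51-residue string.
#: Synthetic convenience: the real molecule is two disulfide-linked chains.
INSULIN_HUMAN = (
    "FVNQHLCGSHLVEALYLVCGERGFFYTPKT" "GIVEQCCTSICSLYQLENYCN"
)

POSITIVE_SERIES = ("b", "y", "a", "c", "z+1", "internal-yb", "internal-ya")
NEGATIVE_SERIES = ("a", "b", "c", "y", "z-H", "x")


@dataclass
class SimConfig:
    """Generative description of one synthetic spectrum."""

    proteins: list[ProteinRecord]
    seed: int
    abundances: list[float] | None = None  # relative, default all 1.0
    series: tuple[str, ...] = POSITIVE_SERIES
    adduct_mix: dict[str, float] = field(
        default_factory=lambda: {"+Na": 0.8, "+H": 0.2}
    )
    sampling_fraction: float = 0.25
    min_fragment_length: int = 2
    max_fragment_length: int = 15
    #: candidate internal anchors per internal series, as a multiple of
    #: the protein length; anchor positions are drawn at random
    internal_anchors_per_residue: float = 0.5
    #: an observed family emits a contiguous run of at least this many
    #: fragment windows (bounded above by the admissible lengths)
    min_run: int = 3
    jitter_ppm_sd: float = 1.0
    noise_per_100da: float = 2.0
    signal_intensity_mean: float = 100.0
    noise_intensity_mean: float = 10.0
    mass_range: tuple[float, float] = (150.0, 2250.0)
    polarity: str = "positive"

    def __post_init__(self):
        if self.abundances is None:
            self.abundances = [1.0] * len(self.proteins)
        if len(self.abundances) != len(self.proteins):
            raise ValueError("one abundance per protein required")
        if not 0 < self.sampling_fraction <= 1:
            raise ValueError("sampling_fraction must lie in (0, 1]")
        total = sum(self.adduct_mix.values())
        if total <= 0 or any(p < 0 for p in self.adduct_mix.values()):
            raise ValueError("adduct mix must be non-negative, not all zero")

    def negative_polarity(self) -> "SimConfig":
        """The same experiment acquired in negative polarity:
        deprotonated fragments, a/b/c plus y, z-H, x series."""
        return replace(
            self,
            series=NEGATIVE_SERIES,
            adduct_mix={"-H": 1.0},
            polarity="negative",
        )


@dataclass(frozen=True)
class TruthEntry:
    protein: str | None  # None for noise peaks
    start: int  # 1-based inclusive; 0 for noise
    end: int
    series: str | None
    adduct: str | None
    true_mz: float  # before jitter; for noise, the drawn m/z
    observed_mz: float
    is_noise: bool


@dataclass
class GroundTruth:
    entries: list[TruthEntry]

    def signal(self) -> list[TruthEntry]:
        return [e for e in self.entries if not e.is_noise]

    def noise(self) -> list[TruthEntry]:
        return [e for e in self.entries if e.is_noise]


def _candidate_anchors(
    n: int, series_name: str, cfg: SimConfig, rng: np.random.Generator
) -> list[int]:
    """Candidate family anchors for one protein x series.

    An anchor is the fixed end of a fragment family: position 1 for
    N-terminal series, n for C-terminal series, an interior start
    position for internal series (drawn at random, without replacement).
    """
    terminus = ion_series(series_name).terminus
    if terminus == Terminus.N:
        return [1]
    if terminus == Terminus.C:
        return [n]
    starts = list(range(2, n - cfg.min_fragment_length + 1))
    k = min(len(starts), int(round(cfg.internal_anchors_per_residue * n)))
    if not starts or k == 0:
        return []
    idx = rng.choice(len(starts), size=k, replace=False)
    return [starts[i] for i in sorted(idx)]


def _family_windows(
    n: int, series_name: str, anchor: int, cfg: SimConfig, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Contiguous run of fragment windows for one observed family.

    Admissible fragment lengths at this anchor are 2..max (clipped by
    the protein for terminal series, by the need to exclude the C
    terminus for internal ones). The run covers a random contiguous
    block of at least ``min_run`` of those lengths.
    """
    terminus = ion_series(series_name).terminus
    lmin = cfg.min_fragment_length
    if terminus == Terminus.N:
        lmax = min(cfg.max_fragment_length, n - 1)
    elif terminus == Terminus.C:
        lmax = min(cfg.max_fragment_length, n - 1)
    else:
        lmax = min(cfg.max_fragment_length, n - anchor)  # end <= n-1
    if lmax < lmin:
        return []
    n_lengths = lmax - lmin + 1
    run = int(rng.integers(min(cfg.min_run, n_lengths), n_lengths + 1))
    offset = int(rng.integers(0, n_lengths - run + 1))
    lengths = range(lmin + offset, lmin + offset + run)
    if terminus == Terminus.N:
        return [(1, l) for l in lengths]
    if terminus == Terminus.C:
        return [(n - l + 1, n) for l in lengths]
    return [(anchor, anchor + l - 1) for l in lengths]


def simulate_spectrum(
    cfg: SimConfig, table: ResidueTable | None = None
) -> tuple[Spectrum, GroundTruth]:
    """Generate one spectrum plus its peak-level ground truth.

    Deterministic given the seed. Fragments falling outside the mass
    range are not emitted (the instrument would not record them).
    """
    if not cfg.proteins:
        raise ValueError("at least one source protein is required")
    table = table or default_table()
    ss = np.random.SeedSequence(cfg.seed)
    select_rng, adduct_rng, jitter_rng, noise_rng, intensity_rng = (
        np.random.default_rng(child) for child in ss.spawn(5)
    )

    adduct_names = sorted(cfg.adduct_mix)
    probs = np.array([cfg.adduct_mix[a] for a in adduct_names], dtype=float)
    cum = np.cumsum(probs / probs.sum())

    lo, hi = cfg.mass_range
    peaks: list[Peak] = []
    entries: list[TruthEntry] = []

    for rec, abundance in zip(cfg.proteins, cfg.abundances):
        seq = table.collapse(rec.sequence)
        n = len(seq)
        keep_p = min(1.0, cfg.sampling_fraction * abundance)
        for series_name in cfg.series:
            for anchor in _candidate_anchors(n, series_name, cfg, select_rng):
                windows = _family_windows(n, series_name, anchor, cfg, select_rng)
                observed = select_rng.random() < keep_p
                # one adduct per family: sequential residue loss does
                # not change the cationizing ion
                u = adduct_rng.random()
                adduct_name = adduct_names[int(np.searchsorted(cum, u, side="right"))]
                if not observed:
                    continue
                for start, end in windows:
                    eps = jitter_rng.normal() * cfg.jitter_ppm_sd * 1e-6
                    frag = seq[start - 1 : end]
                    true_mz = fragment_mz(frag, series_name, adduct_name, table)
                    if not (lo <= true_mz <= hi):
                        continue
                    obs = true_mz * (1.0 + eps)
                    intensity = intensity_rng.exponential(cfg.signal_intensity_mean)
                    peaks.append(Peak(obs, intensity))
                    entries.append(
                        TruthEntry(
                            rec.identifier, start, end, series_name, adduct_name,
                            true_mz, obs, False,
                        )
                    )

    n_noise = int(noise_rng.poisson(cfg.noise_per_100da * (hi - lo) / 100.0))
    for _ in range(n_noise):
        mz = float(noise_rng.uniform(lo, hi))
        intensity = float(intensity_rng.exponential(cfg.noise_intensity_mean))
        peaks.append(Peak(mz, intensity))
        entries.append(TruthEntry(None, 0, 0, None, None, mz, mz, True))

    spectrum = Spectrum(peaks=peaks, polarity=cfg.polarity)
    return spectrum, GroundTruth(entries)


def simulate_full_series(
    sequence: str,
    series_name: str = "b",
    adduct_name: str = "+Na",
    table: ResidueTable | None = None,
    intensity: float = 100.0,
) -> Spectrum:
    """Noiseless complete single-series ladder of one peptide.

    For an N-terminal series this is b1..b(n-1) (etc.); for a
    C-terminal series y1..y(n-1). The ladder's residue differences
    spell residues 2..n-1 of the peptide, so tag extraction on this
    spectrum must recover exactly that subsequence.
    """
    table = table or default_table()
    seq = table.collapse(sequence)
    n = len(seq)
    terminus = ion_series(series_name).terminus
    peaks = []
    for l in range(1, n):
        frag = seq[:l] if terminus == Terminus.N else seq[n - l :]
        peaks.append(Peak(fragment_mz(frag, series_name, adduct_name, table), intensity))
    return Spectrum(peaks=peaks)


AA20 = "ACDEFGHIKLMNPQRSTVWY"


def make_decoy_db(
    n: int,
    length_range: tuple[int, int] = (100, 400),
    seed: int = 0,
    prefix: str = "decoy",
) -> list[ProteinRecord]:
    """n i.i.d. uniform-composition random protein records."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    records = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(AA20[j] for j in rng.integers(0, len(AA20), size=length))
        records.append(ProteinRecord(f"{prefix}_{i:03d}", f"random sequence {i}", seq))
    return records
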