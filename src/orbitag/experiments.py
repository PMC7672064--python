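"""End-to-end validation experiments on synthetic spectra.

Each experiment wires the full pipeline — simulate, chemical-filter,
extract tags, search, score — under stated conditions and reports a
success rate over seeded trials. They serve three purposes: recovery
benchmarks (can the pipeline re-identify the protein a spectrum was
generated from?), negative controls (does pure noise stay silent?),
and invariance checks (do adduct choices leave tag strings unchanged?).

All trial seeds are derived from a single base seed and stay below
2**31.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .filtering import chemical_filter
from .identify import identify_spectrum
from .mass_core import ResidueTable, Tolerance, default_table, fragment_mz
from .profiling import segment_layers
from .simulate import (
    INSULIN_HUMAN,
    LYSOZYME_CHICKEN,
    SimConfig,
    make_decoy_db,
    simulate_full_series,
    simulate_spectrum,
)
from .spectra_io import Peak, ProteinRecord, Spectrum
from .tagging import find_tags

LYSOZYME = ProteinRecord("LYSC_CHICK", "hen egg-white lysozyme", LYSOZYME_CHICKEN)
INSULIN = ProteinRecord("INS_HUMAN", "human insulin B+A chains", INSULIN_HUMAN)


def _trial_seeds(base_seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(base_seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def identify_simulated(
    cfg: SimConfig, db, table: ResidueTable | None = None
):
    """The standard pipeline on one simulated spectrum.

    Intensity filtering is skipped: simulated intensities carry no
    signal/background separation (both are exponential draws), so the
    chemical filter — which provably preserves every ladder member —
    is the appropriate preprocessing here.
    """
    table = table or default_table()
    spectrum, truth = simulate_spectrum(cfg, table)
    filtered = chemical_filter(spectrum, table)
    tags = find_tags(filtered, table)
    results = identify_spectrum(tags, db, table) if tags else []
    return results, spectrum, truth


@dataclass
class RecoveryOutcome:
    n_trials: int
    n_success: int

    @property
    def rate(self) -> float:
        return self.n_success / self.n_trials if self.n_trials else 0.0

    @property
    def percent(self) -> float:
        return 100.0 * self.rate


def parameter_recovery(
    n_trials: int = 50,
    base_seed: int = 0,
    n_decoys: int = 100,
    db_seed: int = 7,
    target: ProteinRecord = LYSOZYME,
) -> RecoveryOutcome:
    """Single-protein recovery: simulate the target with default
    conditions (sampling 0.25, 1 ppm jitter, 2 noise peaks / 100 Da)
    and ask whether it ranks first against the decoy database."""
    db = make_decoy_db(n_decoys, seed=db_seed) + [target]
    wins = 0
    for seed in _trial_seeds(base_seed, n_trials):
        cfg = SimConfig(proteins=[target], seed=seed)
        results, _, _ = identify_simulated(cfg, db)
        if results and results[0].protein == target.identifier:
            wins += 1
    return RecoveryOutcome(n_trials, wins)


def mixture_recovery(
    n_trials: int = 20,
    base_seed: int = 1,
    n_decoys: int = 100,
    db_seed: int = 7,
    proteins: tuple[ProteinRecord, ProteinRecord] = (LYSOZYME, INSULIN),
) -> RecoveryOutcome:
    """Equimolar two-protein deposition: both sources must occupy the
    top two ranks."""
    db = make_decoy_db(n_decoys, seed=db_seed) + list(proteins)
    want = {p.identifier for p in proteins}
    wins = 0
    for seed in _trial_seeds(base_seed, n_trials):
        cfg = SimConfig(proteins=list(proteins), seed=seed)
        results, _, _ = identify_simulated(cfg, db)
        if {r.protein for r in results[:2]} == want:
            wins += 1
    return RecoveryOutcome(n_trials, wins)


def negative_control(
    n_trials: int = 50,
    base_seed: int = 2,
    n_decoys: int = 100,
    db_seed: int = 7,
) -> RecoveryOutcome:
    """Noise-only spectra must never produce an identification backed
    by a protein-unique tag of >= 8 residue steps."""
    db = make_decoy_db(n_decoys, seed=db_seed) + [LYSOZYME]
    clean = 0
    for seed in _trial_seeds(base_seed, n_trials):
        cfg = SimConfig(proteins=[LYSOZYME], abundances=[0.0], seed=seed)
        results, _, _ = identify_simulated(cfg, db)
        if not any(r.unambiguous_identification for r in results):
            clean += 1
    return RecoveryOutcome(n_trials, clean)


def adduct_invariance(seed: int = 11, target: ProteinRecord = LYSOZYME) -> bool:
    """Same seed, pure +H vs pure +Na: the multiset of tag strings must
    be identical (ladder logic sees only m/z differences)."""
    kw = dict(
        proteins=[target],
        seed=seed,
        jitter_ppm_sd=0.0,
        noise_per_100da=0.0,
        mass_range=(50.0, 3500.0),
    )
    tag_sets = []
    for mix in ({"+H": 1.0}, {"+Na": 1.0}):
        spectrum, _ = simulate_spectrum(SimConfig(adduct_mix=mix, **kw))
        tag_sets.append(sorted(t.residues for t in find_tags(spectrum)))
    return tag_sets[0] == tag_sets[1]


def complete_series_recovery(
    n_trials: int = 20, base_seed: int = 3, length: int = 20
) -> RecoveryOutcome:
    """Noiseless full b-series (+Na) of a random peptide: the single
    longest tag must spell residues 2..n-1 exactly (I/L as J)."""
    table = default_table()
    wins = 0
    seeds = _trial_seeds(base_seed, n_trials)
    for seed in seeds:
        rng = np.random.default_rng(seed)
        seq = "".join("ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, length))
        spectrum = simulate_full_series(seq, "b", "+Na", table)
        tags = find_tags(spectrum, table, min_len=1, max_tags=10**6)
        if tags and tags[0].residues == table.collapse(seq)[1:-1]:
            wins += 1
    return RecoveryOutcome(n_trials, wins)


def two_layer_scans(
    boundary: int = 10,
    n_scans: int = 20,
    seed: int = 0,
    marker_mz: float = 78.95905,
    low: float = 1.0,
    high: float = 10.0,
):
    """Synthetic depth-profile scan series: a marker ion steps from a
    low to a high level at the layer boundary, over a background of
    random peaks. Returns (scans, boundary)."""
    rng = np.random.default_rng(seed)
    scans = []
    for s in range(n_scans):
        level = low if s < boundary else high
        intensity = max(0.0, float(rng.normal(level, 0.15 * high)))
        peaks = [Peak(marker_mz, intensity)]
        for _ in range(20):  # uncorrelated background
            peaks.append(Peak(float(rng.uniform(100, 1000)), float(rng.exponential(2.0))))
        scans.append(Spectrum(peaks=peaks, polarity="negative"))
    return scans, boundary


def depth_segmentation(
    n_trials: int = 20, base_seed: int = 4, threshold: float = 0.5
) -> RecoveryOutcome:
    """Noisy two-layer marker step: the detected boundary must fall
    within one scan of the true one."""
    from .profiling import TargetIon, targeted_profile

    wins = 0
    for seed in _trial_seeds(base_seed, n_trials):
        rng = np.random.default_rng(seed)
        boundary = int(rng.integers(5, 16))
        scans, _ = two_layer_scans(boundary=boundary, seed=seed)
        profile = targeted_profile(scans, [TargetIon("marker", 78.95905)])
        bounds = segment_layers(profile.profile("marker"), threshold)
        if bounds and min(abs(b - boundary) for b in bounds) <= 1:
            wins += 1
    return RecoveryOutcome(n_trials, wins)
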