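"""Targeted depth profiling across a sputter scan series.

Given per-scan spectra and a set of marker ions (protein-characteristic
fragments, or a layer marker such as the phospholipid head-group ion
PO3-), the profile of each marker is its summed intensity within
tolerance of the target m/z, per scan. Layer boundaries are placed
where a marker's smoothed profile crosses a fraction of its maximum —
the operational version of assigning tissue layers from the abundance
of a marker ion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .mass_core import Tolerance, fragment_mz
from .spectra_io import Spectrum

#: PO3- m/z, the phospholipid marker used to segment skin layers
PO3_MZ = 78.95905

#: collagen markers: hydroxyproline-containing fragments are collagen
#: indicators (hydroxyproline is ~13.5% of the collagen sequence)
def collagen_marker_targets(tol_ppm: float = 2.0) -> list["TargetIon"]:
    from .mass_core import ResidueTable

    t = ResidueTable.default(hydroxyproline=True, methoxyproline=True)
    return [
        TargetIon("Hyp-immonium-like(b1+H)", fragment_mz(["Hyp"], "b", "+H", t), Tolerance(tol_ppm)),
        TargetIon("Hyp-y1+H", fragment_mz(["Hyp"], "y", "+H", t), Tolerance(tol_ppm)),
        TargetIon("Mep-y1+H", fragment_mz(["Mep"], "y", "+H", t), Tolerance(tol_ppm)),
        TargetIon("PGE-yb+Na", fragment_mz("PGE", "internal-yb", "+Na", t), Tolerance(tol_ppm)),
    ]


@dataclass(frozen=True)
class TargetIon:
    label: str
    mz: float
    tolerance: Tolerance = field(default_factory=Tolerance)

    def __post_init__(self):
        if self.mz <= 0:
            raise ValueError("target m/z must be positive")


@dataclass
class DepthProfile:
    targets: list[TargetIon]
    #: shape (n_targets, n_scans)
    intensities: np.ndarray
    normalization: str | None = None

    @property
    def n_scans(self) -> int:
        return self.intensities.shape[1]

    def profile(self, label: str) -> np.ndarray:
        for i, t in enumerate(self.targets):
            if t.label == label:
                return self.intensities[i]
        raise KeyError(f"no target labelled {label!r}")

    def normalized(self, mode: str = "max") -> "DepthProfile":
        """'max': per-target division by its maximum (values in [0,1]);
        'total-ion': per-scan division by the scan's total ion count."""
        x = self.intensities.astype(float).copy()
        if mode == "max":
            m = x.max(axis=1, keepdims=True)
            m[m == 0] = 1.0
            x = x / m
        elif mode == "total-ion":
            raise ValueError("total-ion normalization needs the scans; "
                             "use targeted_profile(..., normalize='total-ion')")
        else:
            raise ValueError(f"unknown normalization: {mode!r}")
        return DepthProfile(self.targets, x, normalization=mode)


def targeted_profile(
    scans: Sequence[Spectrum],
    targets: Sequence[TargetIon],
    normalize: str | None = None,
) -> DepthProfile:
    """Per-scan summed intensity of each target ion.

    All scans must share polarity. A scan with no peak within tolerance
    contributes 0 for that target.
    """
    if not scans:
        raise ValueError("at least one scan is required")
    polarities = {s.polarity for s in scans}
    if len(polarities) > 1:
        raise ValueError(f"scans mix polarities: {sorted(polarities)}")
    out = np.zeros((len(targets), len(scans)))
    for si, scan in enumerate(scans):
        mz = scan.mz
        inten = scan.intensity
        for ti, t in enumerate(targets):
            half = t.tolerance.window(t.mz)
            lo = int(np.searchsorted(mz, t.mz - half, side="left"))
            hi = int(np.searchsorted(mz, t.mz + half, side="right"))
            if hi > lo:
                out[ti, si] = float(inten[lo:hi].sum())
    profile = DepthProfile(list(targets), out)
    if normalize == "max":
        profile = profile.normalized("max")
    elif normalize == "total-ion":
        totals = np.array([s.intensity.sum() if len(s) else 1.0 for s in scans])
        totals[totals == 0] = 1.0
        profile = DepthProfile(list(targets), out / totals, normalization="total-ion")
    elif normalize is not None:
        raise ValueError(f"unknown normalization: {normalize!r}")
    return profile


def moving_average(x: np.ndarray, width: int = 3) -> np.ndarray:
    """Centered moving average with edge truncation (window shrinks at
    the ends), so a step stays a monotone ramp of the same height."""
    n = len(x)
    half = width // 2
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        out[i] = x[lo:hi].mean()
    return out


def segment_layers(
    marker: np.ndarray | Sequence[float], threshold_fraction: float = 0.5
) -> list[int]:
    """Scan indices where the smoothed marker profile crosses
    threshold_fraction x its maximum.

    Returns the index of the first scan *after* each crossing, i.e. a
    boundary ``b`` separates scans ``b-1`` and ``b`` (0-based). A flat
    all-zero profile yields no boundaries.
    """
    marker = np.asarray(marker, dtype=float)
    if marker.size == 0:
        raise ValueError("marker profile is empty")
    if not 0 < threshold_fraction < 1:
        raise ValueError("threshold_fraction must lie in (0, 1)")
    smooth = moving_average(marker, 3)
    peak = smooth.max()
    if peak <= 0:
        return []
    level = threshold_fraction * peak
    above = smooth >= level
    boundaries = [
        i for i in range(1, len(above)) if above[i] != above[i - 1]
    ]
    return boundaries
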