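"""Background removal for SIMS peak lists.

Two independent filters, applied before ladder detection:

* intensity filtering removes the low-intensity background hump
  (absolute threshold, percentile of the intensity distribution, or a
  multiple of the median intensity);
* chemical filtering keeps peptide-plausible peaks. The default
  "difference-participation" mode keeps exactly the peaks that have at
  least one partner peak whose m/z difference matches a residue mass
  within tolerance — the precondition for appearing in any sequence
  ladder, so it cannot discard signal used downstream. A secondary
  mass-defect-window mode keeps peaks whose fractional mass lies within
  a band around the peptide mass-defect line.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mass_core import ResidueTable, Tolerance, default_table
from .spectra_io import Spectrum


@dataclass
class FilterConfig:
    intensity_mode: str = "percentile"  # absolute | percentile | median-multiple
    intensity_threshold: float = 60.0
    chemical_mode: str = "difference-participation"  # or mass-defect-window | off
    tolerance: Tolerance = field(default_factory=Tolerance)
    # mass-defect-window parameters: fractional mass expected near
    # slope * mz; peaks kept when |frac(mz) - slope*mz| <= half_width
    defect_slope: float = 0.00048
    defect_half_width: float = 0.25

    def __post_init__(self):
        if self.intensity_threshold < 0:
            raise ValueError("intensity threshold must be >= 0")
        if self.intensity_mode == "percentile" and not (
            0 <= self.intensity_threshold <= 100
        ):
            raise ValueError("percentile must lie in [0, 100]")


def intensity_filter(s: Spectrum, cfg: FilterConfig) -> Spectrum:
    """Drop peaks below the configured intensity cutoff."""
    if len(s) == 0:
        return s.subset([])
    intensities = s.intensity
    mode = cfg.intensity_mode
    if mode == "absolute":
        cutoff = cfg.intensity_threshold
    elif mode == "percentile":
        # linear-interpolation percentile (numpy default definition)
        cutoff = float(np.percentile(intensities, cfg.intensity_threshold))
    elif mode == "median-multiple":
        cutoff = cfg.intensity_threshold * float(np.median(intensities))
    else:
        raise ValueError(f"unknown intensity mode: {mode!r}")
    keep = [i for i, x in enumerate(intensities) if x >= cutoff]
    return s.subset(keep)


def difference_participation(
    s: Spectrum, table: ResidueTable, tol: Tolerance
) -> list[int]:
    """Indices of peaks with >= 1 partner at a residue-mass difference.

    Sorted two-pointer sweep per residue mass; O(R * n) with tight
    windows instead of the all-pairs scan. The gap window is the same
    absolute step window used by the ladder graph, so no ladder member
    can be lost here.
    """
    mz = s.mz
    n = len(mz)
    keep = np.zeros(n, dtype=bool)
    half = tol.step_window()
    masses = sorted(m for _, m in table.items())
    for rm in masses:
        for i in range(n):
            target = mz[i] + rm
            lo = int(np.searchsorted(mz, target - half, side="left"))
            hi = int(np.searchsorted(mz, target + half, side="right"))
            if hi > lo:
                keep[i] = True
                keep[lo:hi] = True
    return [i for i in range(n) if keep[i]]


def chemical_filter(
    s: Spectrum, table: ResidueTable | None = None, cfg: FilterConfig | None = None
) -> Spectrum:
    """Keep peptide-plausible peaks (see module docstring for modes)."""
    table = table or default_table()
    cfg = cfg or FilterConfig()
    mode = cfg.chemical_mode
    if mode == "off" or len(s) == 0:
        return s.subset(range(len(s)))
    if mode == "difference-participation":
        return s.subset(difference_participation(s, table, cfg.tolerance))
    if mode == "mass-defect-window":
        keep = []
        for i, p in enumerate(s.peaks):
            frac = p.mz - np.floor(p.mz)
            expected = cfg.defect_slope * p.mz
            dev = frac - expected
            # fractional mass wraps at 1
            dev = dev - np.round(dev)
            if abs(dev) <= cfg.defect_half_width:
                keep.append(i)
        return s.subset(keep)
    raise ValueError(f"unknown chemical mode: {mode!r}")


def apply_filters(
    s: Spectrum, table: ResidueTable | None = None, cfg: FilterConfig | None = None
) -> Spectrum:
    """Intensity filter then chemical filter, the standard preprocessing."""
    cfg = cfg or FilterConfig()
    return chemical_filter(intensity_filter(s, cfg), table, cfg)
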