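"""Plain-text (YAML) analysis configuration.

A config file collects the knobs shared across a run: ppm tolerance,
residue-table variants, ion series, adducts, and filter settings.
Example::

    tolerance_ppm: 2.0
    variants:
      hydroxyproline: true
      disulfide-variants: false
    filter:
      intensity_mode: percentile
      intensity_threshold: 60
      chemical_mode: difference-participation
    tagging:
      min_len: 3
      max_tags: 5000
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .filtering import FilterConfig
from .mass_core import ResidueTable, Tolerance


@dataclass
class AnalysisConfig:
    tolerance: Tolerance = field(default_factory=Tolerance)
    table: ResidueTable = field(default_factory=ResidueTable.default)
    filter: FilterConfig = field(default_factory=FilterConfig)
    min_tag_len: int = 3
    max_tags: int = 5000


def load_config(path: str | Path | None) -> AnalysisConfig:
    """Build an AnalysisConfig from a YAML file (or defaults if None)."""
    if path is None:
        return AnalysisConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    tol = Tolerance(float(raw.get("tolerance_ppm", 2.0)))
    variants = raw.get("variants", {}) or {}
    table = ResidueTable.default(
        hydroxyproline=bool(variants.get("hydroxyproline", False)),
        methoxyproline=bool(variants.get("methoxyproline", False)),
        disulfide_variants=bool(variants.get("disulfide-variants", False)),
        merge_tol_ppm=tol.ppm,
    )
    fraw = raw.get("filter", {}) or {}
    fcfg = FilterConfig(
        intensity_mode=fraw.get("intensity_mode", "percentile"),
        intensity_threshold=float(fraw.get("intensity_threshold", 60.0)),
        chemical_mode=fraw.get("chemical_mode", "difference-participation"),
        tolerance=tol,
    )
    traw = raw.get("tagging", {}) or {}
    return AnalysisConfig(
        tolerance=tol,
        table=table,
        filter=fcfg,
        min_tag_len=int(traw.get("min_len", 3)),
        max_tags=int(traw.get("max_tags", 5000)),
    )
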