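"""Mass arithmetic for singly charged SIMS peptide fragments.

Everything downstream (filtering, tagging, identification, simulation)
reduces to three pieces of arithmetic housed here:

* monoisotopic residue masses, including modified/variant residues
  (hydroxyproline, methoxyproline, the disulfide-cleavage cysteine
  variants) and the isobaric I/L group;
* ion-series neutral offsets for N-terminal (a, b, c), C-terminal
  (x, y, z, z+1, z+2) and internal (yb, ya, yc, ya-NH3) fragments;
* adduct deltas (+H, +Na, -H) and ppm tolerance tests.

Conventions: all ions are singly charged; adduct deltas include the
electron mass (a cation's m/z is the neutral fragment mass plus the
cation mass, i.e. atom mass minus one electron), so theoretical values
are physically exact for an Orbitrap-class analyser.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

from pyteomics import mass as _pmass

# -- elemental / small-molecule monoisotopic masses (pyteomics NIST table) --
MASS_H = _pmass.calculate_mass(formula="H")
MASS_H2O = _pmass.calculate_mass(formula="H2O")
MASS_CO = _pmass.calculate_mass(formula="CO")
MASS_NH3 = _pmass.calculate_mass(formula="NH3")
MASS_O = _pmass.calculate_mass(formula="O")
MASS_S = _pmass.calculate_mass(formula="S")
MASS_CH2O = _pmass.calculate_mass(formula="CH2O")
MASS_PROTON = _pmass.nist_mass["H+"][0][0]
MASS_ELECTRON = _pmass.nist_mass["e*"][0][0]
MASS_NA = _pmass.nist_mass["Na"][0][0]

#: m/z gap between the +Na and +H forms of the same fragment:
#: (Na - e) - proton. Not exactly Na minus the H *atom* mass — the
#: atomic mass includes the 1.5e-8 Da electron binding energy.
NA_MINUS_H = (MASS_NA - MASS_ELECTRON) - MASS_PROTON  # 21.98194...


class ResidueKind(str, Enum):
    STANDARD = "standard"
    MODIFIED = "modified"
    AMBIGUOUS = "ambiguous-group"


@dataclass(frozen=True)
class ResidueEntry:
    code: str
    mass: float
    kind: ResidueKind
    #: single-letter codes subsumed by an ambiguous group (e.g. J -> I, L)
    members: tuple[str, ...] = ()


class UnknownResidueError(KeyError):
    """Residue code absent from the active table."""

    def __init__(self, code: str):
        super().__init__(code)
        self.code = code

    def __str__(self) -> str:  # KeyError repr-quotes its arg; be explicit
        return f"unknown residue code: {self.code!r}"


# Variant residue masses, relative to their parent residue.
_HYP_MASS = _pmass.std_aa_mass["P"] + MASS_O  # hydroxyproline
_MEP_MASS = _pmass.std_aa_mass["P"] + MASS_CH2O  # methoxyproline
_C_MINUS_SH2 = _pmass.std_aa_mass["C"] - (MASS_S + 2 * MASS_H)  # R-SH2 loss
_C_PLUS_S = _pmass.std_aa_mass["C"] + MASS_S  # R-S disulfide remnant


class ResidueTable:
    """Monoisotopic residue masses keyed by residue code.

    The default table holds the 20 standard residues with isoleucine and
    leucine collapsed into the ambiguous group ``J`` (they are exactly
    isobaric). Lysine and glutamine differ by 0.03638 Da and stay
    distinct: at 2 ppm they are only confusable above m/z ~ 9000, beyond
    the mass range considered here. Optional variants (hydroxyproline
    ``Hyp``, methoxyproline ``Mep``, cysteine disulfide-cleavage
    products ``C-SH2``/``C+S``) can be enabled per analysis.
    """

    #: residue pairs are merged when their masses differ by less than the
    #: two-sided ppm window at this reference m/z.
    DEFAULT_MERGE_REF_MZ = 1000.0

    def __init__(
        self,
        entries: Iterable[ResidueEntry],
        merge_tol_ppm: float = 2.0,
        merge_ref_mz: float = DEFAULT_MERGE_REF_MZ,
    ):
        self.entries: dict[str, ResidueEntry] = {}
        for e in entries:
            if e.mass <= 0:
                raise ValueError(f"residue {e.code!r} has non-positive mass")
            self.entries[e.code] = e
        self._check_merge(merge_tol_ppm, merge_ref_mz)

    def _check_merge(self, tol_ppm: float, ref_mz: float) -> None:
        # two residues both match one observed gap when their masses differ
        # by less than the full two-sided window
        window = 2.0 * tol_ppm * ref_mz / 1e6
        codes = sorted(self.entries)
        for i, a in enumerate(codes):
            for b in codes[i + 1 :]:
                if abs(self.entries[a].mass - self.entries[b].mass) < window:
                    raise ValueError(
                        f"residues {a!r} and {b!r} are isobaric within "
                        f"{tol_ppm} ppm at m/z {ref_mz}; collapse them into "
                        "an ambiguous group before building the table"
                    )

    # mapping-ish surface -------------------------------------------------
    def __contains__(self, code: str) -> bool:
        return code in self.entries

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def mass(self, code: str) -> float:
        try:
            return self.entries[code].mass
        except KeyError:
            raise UnknownResidueError(code) from None

    def items(self):
        return {c: e.mass for c, e in self.entries.items()}.items()

    def collapse(self, sequence: str) -> str:
        """Rewrite a plain-letter sequence into this table's alphabet
        (e.g. I and L both become J under the default table)."""
        sub = {}
        for e in self.entries.values():
            for m in e.members:
                sub[m] = e.code
        return "".join(sub.get(ch, ch) for ch in sequence)

    def to_text(self) -> str:
        """Dump the table as aligned text for inspection."""
        lines = ["code\tmass_da\tkind\tmembers"]
        for code in sorted(self.entries):
            e = self.entries[code]
            lines.append(
                f"{code}\t{e.mass:.5f}\t{e.kind.value}\t{''.join(e.members)}"
            )
        return "\n".join(lines) + "\n"

    @classmethod
    def default(
        cls,
        hydroxyproline: bool = False,
        methoxyproline: bool = False,
        disulfide_variants: bool = False,
        merge_tol_ppm: float = 2.0,
    ) -> "ResidueTable":
        entries = []
        standard = dict(_pmass.std_aa_mass)
        # std_aa_mass includes rare residues (O/U) in some versions; keep
        # the 20 standard ones, with I/L always collapsed (exactly isobaric)
        keep = set("ACDEFGHKMNPQRSTVWY")
        for code in sorted(keep):
            entries.append(ResidueEntry(code, standard[code], ResidueKind.STANDARD))
        entries.append(
            ResidueEntry("J", standard["I"], ResidueKind.AMBIGUOUS, members=("I", "L"))
        )
        if hydroxyproline:
            entries.append(ResidueEntry("Hyp", _HYP_MASS, ResidueKind.MODIFIED))
        if methoxyproline:
            entries.append(ResidueEntry("Mep", _MEP_MASS, ResidueKind.MODIFIED))
        if disulfide_variants:
            entries.append(ResidueEntry("C-SH2", _C_MINUS_SH2, ResidueKind.MODIFIED))
            entries.append(ResidueEntry("C+S", _C_PLUS_S, ResidueKind.MODIFIED))
        return cls(entries, merge_tol_ppm=merge_tol_ppm)


def residue_mass(code: str, table: ResidueTable | None = None) -> float:
    """Monoisotopic residue mass in Da; raises UnknownResidueError."""
    if table is None:
        table = default_table()
    return table.mass(code)


# --- ion series --------------------------------------------------------


class Terminus(str, Enum):
    N = "N"
    C = "C"
    INTERNAL = "internal"


@dataclass(frozen=True)
class IonSeries:
    """A fragment-ion series: name, terminus class, and the neutral mass
    offset added to the summed residue masses.

    b has offset 0 and y has offset +H2O (terminal H/OH absorbed into the
    offsets). The remaining series follow the standard relations
    a = b - CO, c = b + NH3, x = y + CO - H2, z = y - NH3, z+1 = z + H,
    z+2 = z + 2H; internal yb-type ions carry offset 0 and ya / yc /
    ya-NH3 are -CO / +NH3 / -CO-NH3 relative to yb.
    """

    name: str
    terminus: Terminus
    neutral_offset: float


ION_SERIES: dict[str, IonSeries] = {
    "b": IonSeries("b", Terminus.N, 0.0),
    "a": IonSeries("a", Terminus.N, -MASS_CO),
    "c": IonSeries("c", Terminus.N, MASS_NH3),
    "y": IonSeries("y", Terminus.C, MASS_H2O),
    "x": IonSeries("x", Terminus.C, MASS_H2O + MASS_CO - 2 * MASS_H),
    "z": IonSeries("z", Terminus.C, MASS_H2O - MASS_NH3),
    "z+1": IonSeries("z+1", Terminus.C, MASS_H2O - MASS_NH3 + MASS_H),
    "z+2": IonSeries("z+2", Terminus.C, MASS_H2O - MASS_NH3 + 2 * MASS_H),
    "z-H": IonSeries("z-H", Terminus.C, MASS_H2O - MASS_NH3 - MASS_H),
    "internal-yb": IonSeries("internal-yb", Terminus.INTERNAL, 0.0),
    "internal-ya": IonSeries("internal-ya", Terminus.INTERNAL, -MASS_CO),
    "internal-yc": IonSeries("internal-yc", Terminus.INTERNAL, MASS_NH3),
    "internal-ya-NH3": IonSeries(
        "internal-ya-NH3", Terminus.INTERNAL, -MASS_CO - MASS_NH3
    ),
}


def ion_series(name: str) -> IonSeries:
    try:
        return ION_SERIES[name]
    except KeyError:
        raise KeyError(f"unknown ion series: {name!r}") from None


# --- adducts ------------------------------------------------------------


@dataclass(frozen=True)
class Adduct:
    name: str
    charge: int  # +1 or -1
    delta: float  # m/z delta added to the neutral fragment mass


ADDUCTS: dict[str, Adduct] = {
    "+H": Adduct("+H", +1, MASS_PROTON),
    "+Na": Adduct("+Na", +1, MASS_NA - MASS_ELECTRON),
    "-H": Adduct("-H", -1, -MASS_PROTON),
}


def adduct(name: str) -> Adduct:
    try:
        return ADDUCTS[name]
    except KeyError:
        raise KeyError(f"unknown adduct: {name!r}") from None


# --- tolerance ----------------------------------------------------------


#: fixed reference m/z at which the relative tolerance is converted to
#: the absolute window used for residue-gap (ladder-step) matching
STEP_REFERENCE_MZ = 1000.0


@dataclass(frozen=True)
class Tolerance:
    """Relative mass tolerance, ppm = 1e6 * (obs - theo) / theo.

    Two windows derive from it. Absolute peak positions are matched
    within ``window(mz)``, the ppm band at the peak's own m/z. Ladder
    *steps* (gaps between peaks) are matched within the constant
    ``step_window()`` — the ppm band evaluated at a fixed reference m/z
    (2 ppm -> +/- 2 mDa), the usual absolute fragment-gap tolerance.
    A constant gap window keeps the residue-difference graph strictly
    identical under a global adduct exchange (every gap is unchanged
    when +H is swapped for +Na), which a peak-anchored window would
    break for near-boundary coincidences.
    """

    ppm: float = 2.0

    def __post_init__(self):
        if self.ppm <= 0:
            raise ValueError("tolerance must be strictly positive")

    def window(self, mz: float) -> float:
        """Absolute half-width of the window at a given m/z."""
        return self.ppm * mz / 1e6

    def step_window(self) -> float:
        """Absolute half-width for residue-gap matching, in Da."""
        return self.ppm * STEP_REFERENCE_MZ / 1e6


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return 1e6 * (observed - theoretical) / theoretical


def within_tolerance(observed: float, theoretical: float, tol: Tolerance) -> bool:
    return abs(ppm_error(observed, theoretical)) <= tol.ppm


# --- fragment m/z -------------------------------------------------------


def fragment_mass(
    peptide: str | Iterable[str], series: IonSeries | str, table: ResidueTable
) -> float:
    """Neutral fragment mass: sum of residue masses plus series offset."""
    if isinstance(series, str):
        series = ion_series(series)
    codes = list(peptide)
    if not codes:
        raise ValueError("empty peptide")
    return sum(table.mass(c) for c in codes) + series.neutral_offset


def fragment_mz(
    peptide: str | Iterable[str],
    series: IonSeries | str,
    adduct_: Adduct | str,
    table: ResidueTable | None = None,
) -> float:
    """m/z of a singly charged fragment ion.

    `peptide` is a residue-code string (or iterable of codes, required
    for multi-character variant codes such as "Hyp").
    """
    if table is None:
        table = default_table()
    if isinstance(adduct_, str):
        adduct_ = adduct(adduct_)
    return fragment_mass(peptide, series, table) + adduct_.delta


_DEFAULT_TABLE: ResidueTable | None = None


def default_table() -> ResidueTable:
    """The shared default residue table (20 standard residues, I/L as J)."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = ResidueTable.default()
    return _DEFAULT_TABLE
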