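"""Peak-list, FASTA and report I/O.

Peak lists arrive as two-column CSV/TSV exports (m/z, intensity; header
optional; an optional third column carries a scan index for depth
profiles) or as centroided mzML. Protein databases are FASTA. Reports
are written as TSV or JSON with deterministic column order and fixed
float precision so runs are diffable.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

#: peaks closer than this in m/z are merged on read (intensities summed)
MERGE_EPS = 1e-6

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float
    scan: int | None = None

    def __post_init__(self):
        if self.mz <= 0:
            raise ValueError(f"peak m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"peak intensity must be non-negative")


@dataclass
class Spectrum:
    """An m/z-sorted centroided peak list with polarity and metadata."""

    peaks: list[Peak] = field(default_factory=list)
    polarity: str = "positive"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.polarity not in ("positive", "negative"):
            raise ValueError("polarity must be 'positive' or 'negative'")
        self.peaks = _normalize_peaks(self.peaks)

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def mz(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks])

    @property
    def intensity(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks])

    def subset(self, indices: Iterable[int]) -> "Spectrum":
        idx = sorted(set(indices))
        return Spectrum(
            peaks=[self.peaks[i] for i in idx],
            polarity=self.polarity,
            metadata=dict(self.metadata),
        )


def _normalize_peaks(peaks: Sequence[Peak]) -> list[Peak]:
    """Sort by m/z and merge peaks closer than MERGE_EPS (sum intensities)."""
    out: list[Peak] = []
    for p in sorted(peaks, key=lambda p: p.mz):
        if out and p.mz - out[-1].mz < MERGE_EPS:
            prev = out[-1]
            out[-1] = Peak(prev.mz, prev.intensity + p.intensity, prev.scan)
        else:
            out.append(p)
    return out


@dataclass(frozen=True)
class ProteinRecord:
    identifier: str
    description: str
    sequence: str


class FastaAlphabetError(ValueError):
    def __init__(self, record_id: str, position: int, char: str):
        super().__init__(
            f"record {record_id!r}: invalid residue {char!r} at position {position}"
        )
        self.record_id = record_id
        self.position = position
        self.char = char


# --- peak lists -----------------------------------------------------------


def read_peaklist(path: str | Path, format: str | None = None) -> Spectrum:
    """Read a single-spectrum peak list (CSV/TSV two columns, or mzML).

    Format is inferred from the extension when not given. Multi-scan
    files should go through :func:`read_scan_series` instead.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "mzml":
        scans = read_mzml(path)
        if not scans:
            return Spectrum()
        if len(scans) > 1:
            raise ValueError(
                f"{path} contains {len(scans)} spectra; use read_scan_series"
            )
        return scans[0]
    return _read_delimited(path, fmt)


def read_scan_series(path: str | Path, format: str | None = None) -> list[Spectrum]:
    """Read a multi-scan depth-profile series, one Spectrum per scan.

    A delimited file uses a third column as the 0-based scan index;
    mzML yields one Spectrum per contained spectrum, in file order.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "mzml":
        return read_mzml(path)
    df = _load_table(path, fmt)
    if df.empty:
        return []
    if "scan" not in df.columns:
        return [_frame_to_spectrum(df)]
    return [
        _frame_to_spectrum(g)
        for _, g in df.groupby("scan", sort=True)
    ]


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".mzml":
        return "mzml"
    if suffix == ".tsv":
        return "tsv"
    return "csv"


def _load_table(path: Path, fmt: str) -> pd.DataFrame:
    text = Path(path).read_text()
    if not text.strip():
        return pd.DataFrame(columns=["mz", "intensity"])
    sep = "\t" if fmt == "tsv" else ","
    # auto-detect the other delimiter if the declared one is absent
    first = text.splitlines()[0]
    if sep not in first:
        other = "," if sep == "\t" else "\t"
        if other in first:
            sep = other
    has_header = _looks_like_header(first, sep)
    try:
        df = pd.read_csv(
            io.StringIO(text),
            sep=sep,
            header=0 if has_header else None,
            comment="#",
        )
    except Exception as exc:  # pragma: no cover - pandas error paths vary
        raise ValueError(f"cannot parse peak list {path}: {exc}") from exc
    if has_header:
        df.columns = [str(c).strip().lower() for c in df.columns]
        rename = {"m/z": "mz", "mass": "mz", "int": "intensity"}
        df = df.rename(columns=rename)
    else:
        names = ["mz", "intensity", "scan"][: df.shape[1]]
        df.columns = names
    if "mz" not in df.columns or "intensity" not in df.columns:
        raise ValueError(f"{path}: expected columns mz,intensity[,scan]")
    for i, row in df.iterrows():
        try:
            float(row["mz"]), float(row["intensity"])
        except (TypeError, ValueError):
            line = i + 2 if has_header else i + 1
            raise ValueError(f"{path}: unparseable row at line {line}") from None
    return df


def _looks_like_header(line: str, sep: str) -> bool:
    try:
        float(line.split(sep)[0])
        return False
    except ValueError:
        return True


def _frame_to_spectrum(df: pd.DataFrame, polarity: str = "positive") -> Spectrum:
    scan_col = df["scan"] if "scan" in df.columns else None
    peaks = [
        Peak(
            float(r.mz),
            float(r.intensity),
            int(r.scan) if scan_col is not None else None,
        )
        for r in df.itertuples()
    ]
    return Spectrum(peaks=peaks, polarity=polarity)


def _read_delimited(path: Path, fmt: str) -> Spectrum:
    df = _load_table(path, fmt)
    if "scan" in df.columns and df["scan"].nunique() > 1:
        raise ValueError(f"{path} has multiple scans; use read_scan_series")
    return _frame_to_spectrum(df)


def write_peaklist(spectrum: Spectrum, path: str | Path) -> None:
    """Write a spectrum as CSV (mz,intensity[,scan]) at fixed precision."""
    path = Path(path)
    has_scan = any(p.scan is not None for p in spectrum.peaks)
    with open(path, "w") as fh:
        fh.write("mz,intensity,scan\n" if has_scan else "mz,intensity\n")
        for p in spectrum.peaks:
            if has_scan:
                fh.write(f"{p.mz:.6f},{p.intensity:.6f},{p.scan or 0}\n")
            else:
                fh.write(f"{p.mz:.6f},{p.intensity:.6f}\n")


def read_mzml(path: str | Path) -> list[Spectrum]:
    """Read centroided spectra from mzML; profile-mode data is rejected.

    Minimal reader for the centroided subset of mzML (64-bit float
    arrays, zlib or no compression), built directly on lxml.
    """
    import base64
    import struct
    import zlib

    from lxml import etree

    ns = "{http://psi.hupo.org/ms/mzml}"

    def cv_names(elem):
        return {cv.get("name") for cv in elem.iter(f"{ns}cvParam")}

    def decode_array(bda):
        names = cv_names(bda)
        binary = bda.find(f"{ns}binary")
        raw = base64.b64decode((binary.text or "").strip())
        if "zlib compression" in names:
            raw = zlib.decompress(raw)
        if "64-bit float" in names:
            fmt, width = "d", 8
        elif "32-bit float" in names:
            fmt, width = "f", 4
        else:
            raise ValueError(f"{path}: unsupported binary data encoding")
        return struct.unpack(f"<{len(raw) // width}{fmt}", raw), names

    out: list[Spectrum] = []
    tree = etree.parse(str(path))
    for i, spec in enumerate(tree.iter(f"{ns}spectrum")):
        names = cv_names(spec)
        if "profile spectrum" in names:
            raise ValueError(
                f"{path}: spectrum {i} is profile-mode; centroid it first"
            )
        polarity = "negative" if "negative scan" in names else "positive"
        mzs, ints = (), ()
        for bda in spec.iter(f"{ns}binaryDataArray"):
            values, anames = decode_array(bda)
            if "m/z array" in anames:
                mzs = values
            elif "intensity array" in anames:
                ints = values
        peaks = [Peak(float(m), float(x), scan=i) for m, x in zip(mzs, ints)]
        out.append(Spectrum(peaks=peaks, polarity=polarity))
    return out


# --- FASTA ----------------------------------------------------------------


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA into records.

    Policy for non-standard letters: terminal ``*`` stripped; ``U``
    (selenocysteine) mapped to ``C``; ``X`` kept (never matched by a
    tag); ``B``/``Z`` and anything else rejected with the position.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace(" ", "")
        if seq.endswith("*"):
            seq = seq[:-1]
        if "U" in seq:
            seq = seq.replace("U", "C")
        for pos, ch in enumerate(seq, start=1):
            if ch not in AA_ALPHABET:
                raise FastaAlphabetError(rec.id, pos, ch)
        if not seq:
            raise ValueError(f"record {rec.id!r} has an empty sequence")
        records.append(
            ProteinRecord(rec.id, rec.description, seq)
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.identifier
            if rec.description and not rec.description.startswith(rec.identifier):
                header = f"{rec.identifier} {rec.description}"
            elif rec.description:
                header = rec.description
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


# --- reports ----------------------------------------------------------------

REPORT_COLUMNS = [
    "protein",
    "score",
    "coverage_percent",
    "n_tags",
    "unique_tags",
    "ambiguous",
]


def write_report(results, path: str | Path, format: str = "tsv") -> None:
    """Write ranked identification results as TSV or JSON.

    Accepts the MatchResult list produced by identify.score_proteins.
    Column order is fixed; floats use 6 decimals.
    """
    rows = [
        {
            "protein": r.protein,
            "score": float(r.score),
            "coverage_percent": int(r.coverage_percent),
            "n_tags": len(r.matches),
            "unique_tags": int(r.unique_tag_count),
            "ambiguous": bool(r.ambiguous),
        }
        for r in results
    ]
    path = Path(path)
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(REPORT_COLUMNS) + "\n")
            for row in rows:
                fh.write(
                    "\t".join(
                        f"{row[c]:.6f}" if isinstance(row[c], float) else str(row[c])
                        for c in REPORT_COLUMNS
                    )
                    + "\n"
                )
    elif format == "json":
        with open(path, "w") as fh:
            json.dump(rows, fh, indent=2)
            fh.write("\n")
    else:
        raise ValueError(f"unknown report format: {format!r}")


def read_report(path: str | Path):
    """Read back a report written by write_report (for round-trips)."""
    path = Path(path)
    if path.suffix == ".json":
        return json.loads(path.read_text())
    df = pd.read_csv(path, sep="\t")
    return df.to_dict(orient="records")
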