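"""Domain types and file I/O shared by every pipeline stage.

Spectra are stored with a strictly decreasing ppm axis (NMR display order).
Window bounds throughout the package are ``(high_ppm, low_ppm)`` and select
the half-open interval ``[high_ppm, low_ppm)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "ValidationError",
    "Spectrum",
    "ProtonGroup",
    "MetaboliteSignature",
    "ConcentrationTable",
    "CohortDesign",
    "read_spectrum",
    "write_spectrum",
    "read_signature_library",
    "write_signature_library",
    "default_signature_library",
    "read_table",
    "write_table",
    "read_concentration_table",
    "packaged_data_path",
]

DEFAULT_FREQUENCY_MHZ = 600.0

UNITS = ("umol_per_L", "umol_per_mmol_creatinine", "area")


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(ValueError):
    """A domain-type invariant was violated."""


def packaged_data_path(name: str) -> Path:
    """Path to a data file shipped inside the package."""
    return Path(__file__).parent / "data" / name


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Spectrum:
    """A frequency-domain real 1H spectrum on a decreasing ppm axis.

    Parameters
    ----------
    sample_id : str
        Identifier carried through to concentration tables.
    ppm : ndarray
        Chemical-shift axis, strictly decreasing.
    intensity : ndarray
        Real intensities, same length as ``ppm``.
    frequency_mhz : float
        Spectrometer proton frequency; converts Hz-valued quantities
        (J-couplings, linewidths) to ppm.
    metadata : dict
        Free-form acquisition tags / QC flags.
    """

    sample_id: str
    ppm: np.ndarray
    intensity: np.ndarray
    frequency_mhz: float = DEFAULT_FREQUENCY_MHZ
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.ndim != 1 or self.intensity.ndim != 1:
            raise ValidationError("ppm and intensity must be 1-D")
        if len(self.ppm) != len(self.intensity):
            raise ValidationError(
                f"length mismatch: {len(self.ppm)} ppm vs {len(self.intensity)} intensity"
            )
        if len(self.ppm) >= 2 and not np.all(np.diff(self.ppm) < 0):
            raise ValidationError("ppm axis must be strictly decreasing")
        if not self.frequency_mhz > 0:
            raise ValidationError("frequency_mhz must be positive")
        if not np.all(np.isfinite(self.intensity)):
            raise ValidationError("intensities must be finite")

    def window_slice(self, high_ppm: float, low_ppm: float) -> slice:
        """Index slice covering the half-open window [high_ppm, low_ppm)."""
        if high_ppm <= low_ppm:
            raise ValueError(f"empty window ({high_ppm}, {low_ppm})")
        # decreasing axis: first index with ppm <= high, first with ppm <= low
        start = int(np.searchsorted(-self.ppm, -high_ppm, side="left"))
        stop = int(np.searchsorted(-self.ppm, -low_ppm, side="left"))
        return slice(start, stop)

    def copy(self) -> "Spectrum":
        return Spectrum(
            self.sample_id,
            self.ppm.copy(),
            self.intensity.copy(),
            self.frequency_mhz,
            dict(self.metadata),
        )


@dataclass(frozen=True)
class ProtonGroup:
    """One group of magnetically equivalent protons.

    ``couplings`` is a tuple of ``(J_hz, m)`` pairs: scalar coupling constant
    and the number of equivalent coupling partners; ``mobility_ppm`` is the
    half-width of the window within which the group centre may drift between
    samples (pH / ionic-strength sensitivity).
    """

    center_ppm: float
    n_protons: int
    couplings: tuple = ()
    mobility_ppm: float = 0.0

    def __post_init__(self) -> None:
        if self.n_protons < 1:
            raise ValidationError("n_protons must be >= 1")
        for j, m in self.couplings:
            if j < 0:
                raise ValidationError(f"negative J coupling: {j}")
            if int(m) < 1:
                raise ValidationError(f"coupling multiplicity must be >= 1, got {m}")
        if self.mobility_ppm < 0:
            raise ValidationError("mobility_ppm must be >= 0")


@dataclass(frozen=True)
class MetaboliteSignature:
    """Prior knowledge for one metabolite: its proton groups."""

    name: str
    groups: tuple
    pathway: str = ""

    def __post_init__(self) -> None:
        if len(self.groups) < 1:
            raise ValidationError(f"signature {self.name!r} has no proton groups")

    @property
    def total_protons(self) -> int:
        return sum(g.n_protons for g in self.groups)


class ConcentrationTable:
    """Samples x metabolites matrix with a unit state and absence mask."""

    def __init__(self, values: pd.DataFrame, units: str, absent_mask: pd.DataFrame | None = None):
        if units not in UNITS:
            raise ValidationError(f"units must be one of {UNITS}, got {units!r}")
        values = values.astype(float)
        if absent_mask is None:
            absent_mask = values.isna()
        absent_mask = absent_mask.astype(bool)
        if not values.index.equals(absent_mask.index) or not values.columns.equals(
            absent_mask.columns
        ):
            raise ValidationError("absent_mask shape must match values")
        present = values.values[~absent_mask.values]
        if np.any(present < 0):
            raise ValidationError("concentrations must be >= 0 where not absent")
        self.values = values
        self.units = units
        self.absent_mask = absent_mask

    @property
    def samples(self) -> list:
        return list(self.values.index)

    @property
    def metabolites(self) -> list:
        return list(self.values.columns)

    def column(self, name: str, drop_absent: bool = True) -> pd.Series:
        col = self.values[name]
        if drop_absent:
            col = col[~self.absent_mask[name]]
        return col

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"ConcentrationTable({len(self.samples)} samples x "
            f"{len(self.metabolites)} metabolites, units={self.units})"
        )


@dataclass
class CohortDesign:
    """Maps samples to individuals, replicate groups and collection days.

    ``samples`` is indexed by sample_id with columns ``individual``,
    ``replicate_group`` (nullable) and ``collection_day`` (int);
    ``covariates`` is indexed by individual (e.g. ``sex``, ``bmi``).
    """

    samples: pd.DataFrame
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        if "individual" not in self.samples.columns:
            raise ValidationError("design needs an 'individual' column")
        if self.samples.index.has_duplicates:
            raise ValidationError("each sample maps to exactly one individual")
        if "replicate_group" not in self.samples.columns:
            self.samples = self.samples.assign(replicate_group=pd.NA)
        if "collection_day" not in self.samples.columns:
            self.samples = self.samples.assign(collection_day=0)

    def require_covariates(self, names) -> pd.DataFrame:
        missing = [n for n in names if n not in self.covariates.columns]
        if missing:
            raise ValidationError(f"missing covariates: {missing}")
        used = self.samples["individual"].unique()
        sub = self.covariates.loc[list(used), list(names)]
        if sub.isna().any().any():
            raise ValidationError("covariates incomplete for some individuals")
        return sub


# ---------------------------------------------------------------------------
# Spectrum I/O
# ---------------------------------------------------------------------------


def _orient(ppm: np.ndarray, intensity: np.ndarray):
    if len(ppm) >= 2 and ppm[0] < ppm[-1]:
        return ppm[::-1].copy(), intensity[::-1].copy()
    return ppm, intensity


def read_spectrum(path, format: str | None = None, frequency_mhz: float | None = None,
                  sample_id: str | None = None) -> Spectrum:
    """Read a spectrum from two-column text or a simple JCAMP-DX file.

    ``format`` is ``"xy_text"`` or ``"jcamp"``; inferred from the extension
    (.jdx/.dx/.jcamp -> jcamp) when omitted. An ascending source axis is
    reversed to the package's decreasing convention.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "jcamp" if path.suffix.lower() in (".jdx", ".dx", ".jcamp") else "xy_text"
    if sample_id is None:
        sample_id = path.stem
    if format == "xy_text":
        return _read_xy_text(path, frequency_mhz, sample_id)
    if format == "jcamp":
        return _read_jcamp(path, frequency_mhz, sample_id)
    raise ValueError(f"unsupported format {format!r}")


def _read_xy_text(path: Path, frequency_mhz, sample_id) -> Spectrum:
    ppm, intens = [], []
    freq = frequency_mhz
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = re.match(r"#\s*frequency_mhz\s*[:=]\s*([0-9.eE+-]+)", line)
                if m and frequency_mhz is None:
                    freq = float(m.group(1))
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected two columns, got {line!r}")
            try:
                ppm.append(float(parts[0]))
                intens.append(float(parts[1]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    if not ppm:
        raise ParseError(f"{path}: no data rows")
    x, y = _orient(np.array(ppm), np.array(intens))
    return Spectrum(sample_id, x, y, freq if freq is not None else DEFAULT_FREQUENCY_MHZ)


def write_spectrum(spectrum: Spectrum, path) -> None:
    """Write a spectrum as two-column text (full float precision)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# sample_id: {spectrum.sample_id}\n")
        fh.write(f"# frequency_mhz: {spectrum.frequency_mhz:.17g}\n")
        for x, y in zip(spectrum.ppm, spectrum.intensity):
            fh.write(f"{x:.17g}\t{y:.17g}\n")


_JCAMP_NUM = re.compile(r"[+-]?\d+\.?\d*(?:[eE][+-]?\d+)?")


def _read_jcamp(path: Path, frequency_mhz, sample_id) -> Spectrum:
    """Minimal JCAMP-DX reader: AFFN ``(X++(Y..Y))`` XYDATA or NTUPLES
    ``(X++(R..R))`` data tables only (compressed DIFDUP forms rejected)."""
    headers: dict[str, str] = {}
    ys: list[float] = []
    in_data = False
    data_lineno = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("##"):
                if in_data and (line.startswith("##END") or line.startswith("##PAGE")):
                    in_data = False
                key, _, val = line[2:].partition("=")
                key = key.strip().upper().replace(" ", "")
                val = val.strip()
                headers[key] = val
                if key == "XYDATA" or key == "DATATABLE":
                    if "X++" not in val.replace(" ", ""):
                        raise ParseError(f"{path}:{lineno}: unsupported data form {val!r}")
                    in_data = True
                    data_lineno = lineno
                continue
            if in_data:
                nums = _JCAMP_NUM.findall(line)
                if len(nums) < 2:
                    raise ParseError(f"{path}:{lineno}: unparsable data line {line!r}")
                ys.extend(float(v) for v in nums[1:])  # leading value is the X check value
    if not ys:
        raise ParseError(f"{path}: no XYDATA block found (line {data_lineno or '?'})")
    try:
        firstx = float(headers["FIRSTX"])
        lastx = float(headers["LASTX"])
        npoints = int(float(headers["NPOINTS"]))
    except KeyError as exc:
        raise ParseError(f"{path}: missing JCAMP header ##{exc.args[0]}") from None
    if npoints != len(ys):
        raise ParseError(f"{path}: NPOINTS={npoints} but {len(ys)} Y values read")
    xfactor = float(headers.get("XFACTOR", 1.0))
    yfactor = float(headers.get("YFACTOR", 1.0))
    x = np.linspace(firstx, lastx, npoints) * xfactor
    y = np.asarray(ys) * yfactor
    freq = frequency_mhz
    if freq is None:
        for key in (".OBSERVEFREQUENCY", "OBSERVEFREQUENCY"):
            if key in headers:
                m = _JCAMP_NUM.search(headers[key])
                if m:
                    freq = float(m.group(0))
                    break
    x, y = _orient(x, y)
    return Spectrum(sample_id, x, y, freq if freq is not None else DEFAULT_FREQUENCY_MHZ)


# ---------------------------------------------------------------------------
# Signature library I/O
# ---------------------------------------------------------------------------

_LIB_COLUMNS = ["metabolite", "pathway", "center_ppm", "n_protons", "couplings", "mobility_ppm"]


def _parse_couplings(text: str) -> tuple:
    text = (text or "").strip()
    if not text or text == "-":
        return ()
    out = []
    for token in text.split(";"):
        token = token.strip()
        if not token:
            continue
        try:
            j, m = token.split(":")
            out.append((float(j), int(m)))
        except ValueError:
            raise ParseError(f"bad coupling token {token!r} (expected 'J_hz:m')") from None
    return tuple(out)


def _format_couplings(couplings) -> str:
    return ";".join(f"{j:g}:{m}" for j, m in couplings)


def read_signature_library(path) -> list:
    """Read a TSV signature library: one row per proton group.

    Columns: metabolite, pathway, center_ppm, n_protons, couplings
    (``J:m;J:m`` or empty), mobility_ppm. Rows of the same metabolite are
    consecutive groups. Duplicate metabolite blocks are rejected.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    missing = [c for c in _LIB_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    signatures: list[MetaboliteSignature] = []
    seen: set[str] = set()
    current: str | None = None
    groups: list[ProtonGroup] = []
    pathway = ""

    def flush():
        if current is not None:
            signatures.append(
                MetaboliteSignature(name=current, groups=tuple(groups), pathway=pathway)
            )

    for row in df.itertuples():
        name = str(row.metabolite)
        if name != current:
            flush()
            if name in seen:
                raise ValidationError(f"duplicate metabolite name {name!r}")
            seen.add(name)
            current, groups, pathway = name, [], str(row.pathway)
        groups.append(
            ProtonGroup(
                center_ppm=float(row.center_ppm),
                n_protons=int(row.n_protons),
                couplings=_parse_couplings(row.couplings),
                mobility_ppm=float(row.mobility_ppm),
            )
        )
    flush()
    return signatures


def write_signature_library(signatures, path) -> None:
    rows = []
    for sig in signatures:
        for g in sig.groups:
            rows.append(
                {
                    "metabolite": sig.name,
                    "pathway": sig.pathway,
                    "center_ppm": g.center_ppm,
                    "n_protons": g.n_protons,
                    "couplings": _format_couplings(g.couplings),
                    "mobility_ppm": g.mobility_ppm,
                }
            )
    pd.DataFrame(rows, columns=_LIB_COLUMNS).to_csv(path, sep="\t", index=False)


def default_signature_library() -> list:
    """The packaged reference library (a scaled-down public-shift subset)."""
    return read_signature_library(packaged_data_path("library.tsv"))


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------


def read_table(path) -> pd.DataFrame:
    """Read a TSV with a header row; first column becomes the index."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from None
    return df


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_concentration_table(path, units: str) -> ConcentrationTable:
    """Read a concentration TSV; empty cells are marked absent."""
    df = read_table(path)
    return ConcentrationTable(df, units=units)


def write_concentration_table(table: ConcentrationTable, path) -> None:
    out = table.values.mask(table.absent_mask)
    out.to_csv(path, sep="\t")
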