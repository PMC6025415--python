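"""Domain containers and plain-text readers/writers.

Three kinds of input move through the pipeline:

* excitation–emission matrices (EEMs) — fluorescence intensity on a
  rectangular wavelength grid, one file per sample;
* UV–Vis absorbance spectra — optical density vs wavelength, two-column CSV;
* the per-sample survey table — site, season, water-quality covariates and
  the three phthalate congener concentrations (DMP, DEP, DBP) in mg/L.

All dialects are plain text so that a written file re-read is bit-identical.
The EEM dialect puts emission wavelengths across the columns and excitation
wavelengths down the first column; an orientation flag transposes on read
for instruments that export the other way around.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import MissingInputError, ParseError, ValidationError

__all__ = [
    "EEMGrid",
    "AbsorptionSpectrum",
    "SampleRecord",
    "SurveyTable",
    "PAE_CONGENERS",
    "SEASONS",
    "read_eem",
    "write_eem",
    "read_absorbance",
    "write_absorbance",
    "read_samples",
    "write_samples",
]

#: Phthalate congeners quantified by the survey, in reporting order.
PAE_CONGENERS = ("DMP", "DEP", "DBP")

#: The two sampling campaigns: June (normal season) and October (dry season).
SEASONS = ("JUN", "OCT")

_FLOAT_FMT = "%.17g"  # round-trips IEEE doubles exactly


def _as_axis(values: Iterable[float], name: str) -> np.ndarray:
    axis = np.asarray(list(values), dtype=float)
    if axis.ndim != 1 or axis.size < 2:
        raise ValidationError(f"{name} axis must be 1-D with at least 2 points")
    if not np.all(np.isfinite(axis)):
        raise ValidationError(f"{name} axis contains non-finite wavelengths")
    if not np.all(np.diff(axis) > 0):
        raise ValidationError(f"{name} axis must be strictly increasing")
    return axis


@dataclass(frozen=True)
class EEMGrid:
    """One sample's excitation–emission matrix.

    ``intensity[i, j]`` is the fluorescence intensity (instrument units; the
    pipeline is unit-agnostic) at excitation ``excitation_nm[i]`` and emission
    ``emission_nm[j]``.  ``corrections_applied`` records which preprocessing
    steps have already been run ({"blank", "scatter", "inner_filter"}).
    """

    excitation_nm: np.ndarray
    emission_nm: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    corrections_applied: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        ex = _as_axis(self.excitation_nm, "excitation")
        em = _as_axis(self.emission_nm, "emission")
        inten = np.asarray(self.intensity, dtype=float)
        if inten.shape != (ex.size, em.size):
            raise ValidationError(
                f"intensity shape {inten.shape} does not match axes "
                f"({ex.size}, {em.size})"
            )
        if not np.all(np.isfinite(inten)):
            raise ValidationError("intensity contains non-finite values")
        object.__setattr__(self, "excitation_nm", ex)
        object.__setattr__(self, "emission_nm", em)
        object.__setattr__(self, "intensity", inten)
        object.__setattr__(self, "corrections_applied", frozenset(self.corrections_applied))

    # -- convenience -----------------------------------------------------

    def with_intensity(self, intensity: np.ndarray, add_corrections: Iterable[str] = ()) -> "EEMGrid":
        """Copy of this grid with new intensities and extra correction tags."""
        return replace(
            self,
            intensity=intensity,
            corrections_applied=self.corrections_applied | frozenset(add_corrections),
        )

    def index_of(self, excitation: float, emission: float, tol: float = 1e-6) -> tuple[int, int]:
        """Grid indices of an exact (λex, λem) pair, or a ValidationError."""
        i = np.where(np.abs(self.excitation_nm - excitation) <= tol)[0]
        j = np.where(np.abs(self.emission_nm - emission) <= tol)[0]
        if i.size != 1 or j.size != 1:
            raise ValidationError(
                f"({excitation}, {emission}) nm is not a grid point of sample "
                f"{self.sample_id!r}"
            )
        return int(i[0]), int(j[0])

    def value_at(self, excitation: float, emission: float) -> float:
        i, j = self.index_of(excitation, emission)
        return float(self.intensity[i, j])


def default_eem_axes() -> tuple[np.ndarray, np.ndarray]:
    """Acquisition grid of the survey: Ex 220–450 nm @5 nm, Em 250–600 nm @1 nm."""
    return np.arange(220.0, 451.0, 5.0), np.arange(250.0, 601.0, 1.0)


@dataclass(frozen=True)
class AbsorptionSpectrum:
    """A UV–Vis optical-density spectrum in a cuvette of known path length.

    Optical density is decadic and dimensionless; ``path_length_m`` defaults
    to the 1 cm quartz cell used for both absorbance and fluorescence.
    """

    wavelength_nm: np.ndarray
    optical_density: np.ndarray
    path_length_m: float = 0.01
    sample_id: str = ""

    def __post_init__(self) -> None:
        wl = _as_axis(self.wavelength_nm, "wavelength")
        od = np.asarray(self.optical_density, dtype=float)
        if od.shape != wl.shape:
            raise ValidationError("optical_density length must match wavelength axis")
        if not np.all(np.isfinite(od)):
            raise ValidationError("optical density contains non-finite values")
        if not self.path_length_m > 0:
            raise ValidationError("path_length_m must be positive")
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "optical_density", od)

    def covers(self, wavelengths: np.ndarray) -> bool:
        wavelengths = np.asarray(wavelengths, dtype=float)
        return bool(
            wavelengths.min() >= self.wavelength_nm[0]
            and wavelengths.max() <= self.wavelength_nm[-1]
        )

    def od_at(self, wavelengths) -> np.ndarray:
        """OD linearly interpolated inside the measured range (no extrapolation)."""
        wavelengths = np.atleast_1d(np.asarray(wavelengths, dtype=float))
        if not self.covers(wavelengths):
            raise ValidationError(
                f"wavelengths outside measured range "
                f"[{self.wavelength_nm[0]:g}, {self.wavelength_nm[-1]:g}] nm"
            )
        return np.interp(wavelengths, self.wavelength_nm, self.optical_density)


@dataclass
class SampleRecord:
    """One row of the survey table.  Missing covariates are NaN, never zero."""

    site_id: int
    season: str
    doc_mg_per_l: float = math.nan
    chla_ug_per_l: float = math.nan
    tp_mg_per_l: float = math.nan
    nh3n_mg_per_l: float = math.nan
    cod_mg_per_l: float = math.nan
    ph: float = math.nan
    ec_us_per_cm: float = math.nan
    ism_mg_per_l: float = math.nan
    osm_mg_per_l: float = math.nan
    dmp_mg_per_l: float = math.nan
    dep_mg_per_l: float = math.nan
    dbp_mg_per_l: float = math.nan

    def __post_init__(self) -> None:
        self.site_id = int(self.site_id)
        if not 1 <= self.site_id <= 25:
            raise ValidationError(f"site_id {self.site_id} outside 1–25")
        if self.season not in SEASONS:
            raise ValidationError(f"season {self.season!r} not one of {SEASONS}")
        for name in _CONCENTRATION_FIELDS:
            v = getattr(self, name)
            if v is not None and not math.isnan(v) and v < 0:
                raise ValidationError(f"{name} negative ({v}) for site {self.site_id}")

    @property
    def sample_id(self) -> str:
        return f"{self.season}_{self.site_id:02d}"

    def pae_concentrations(self) -> dict[str, float]:
        return {
            "DMP": self.dmp_mg_per_l,
            "DEP": self.dep_mg_per_l,
            "DBP": self.dbp_mg_per_l,
        }


_CONCENTRATION_FIELDS = (
    "doc_mg_per_l",
    "chla_ug_per_l",
    "tp_mg_per_l",
    "nh3n_mg_per_l",
    "cod_mg_per_l",
    "ec_us_per_cm",
    "ism_mg_per_l",
    "osm_mg_per_l",
    "dmp_mg_per_l",
    "dep_mg_per_l",
    "dbp_mg_per_l",
)

_SAMPLE_COLUMNS = ("site_id", "season") + _CONCENTRATION_FIELDS[:5] + ("ph",) + _CONCENTRATION_FIELDS[5:]


@dataclass
class SurveyTable:
    """Typed survey records plus any unrecognised columns kept as a side table."""

    records: list
    extra: pd.DataFrame

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        """Records as a DataFrame in file order (extra columns appended)."""
        base = pd.DataFrame([vars(r) for r in self.records], columns=list(_SAMPLE_COLUMNS))
        if not self.extra.empty:
            base = pd.concat([base, self.extra.reset_index(drop=True)], axis=1)
        return base


# ---------------------------------------------------------------------------
# EEM matrix dialect
# ---------------------------------------------------------------------------

def write_eem(eem: EEMGrid, path) -> None:
    """Write the documented matrix dialect.

    First row: ``ex_nm/em_nm`` then the emission wavelengths; each following
    row: the excitation wavelength then that row of intensities.
    """
    path = Path(path)
    with path.open("w") as fh:
        header = ",".join(["ex_nm/em_nm"] + [_FLOAT_FMT % w for w in eem.emission_nm])
        fh.write(header + "\n")
        for ex, row in zip(eem.excitation_nm, eem.intensity):
            fh.write(",".join([_FLOAT_FMT % ex] + [_FLOAT_FMT % v for v in row]) + "\n")


def read_eem(path, transpose: bool = False, sample_id: str | None = None) -> EEMGrid:
    """Read an EEM matrix with wavelength headers.

    Parameters
    ----------
    transpose
        Set when the file has excitation across the columns instead of rows.
    """
    path = Path(path)
    if not path.exists():
        raise MissingInputError(f"EEM file not found: {path}")
    rows: list[list[str]] = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if line:
                rows.append(line.split(","))
    if len(rows) < 2:
        raise ParseError(f"{path}: EEM file needs a header row and data rows")
    width = len(rows[0])
    for lineno, r in enumerate(rows, start=1):
        if len(r) != width:
            raise ParseError(f"{path}: ragged row at line {lineno} "
                             f"({len(r)} fields, expected {width})")
    try:
        col_axis = np.array([float(v) for v in rows[0][1:]])
        row_axis = np.array([float(r[0]) for r in rows[1:]])
        values = np.array([[float(v) for v in r[1:]] for r in rows[1:]])
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric cell ({exc})") from None
    if transpose:
        row_axis, col_axis, values = col_axis, row_axis, values.T
    return EEMGrid(
        excitation_nm=row_axis,
        emission_nm=col_axis,
        intensity=values,
        sample_id=sample_id if sample_id is not None else path.stem,
    )


# ---------------------------------------------------------------------------
# Absorbance dialect: two-column CSV (wavelength_nm, optical_density)
# ---------------------------------------------------------------------------

def write_absorbance(spec: AbsorptionSpectrum, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("wavelength_nm,optical_density\n")
        for wl, od in zip(spec.wavelength_nm, spec.optical_density):
            fh.write((_FLOAT_FMT % wl) + "," + (_FLOAT_FMT % od) + "\n")


def read_absorbance(path, path_length_m: float = 0.01,
                    sample_id: str | None = None) -> AbsorptionSpectrum:
    path = Path(path)
    if not path.exists():
        raise MissingInputError(f"absorbance file not found: {path}")
    wl: list[float] = []
    od: list[float] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split(",")
            if len(fields) != 2:
                raise ParseError(f"{path}: line {lineno} has {len(fields)} fields, expected 2")
            try:
                wl.append(float(fields[0]))
                od.append(float(fields[1]))
            except ValueError:
                if lineno == 1:  # optional header
                    continue
                raise ParseError(f"{path}: non-numeric value at line {lineno}") from None
    if not wl:
        raise ParseError(f"{path}: no data rows")
    wl_arr = np.array(wl)
    if np.unique(wl_arr).size != wl_arr.size:
        raise ValidationError(f"{path}: duplicate wavelengths present")
    return AbsorptionSpectrum(
        wavelength_nm=wl_arr,
        optical_density=np.array(od),
        path_length_m=path_length_m,
        sample_id=sample_id if sample_id is not None else path.stem,
    )


# ---------------------------------------------------------------------------
# Survey table
# ---------------------------------------------------------------------------

def write_samples(table: SurveyTable | Sequence[SampleRecord], path) -> None:
    if isinstance(table, SurveyTable):
        frame = table.to_frame()
    else:
        frame = SurveyTable(records=list(table), extra=pd.DataFrame()).to_frame()
    frame.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_samples(path) -> SurveyTable:
    """Read the survey CSV into typed records.

    Unknown columns are preserved in ``SurveyTable.extra`` so downstream
    correlation analyses can use them.  Empty water-quality cells become NaN
    missing markers; negative concentrations and unknown season labels raise.
    """
    path = Path(path)
    if not path.exists():
        raise MissingInputError(f"sample table not found: {path}")
    frame = pd.read_csv(path)
    missing = [c for c in ("site_id", "season", "dmp_mg_per_l", "dep_mg_per_l", "dbp_mg_per_l")
               if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: required columns missing: {missing}")
    known = [c for c in _SAMPLE_COLUMNS if c in frame.columns]
    extra = frame[[c for c in frame.columns if c not in _SAMPLE_COLUMNS]].copy()
    records = []
    for idx, row in frame[known].iterrows():
        kwargs = {}
        for col in known:
            v = row[col]
            if col == "season":
                kwargs[col] = str(v).strip()
            elif col == "site_id":
                kwargs[col] = int(v)
            else:
                kwargs[col] = float(v) if pd.notna(v) else math.nan
        try:
            records.append(SampleRecord(**kwargs))
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {idx + 2}: {exc}") from None
    pairs = [(r.site_id, r.season) for r in records]
    if len(set(pairs)) != len(pairs):
        raise ValidationError(f"{path}: duplicate (site_id, season) pairs")
    return SurveyTable(records=records, extra=extra)
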