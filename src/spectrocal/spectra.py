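"""Reflectance spectra: containers, file I/O, region trimming, replicate handling.

A :class:`Spectrum` is one replicate's diffuse-reflectance curve on a strictly
increasing wavelength grid (nominally 250-2000 nm at 1 nm resolution, as
recorded on a UV-Vis-NIR spectrophotometer with an integrating sphere).
A :class:`SpectraSet` collects replicates of several samples on a common grid.
:func:`trim_regions` restricts a spectrum to a set of closed wavelength
intervals -- the mechanism used to discard the saturated UV end and the
detector-switch artifact near 900 nm before any derivative is taken.

On-disk formats
---------------
``csv-wide``
    First column ``wavelength_nm``; each further column is one replicate,
    headed ``<sample>_<replicate>`` (e.g. ``A_r1``). UTF-8, ``.`` decimal.
``csv-long``
    Columns ``wavelength_nm, sample, replicate, value``.
``jcampdx-min``
    A minimal JCAMP-DX-like dialect: ``##TITLE=<sample>_<replicate>`` header
    records and an ``##XYDATA=(XY..XY)`` table with one ``x, y`` pair per
    line on a fixed-step grid; one spectrum per block, ``##END=`` terminated.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "SpectraSet",
    "RegionSet",
    "SpectrumFormatError",
    "load_spectra",
    "write_spectra",
    "trim_regions",
    "average_replicates",
]

DIALECTS = ("csv-wide", "csv-long", "jcampdx-min")


class SpectrumFormatError(ValueError):
    """Raised for malformed spectrum files or invariant violations on load."""


def _as_float_array(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


@dataclass(frozen=True)
class Spectrum:
    """One replicate's reflectance curve.

    Parameters
    ----------
    wavelengths_nm : array-like
        Strictly increasing wavelength grid in nm.
    values : array-like
        Reflectance in arbitrary units, same length as the grid, finite.
    sample_id : str
        Sample label (e.g. ``"A"``..``"J"``).
    replicate_id : int
        Small integer identifying the replicate within the sample.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    sample_id: str = ""
    replicate_id: int = 1

    def __post_init__(self) -> None:
        w = _as_float_array(self.wavelengths_nm)
        v = _as_float_array(self.values)
        if w.ndim != 1 or v.ndim != 1:
            raise SpectrumFormatError("wavelengths and values must be 1-D")
        if w.size != v.size:
            raise SpectrumFormatError(
                f"length mismatch: {w.size} wavelengths vs {v.size} values"
            )
        if w.size == 0:
            raise SpectrumFormatError("empty spectrum")
        if np.any(np.diff(w) <= 0):
            raise SpectrumFormatError("non-monotone grid")
        if not np.all(np.isfinite(v)):
            raise SpectrumFormatError("non-finite reflectance values")
        object.__setattr__(self, "wavelengths_nm", w)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.wavelengths_nm.size

    @property
    def label(self) -> str:
        return f"{self.sample_id}_r{self.replicate_id}"


@dataclass(frozen=True)
class SpectraSet:
    """A collection of spectra sharing one wavelength grid."""

    spectra: tuple[Spectrum, ...]

    def __post_init__(self) -> None:
        spectra = tuple(self.spectra)
        if not spectra:
            raise SpectrumFormatError("empty spectra set")
        grid = spectra[0].wavelengths_nm
        for s in spectra[1:]:
            if s.wavelengths_nm.size != grid.size or not np.array_equal(
                s.wavelengths_nm, grid
            ):
                raise SpectrumFormatError(
                    f"grid mismatch for {s.label}: all spectra must share one grid"
                )
        object.__setattr__(self, "spectra", spectra)

    @property
    def grid(self) -> np.ndarray:
        return self.spectra[0].wavelengths_nm

    @property
    def sample_ids(self) -> list[str]:
        seen: list[str] = []
        for s in self.spectra:
            if s.sample_id not in seen:
                seen.append(s.sample_id)
        return seen

    def replicates(self, sample_id: str) -> list[Spectrum]:
        out = [s for s in self.spectra if s.sample_id == sample_id]
        if not out:
            raise KeyError(f"unknown sample_id {sample_id!r}")
        return out

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    def to_matrix(self) -> pd.DataFrame:
        """Rows = spectra (indexed by label), columns = wavelengths."""
        return pd.DataFrame(
            np.vstack([s.values for s in self.spectra]),
            index=[s.label for s in self.spectra],
            columns=self.grid,
        )


@dataclass(frozen=True)
class RegionSet:
    """Ordered, non-overlapping closed wavelength intervals [lo, hi] in nm."""

    intervals: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        ivs = tuple((float(lo), float(hi)) for lo, hi in self.intervals)
        if not ivs:
            raise ValueError("at least one interval required")
        for lo, hi in ivs:
            if lo > hi:
                raise ValueError(f"interval [{lo}, {hi}] has lo > hi")
        for (_, hi_prev), (lo, _) in zip(ivs, ivs[1:]):
            if lo <= hi_prev:
                raise ValueError("intervals must be sorted and non-overlapping")
        object.__setattr__(self, "intervals", ivs)

    def mask(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        w = _as_float_array(wavelengths_nm)
        m = np.zeros(w.shape, dtype=bool)
        for lo, hi in self.intervals:
            m |= (w >= lo) & (w <= hi)
        return m


#: Intervals retained for the untransformed (zero-order) spectra: the saturated
#: region below 270 nm and the detector-switch region 851-906 nm are discarded.
ZERO_ORDER_REGIONS = RegionSet(((270.0, 850.0), (907.0, 2000.0)))
#: Post-derivative intervals for the Golay-Savitzky treated spectra.
GS_REGIONS = RegionSet(((270.0, 850.0), (935.0, 1920.0)))
#: Post-derivative intervals for the step-by-step-filter treated spectra.
SBSF_REGIONS = RegionSet(((270.0, 850.0), (935.0, 1980.0)))


def trim_regions(s, regions: RegionSet):
    """Keep exactly the grid points lying inside some closed interval.

    Works for :class:`Spectrum` and any dataclass with ``wavelengths_nm`` /
    ``values`` fields (e.g. a derivative spectrum); order is preserved and the
    input is never modified.
    """
    m = regions.mask(s.wavelengths_nm)
    if not m.any():
        raise ValueError("regions exclude all points")
    return dataclasses.replace(
        s, wavelengths_nm=s.wavelengths_nm[m], values=s.values[m]
    )


def average_replicates(ss: SpectraSet) -> SpectraSet:
    """Arithmetic mean over replicates, one output spectrum per sample.

    Averaging the replicates reduces the between-measurement variation caused
    by inhomogeneous packing of the powdered material; with k i.i.d. noise
    realisations the noise variance drops by a factor of k.
    """
    out = []
    for sid in ss.sample_ids:
        reps = ss.replicates(sid)
        mean = np.mean([r.values for r in reps], axis=0)
        out.append(
            Spectrum(
                wavelengths_nm=ss.grid, values=mean, sample_id=sid, replicate_id=0
            )
        )
    return SpectraSet(tuple(out))


# ---------------------------------------------------------------------------
# I/O


_COLUMN_RE = re.compile(r"^(?P<sample>.+?)_r?(?P<rep>\d+)$")


def _parse_column_label(label: str) -> tuple[str, int]:
    m = _COLUMN_RE.match(str(label).strip())
    if not m:
        raise SpectrumFormatError(
            f"cannot parse sample/replicate from column {label!r} "
            "(expected '<sample>_<replicate>')"
        )
    return m.group("sample"), int(m.group("rep"))


def load_spectra(path, dialect: str = "csv-wide") -> SpectraSet:
    """Read a :class:`SpectraSet` from disk.

    Parameters
    ----------
    path : path-like
        Input file.
    dialect : {"csv-wide", "csv-long", "jcampdx-min"}
        On-disk layout; see the module docstring.
    """
    path = Path(path)
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "csv-wide":
        return _load_csv_wide(path)
    if dialect == "csv-long":
        return _load_csv_long(path)
    return _load_jcampdx_min(path)


def _load_csv_wide(path: Path) -> SpectraSet:
    # round_trip parser: exact float64 recovery of written values
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] < 2:
        raise SpectrumFormatError("csv-wide file needs a wavelength and a value column")
    w = df.iloc[:, 0].to_numpy(dtype=float)
    spectra = []
    for col in df.columns[1:]:
        sid, rep = _parse_column_label(col)
        spectra.append(
            Spectrum(w, df[col].to_numpy(dtype=float), sample_id=sid, replicate_id=rep)
        )
    return SpectraSet(tuple(spectra))


def _load_csv_long(path: Path) -> SpectraSet:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"wavelength_nm", "sample", "replicate", "value"}
    if not required.issubset(df.columns):
        raise SpectrumFormatError(
            f"csv-long file must have columns {sorted(required)}"
        )
    spectra = []
    for (sid, rep), grp in df.groupby(["sample", "replicate"], sort=True):
        grp = grp.sort_values("wavelength_nm", kind="stable")
        spectra.append(
            Spectrum(
                grp["wavelength_nm"].to_numpy(dtype=float),
                grp["value"].to_numpy(dtype=float),
                sample_id=str(sid),
                replicate_id=int(rep),
            )
        )
    return SpectraSet(tuple(spectra))


def _load_jcampdx_min(path: Path) -> SpectraSet:
    spectra = []
    title = None
    xy: list[tuple[float, float]] = []
    in_table = False
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper()
            if key == "TITLE":
                title = value.strip()
                xy = []
                in_table = False
            elif key == "XYDATA":
                in_table = True
            elif key == "END":
                if title is None or not xy:
                    raise SpectrumFormatError("jcampdx-min block missing TITLE or XYDATA")
                sid, rep = _parse_column_label(title)
                w, v = (np.array(c, dtype=float) for c in zip(*xy))
                spectra.append(Spectrum(w, v, sample_id=sid, replicate_id=rep))
                title, xy, in_table = None, [], False
            continue
        if in_table:
            parts = re.split(r"[,\s]+", line)
            if len(parts) != 2:
                raise SpectrumFormatError(f"malformed XYDATA line: {raw!r}")
            xy.append((float(parts[0]), float(parts[1])))
    if not spectra:
        raise SpectrumFormatError("no spectra found in jcampdx-min file")
    steps = np.diff(spectra[0].wavelengths_nm)
    if spectra and not np.allclose(steps, steps[0]):
        raise SpectrumFormatError("jcampdx-min requires a fixed-step grid")
    return SpectraSet(tuple(spectra))


def write_spectra(ss: SpectraSet, path, dialect: str = "csv-wide") -> None:
    """Write a :class:`SpectraSet`; inverse of :func:`load_spectra`.

    Values are written with 17 significant digits, so a round trip through
    ``csv-wide``/``csv-long`` reproduces float64 values exactly.
    """
    path = Path(path)
    fmt = "%.17g"
    if dialect == "csv-wide":
        df = pd.DataFrame({"wavelength_nm": ss.grid})
        for s in ss:
            df[s.label] = s.values
        df.to_csv(path, index=False, float_format=fmt)
    elif dialect == "csv-long":
        frames = [
            pd.DataFrame(
                {
                    "wavelength_nm": s.wavelengths_nm,
                    "sample": s.sample_id,
                    "replicate": s.replicate_id,
                    "value": s.values,
                }
            )
            for s in ss
        ]
        pd.concat(frames).to_csv(path, index=False, float_format=fmt)
    elif dialect == "jcampdx-min":
        with open(path, "w") as fh:
            for s in ss:
                fh.write(f"##TITLE={s.label}\n")
                fh.write("##XUNITS=NANOMETERS\n##YUNITS=REFLECTANCE\n")
                fh.write("##XYDATA=(XY..XY)\n")
                for w, v in zip(s.wavelengths_nm, s.values):
                    fh.write(f"{w:.17g}, {v:.17g}\n")
                fh.write("##END=\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
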