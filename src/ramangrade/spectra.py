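"""Raman spectrum containers, table I/O, normalization and 1D augmentations.

A Raman spectrum is intensity (arbitrary units) against Raman shift
(wavenumber, cm^-1).  Every spectrum carries a patient identifier and a
histological grade in {E, G1, G2, G3, unknown}: E is benign enchondroma,
G1-G3 are chondrosarcoma grades of increasing malignancy.  G2 and G3 are
always collapsed into a single G2G3 category downstream, because grade
assignment between them is tissue-sample dependent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GRADES",
    "DEFAULT_GRID",
    "RamanSpectrum",
    "SpectraDataset",
    "BinaryTask",
    "TASK_EG1_VS_G2G3",
    "TASK_E_VS_G1",
    "grade_class",
    "read_spectra_table",
    "write_spectra_table",
    "resample_to_grid",
    "zscore_normalize",
    "augment_noise",
    "augment_shift",
]

GRADES = ("E", "G1", "G2", "G3", "unknown")

#: Default acquisition range 200-3400 cm^-1 at 2 cm^-1 spacing (1601 points),
#: finer than the 5 cm^-1 FWHM instrumental resolution.
DEFAULT_GRID = np.linspace(200.0, 3400.0, 1601)


def _parse_grade(raw) -> str:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return "unknown"
    text = str(raw).strip()
    for g in GRADES:
        if text.lower() == g.lower():
            return g
    return "unknown"


def grade_class(grade: str) -> str:
    """Collapse a histological grade to its classification category.

    G2 and G3 map to the single ``G2G3`` category; E and G1 map to
    themselves.
    """
    if grade in ("G2", "G3", "G2G3"):
        return "G2G3"
    if grade in ("E", "G1"):
        return grade
    raise ValueError(f"grade {grade!r} has no classification category")


@dataclass(frozen=True)
class RamanSpectrum:
    """One spectrum: a strictly increasing wavenumber grid plus intensities."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    patient_id: str = ""
    grade: str = "unknown"
    spectrum_id: str = ""
    degenerate: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        wn = np.asarray(self.wavenumbers, dtype=float)
        it = np.asarray(self.intensities, dtype=float)
        if wn.ndim != 1 or it.ndim != 1 or len(wn) != len(it):
            raise ValueError("wavenumbers and intensities must be 1D of equal length")
        if len(wn) < 2:
            raise ValueError("a spectrum needs at least 2 points")
        if not np.all(np.diff(wn) > 0):
            raise ValueError("wavenumbers must be strictly increasing")
        if not np.all(np.isfinite(it)):
            raise ValueError("intensities must be finite")
        if self.grade not in GRADES:
            raise ValueError(f"grade must be one of {GRADES}, got {self.grade!r}")
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "intensities", it)

    def __len__(self) -> int:
        return len(self.wavenumbers)

    def with_intensities(self, values: np.ndarray, **kwargs) -> "RamanSpectrum":
        return replace(self, intensities=np.asarray(values, dtype=float), **kwargs)


@dataclass
class SpectraDataset:
    """Ordered collection of spectra on one shared wavenumber grid."""

    spectra: list
    shared_grid: np.ndarray

    def __post_init__(self):
        grid = np.asarray(self.shared_grid, dtype=float)
        for sp in self.spectra:
            if len(sp.wavenumbers) != len(grid) or not np.allclose(sp.wavenumbers, grid):
                raise ValueError(
                    f"spectrum {sp.spectrum_id!r} is not on the shared grid; "
                    "resample first"
                )
        self.shared_grid = grid

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    def __getitem__(self, i):
        return self.spectra[i]

    def intensity_matrix(self) -> np.ndarray:
        """(n_spectra, n_points) intensity array."""
        if not self.spectra:
            return np.empty((0, len(self.shared_grid)))
        return np.stack([sp.intensities for sp in self.spectra])

    def labels(self, collapse: bool = True) -> np.ndarray:
        """Grade labels; ``collapse`` maps G2/G3 to G2G3."""
        if collapse:
            return np.array([grade_class(sp.grade) for sp in self.spectra])
        return np.array([sp.grade for sp in self.spectra])

    def patient_ids(self) -> np.ndarray:
        return np.array([sp.patient_id for sp in self.spectra])

    def subset(self, mask) -> "SpectraDataset":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return SpectraDataset([self.spectra[i] for i in idx], self.shared_grid)

    def map(self, fn) -> "SpectraDataset":
        return SpectraDataset([fn(sp) for sp in self.spectra], self.shared_grid)


@dataclass(frozen=True)
class BinaryTask:
    """A binary grouping of grade categories.

    G2 and G3 always travel together: tasks are defined over the collapsed
    categories {E, G1, G2G3}.
    """

    name: str
    positive_classes: tuple
    negative_classes: tuple

    def __post_init__(self):
        pos, neg = set(self.positive_classes), set(self.negative_classes)
        if not pos or not neg or pos & neg:
            raise ValueError("positive/negative class sets must be disjoint and nonempty")

    def label(self, grade: str) -> int:
        """1 for the positive group, 0 for the negative group."""
        cls = grade_class(grade)
        if cls in self.positive_classes:
            return 1
        if cls in self.negative_classes:
            return 0
        raise ValueError(f"class {cls!r} not covered by task {self.name}")

    def mask(self, dataset: SpectraDataset) -> np.ndarray:
        covered = set(self.positive_classes) | set(self.negative_classes)
        return np.array([grade_class(sp.grade) in covered for sp in dataset])


#: Stage-1 task: benign + grade-1 against high-grade chondrosarcoma.
TASK_EG1_VS_G2G3 = BinaryTask("EG1_vs_G2G3", ("E", "G1"), ("G2G3",))
#: Stage-2 task: benign enchondroma against grade-1 chondrosarcoma.
TASK_E_VS_G1 = BinaryTask("E_vs_G1", ("E",), ("G1",))


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

def _read_metadata(metadata_path) -> dict:
    df = pd.read_csv(metadata_path, dtype=str)
    needed = {"spectrum_id", "patient_id", "grade"}
    if not needed.issubset(df.columns):
        raise ValueError(f"metadata file must have columns {sorted(needed)}")
    return {
        row.spectrum_id: (row.patient_id, _parse_grade(row.grade))
        for row in df.itertuples()
    }


def read_spectra_table(path, layout: str = "wide_rows", metadata=None) -> SpectraDataset:
    """Read a spectra table from CSV/TSV.

    Layouts
    -------
    ``wide_rows``
        header = ``spectrum_id`` followed by the wavenumbers; one spectrum
        per row.
    ``wide_cols``
        first column = wavenumbers; one spectrum per remaining column, the
        header carrying spectrum ids.
    ``long``
        columns ``spectrum_id, wavenumber, intensity``.

    ``metadata`` is an optional sidecar CSV with columns
    ``spectrum_id, patient_id, grade``; without it, ``patient_id`` and
    ``grade`` columns embedded in the wide_rows table are used when present.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    meta = _read_metadata(metadata) if metadata is not None else {}
    if layout == "wide_rows":
        df = pd.read_csv(path, sep=sep)
        id_col = df.columns[0]
        extra = [c for c in ("patient_id", "grade") if c in df.columns]
        wn_cols = [c for c in df.columns[1:] if c not in extra]
        try:
            grid = np.array([float(c) for c in wn_cols])
        except ValueError as exc:
            raise ValueError(f"non-numeric wavenumber header column: {exc}") from exc
        _check_grid(grid)
        spectra = []
        for i, row in df.iterrows():
            vals = row[wn_cols].to_numpy()
            try:
                vals = vals.astype(float)
            except ValueError as exc:
                raise ValueError(f"non-numeric intensity in row {i}: {exc}") from exc
            sid = str(row[id_col])
            pid, grade = meta.get(
                sid,
                (str(row.get("patient_id", "")), _parse_grade(row.get("grade"))),
            )
            spectra.append(RamanSpectrum(grid, vals, pid, grade, sid))
        return SpectraDataset(spectra, grid)
    if layout == "wide_cols":
        df = pd.read_csv(path, sep=sep)
        grid = df.iloc[:, 0].to_numpy(dtype=float)
        _check_grid(grid)
        spectra = []
        for col in df.columns[1:]:
            try:
                vals = df[col].to_numpy(dtype=float)
            except ValueError as exc:
                raise ValueError(f"non-numeric intensity in column {col!r}: {exc}") from exc
            pid, grade = meta.get(str(col), ("", "unknown"))
            spectra.append(RamanSpectrum(grid, vals, pid, grade, str(col)))
        return SpectraDataset(spectra, grid)
    if layout == "long":
        df = pd.read_csv(path, sep=sep)
        needed = {"spectrum_id", "wavenumber", "intensity"}
        if not needed.issubset(df.columns):
            raise ValueError(f"long layout needs columns {sorted(needed)}")
        spectra = []
        grid = None
        for sid, grp in df.groupby("spectrum_id", sort=False):
            wn = grp["wavenumber"].to_numpy(dtype=float)
            order = np.argsort(wn)
            wn, vals = wn[order], grp["intensity"].to_numpy(dtype=float)[order]
            _check_grid(wn)
            if grid is None:
                grid = wn
            elif len(wn) != len(grid) or not np.allclose(wn, grid):
                raise ValueError("inconsistent wavenumber grids across spectra")
            pid, grade = meta.get(str(sid), ("", "unknown"))
            spectra.append(RamanSpectrum(wn, vals, pid, grade, str(sid)))
        if grid is None:
            raise ValueError("long table holds no spectra")
        return SpectraDataset(spectra, grid)
    raise ValueError(f"unknown layout {layout!r}")


def _check_grid(grid):
    if not np.all(np.isfinite(grid)):
        raise ValueError("non-finite wavenumber in header")
    if not np.all(np.diff(grid) > 0):
        raise ValueError("wavenumbers must be strictly increasing")


def write_spectra_table(dataset: SpectraDataset, path, layout: str = "wide_rows",
                        metadata=None) -> None:
    """Write a dataset so that :func:`read_spectra_table` round-trips it.

    With ``metadata`` set, a sidecar CSV (spectrum_id, patient_id, grade)
    is written alongside.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    grid = dataset.shared_grid
    if layout == "wide_rows":
        cols = ["spectrum_id"] + [repr(float(w)) for w in grid]
        rows = [[sp.spectrum_id] + list(sp.intensities) for sp in dataset]
        pd.DataFrame(rows, columns=cols).to_csv(path, sep=sep, index=False)
    elif layout == "wide_cols":
        data = {"wavenumber": grid}
        for sp in dataset:
            data[sp.spectrum_id] = sp.intensities
        pd.DataFrame(data).to_csv(path, sep=sep, index=False)
    elif layout == "long":
        rows = {
            "spectrum_id": np.repeat([sp.spectrum_id for sp in dataset], len(grid)),
            "wavenumber": np.tile(grid, len(dataset)),
            "intensity": np.concatenate([sp.intensities for sp in dataset])
            if len(dataset) else np.array([]),
        }
        pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
    else:
        raise ValueError(f"unknown layout {layout!r}")
    if metadata is not None:
        pd.DataFrame(
            {
                "spectrum_id": [sp.spectrum_id for sp in dataset],
                "patient_id": [sp.patient_id for sp in dataset],
                "grade": [sp.grade for sp in dataset],
            }
        ).to_csv(metadata, index=False)


# ---------------------------------------------------------------------------
# Preprocessing and augmentation
# ---------------------------------------------------------------------------

def resample_to_grid(spectrum: RamanSpectrum, grid) -> RamanSpectrum:
    """Linearly interpolate onto a target grid (edge values extended)."""
    grid = np.asarray(grid, dtype=float)
    _check_grid(grid)
    src = spectrum.wavenumbers
    if grid[-1] < src[0] or grid[0] > src[-1]:
        raise ValueError("target grid does not overlap the source range")
    vals = np.interp(grid, src, spectrum.intensities)
    return replace(spectrum, wavenumbers=grid, intensities=vals)


def zscore_normalize(spectrum: RamanSpectrum) -> RamanSpectrum:
    """Per-spectrum zero-mean, unit-variance scaling (population std).

    A constant spectrum has no scale: it maps to all zeros with
    ``degenerate=True`` instead of raising, so batch pipelines keep going.
    """
    x = spectrum.intensities
    mu, sd = x.mean(), x.std()
    if sd == 0.0:
        return spectrum.with_intensities(np.zeros_like(x), degenerate=True)
    return spectrum.with_intensities((x - mu) / sd)


def augment_noise(spectrum: RamanSpectrum, relative_scale: float,
                  mode: str = "proportional_to_peak",
                  rng: np.random.Generator | None = None) -> RamanSpectrum:
    """Additive zero-mean Gaussian noise.

    In ``proportional_to_peak`` mode the standard deviation is
    ``relative_scale * max(intensities)``; in ``absolute`` mode it is
    ``relative_scale`` directly.
    """
    if relative_scale < 0:
        raise ValueError("relative_scale must be >= 0")
    if mode not in ("proportional_to_peak", "absolute"):
        raise ValueError(f"unknown noise mode {mode!r}")
    if relative_scale == 0:
        return spectrum
    rng = np.random.default_rng() if rng is None else rng
    sigma = relative_scale * spectrum.intensities.max() \
        if mode == "proportional_to_peak" else relative_scale
    noise = rng.normal(0.0, sigma, size=len(spectrum))
    return spectrum.with_intensities(spectrum.intensities + noise)


def augment_shift(spectrum: RamanSpectrum, s: int,
                  rng: np.random.Generator | None = None,
                  k: int | None = None) -> RamanSpectrum:
    """Shift intensities by an integer number of grid steps.

    The shift ``k`` is drawn uniformly from the integers in [-s, s]
    (mimicking small wavelength-calibration offsets); vacated positions are
    filled with the edge value and the grid itself is unchanged.  Pass ``k``
    to force a specific shift.
    """
    s = int(s)
    if s < 0:
        raise ValueError("s must be >= 0")
    if s >= len(spectrum):
        raise ValueError("s must be smaller than the spectrum length")
    if k is None:
        rng = np.random.default_rng() if rng is None else rng
        k = int(rng.integers(-s, s + 1))
    elif abs(k) > s:
        raise ValueError("forced shift k outside [-s, s]")
    if k == 0:
        return spectrum
    x = spectrum.intensities
    out = np.empty_like(x)
    if k > 0:
        out[k:] = x[:-k]
        out[:k] = x[0]
    else:
        out[:k] = x[-k:]
        out[k:] = x[-1]
    return spectrum.with_intensities(out)
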