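"""Labeled reflectance spectra and plain-text spectral-library I/O.

A :class:`Spectrum` is one sample's reflectance curve (percent scale, 0-100)
on a strictly increasing wavelength grid in nanometres, tagged with species,
phylum (derived from species) and dryness state.  A :class:`SpectrumSet` is an
ordered collection of spectra, typically sharing a common 1-nm grid after
resampling.

The preprocessing chain mirrors standard field-spectroradiometer practice:
trim the noisy UV end (< 400 nm) and the water-vapour-affected NIR end
(> 900 nm), average replicate reads, and resample to the integer-nm grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SPECIES",
    "PHYLA",
    "DRYNESS_STATES",
    "SPECIES_TO_PHYLUM",
    "Spectrum",
    "SpectrumSet",
    "SpectraError",
    "UnitScaleError",
    "GridError",
    "read_spectra",
    "write_spectra",
    "trim_wavelengths",
    "average_replicates",
    "resample_to_grid",
]

#: The six dominant intertidal seaweed species of the study system.
SPECIES: tuple[str, ...] = (
    "Ulva_pertusa",
    "Sargassum_thunbergii",
    "Sargassum_fusiforme",
    "Chondrus_ocellatus",
    "Chondria_crassiaulis",
    "Grateloupia_filicina",
)

PHYLA: tuple[str, ...] = ("Chlorophyta", "Ochrophyta", "Rhodophyta")

DRYNESS_STATES: tuple[str, ...] = ("wet", "moderate", "dry")

#: Fixed taxonomy: green, brown and red seaweed phyla.
SPECIES_TO_PHYLUM: dict[str, str] = {
    "Ulva_pertusa": "Chlorophyta",
    "Sargassum_thunbergii": "Ochrophyta",
    "Sargassum_fusiforme": "Ochrophyta",
    "Chondrus_ocellatus": "Rhodophyta",
    "Chondria_crassiaulis": "Rhodophyta",
    "Grateloupia_filicina": "Rhodophyta",
}

LONG_COLUMNS = ["sample_id", "species", "dryness", "wavelength_nm", "reflectance_pct"]
WIDE_LABEL_COLUMNS = ["sample_id", "species", "dryness"]


class SpectraError(ValueError):
    """Base error for spectral data problems."""


class UnitScaleError(SpectraError):
    """Reflectance looks fractional (0-1) where percent (0-100) is required."""


class GridError(SpectraError):
    """Wavelength grids are missing, mixed, or out of range."""


@dataclass
class Spectrum:
    """One reflectance curve with its labels.

    Parameters
    ----------
    sample_id : str
        Unique identifier within a set.
    species : str
        One of :data:`SPECIES`, or a template/phylum name for reference
        curves produced by the simulator.
    wavelengths : array-like
        Strictly increasing wavelengths, nm.
    reflectance : array-like
        Reflectance in percent (0-100).  A curve lying entirely in (0, 1]
        is rejected as a unit error; convert fractional data on read with
        ``fractional=True``.
    dryness : str
        ``wet``, ``moderate`` or ``dry``.
    """

    sample_id: str
    species: str
    wavelengths: np.ndarray
    reflectance: np.ndarray
    dryness: str = "moderate"

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.wavelengths.ndim != 1 or self.reflectance.ndim != 1:
            raise SpectraError("wavelengths and reflectance must be 1-D")
        if self.wavelengths.size != self.reflectance.size:
            raise SpectraError(
                f"length mismatch: {self.wavelengths.size} wavelengths vs "
                f"{self.reflectance.size} reflectance values"
            )
        if self.wavelengths.size and np.any(np.diff(self.wavelengths) <= 0):
            raise SpectraError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.reflectance)):
            raise SpectraError(f"non-finite reflectance in sample {self.sample_id!r}")
        if self.dryness not in DRYNESS_STATES:
            raise SpectraError(f"unknown dryness state {self.dryness!r}")
        rmax = self.reflectance.max(initial=0.0)
        if 0.0 < rmax <= 1.0:
            raise UnitScaleError(
                f"sample {self.sample_id!r}: reflectance entirely within (0, 1] — "
                "looks fractional; pass fractional=True when reading, or rescale to percent"
            )

    @property
    def phylum(self) -> str | None:
        """Phylum derived from the species label (None for non-taxon labels)."""
        if self.species in SPECIES_TO_PHYLUM:
            return SPECIES_TO_PHYLUM[self.species]
        if self.species in PHYLA:
            return self.species
        return None

    def __len__(self) -> int:
        return int(self.wavelengths.size)

    def copy_with(self, **changes) -> "Spectrum":
        return replace(self, **changes)


@dataclass
class SpectrumSet:
    """Ordered collection of spectra with unique sample ids."""

    spectra: list[Spectrum] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.spectra]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SpectraError(f"duplicate sample ids: {dupes}")

    @property
    def grid(self) -> np.ndarray | None:
        """Shared wavelength grid, or None if members disagree (or empty)."""
        if not self.spectra:
            return None
        ref = self.spectra[0].wavelengths
        for s in self.spectra[1:]:
            if s.wavelengths.size != ref.size or not np.array_equal(s.wavelengths, ref):
                return None
        return ref

    def reflectance_matrix(self) -> np.ndarray:
        """Samples x wavelengths matrix; requires a common grid."""
        if self.grid is None:
            raise GridError("spectra do not share a common wavelength grid")
        return np.vstack([s.reflectance for s in self.spectra])

    def subset(self, predicate) -> "SpectrumSet":
        return SpectrumSet([s for s in self.spectra if predicate(s)])

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra)

    def __getitem__(self, i) -> Spectrum:
        return self.spectra[i]


def _validate_species(label: str, row: object = None) -> None:
    if label not in SPECIES:
        where = "" if row is None else f" (row {row})"
        raise SpectraError(
            f"unknown species {label!r}{where}; expected one of {', '.join(SPECIES)}"
        )


def read_spectra(
    path: str | Path,
    dialect: str = "long_csv",
    fractional: bool = False,
) -> SpectrumSet:
    """Read a labeled spectral library from CSV.

    ``long_csv`` has columns ``sample_id, species, dryness, wavelength_nm,
    reflectance_pct`` with one row per (sample, wavelength).  ``wide_csv``
    has the three label columns followed by one column per wavelength
    (column names are the wavelengths in nm) and one row per sample.

    ``fractional=True`` declares the input on a 0-1 scale and multiplies
    reflectance by 100 on ingest.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "long_csv":
        df = pd.read_csv(path, dtype={"sample_id": str, "species": str, "dryness": str})
        missing = [c for c in LONG_COLUMNS if c not in df.columns]
        if missing:
            raise SpectraError(f"long_csv missing columns: {missing}")
        refl = pd.to_numeric(df["reflectance_pct"], errors="coerce")
        bad = refl.isna() & df["reflectance_pct"].notna()
        if bad.any():
            idx = int(np.flatnonzero(bad.to_numpy())[0])
            raise SpectraError(
                f"non-numeric reflectance {df['reflectance_pct'].iloc[idx]!r} at data row {idx}"
            )
        df = df.assign(reflectance_pct=refl)
        spectra = []
        # groupby(sort=False) preserves first-appearance order of samples
        for sid, g in df.groupby("sample_id", sort=False):
            species = g["species"].iloc[0]
            _validate_species(species)
            r = g["reflectance_pct"].to_numpy(dtype=float)
            if fractional:
                r = r * 100.0
            spectra.append(
                Spectrum(
                    sample_id=str(sid),
                    species=species,
                    dryness=g["dryness"].iloc[0],
                    wavelengths=g["wavelength_nm"].to_numpy(dtype=float),
                    reflectance=r,
                )
            )
        return SpectrumSet(spectra)
    if dialect == "wide_csv":
        df = pd.read_csv(path, dtype={"sample_id": str, "species": str, "dryness": str})
        missing = [c for c in WIDE_LABEL_COLUMNS if c not in df.columns]
        if missing:
            raise SpectraError(f"wide_csv missing label columns: {missing}")
        wl_cols = [c for c in df.columns if c not in WIDE_LABEL_COLUMNS]
        try:
            wl = np.array([float(c) for c in wl_cols])
        except ValueError as exc:
            raise SpectraError(f"non-numeric wavelength column name: {exc}") from exc
        order = np.argsort(wl)
        wl = wl[order]
        wl_cols = [wl_cols[i] for i in order]
        spectra = []
        for idx, row in df.iterrows():
            _validate_species(row["species"], row=idx)
            vals = pd.to_numeric(row[wl_cols], errors="coerce").to_numpy(dtype=float)
            if np.isnan(vals).any():
                raise SpectraError(f"non-numeric reflectance at data row {idx}")
            if fractional:
                vals = vals * 100.0
            spectra.append(
                Spectrum(
                    sample_id=str(row["sample_id"]),
                    species=row["species"],
                    dryness=row["dryness"],
                    wavelengths=wl.copy(),
                    reflectance=vals,
                )
            )
        return SpectrumSet(spectra)
    raise ValueError(f"unknown dialect {dialect!r}")


def _fmt(x: float) -> str:
    # %.10g round-trips through float parse/format, making write->read->write stable
    return f"{x:.10g}"


def write_spectra(sset: SpectrumSet, path: str | Path, dialect: str = "long_csv") -> None:
    """Write a spectral library as CSV, re-readable by :func:`read_spectra`."""
    if len(sset) == 0:
        raise SpectraError("refusing to write an empty SpectrumSet")
    path = Path(path)
    if dialect == "long_csv":
        lines = [",".join(LONG_COLUMNS)]
        for s in sset:
            for wl, r in zip(s.wavelengths, s.reflectance):
                lines.append(f"{s.sample_id},{s.species},{s.dryness},{_fmt(wl)},{_fmt(r)}")
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        return
    if dialect == "wide_csv":
        grid = sset.grid
        if grid is None:
            raise GridError("wide_csv requires all spectra on a common grid")
        header = WIDE_LABEL_COLUMNS + [_fmt(w) for w in grid]
        lines = [",".join(header)]
        for s in sset:
            lines.append(
                ",".join([s.sample_id, s.species, s.dryness] + [_fmt(r) for r in s.reflectance])
            )
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        return
    raise ValueError(f"unknown dialect {dialect!r}")


def trim_wavelengths(s: Spectrum, lo: float = 400.0, hi: float = 900.0) -> Spectrum:
    """Keep the closed wavelength interval [lo, hi].

    Defaults drop the noisy UV region below 400 nm and the water-vapour
    absorption region above 900 nm, keeping both endpoints.
    """
    if lo > hi:
        raise GridError(f"invalid window: lo={lo} > hi={hi}")
    mask = (s.wavelengths >= lo) & (s.wavelengths <= hi)
    if not mask.any():
        raise GridError(
            f"trim [{lo}, {hi}] nm leaves no data (spectrum spans "
            f"[{s.wavelengths[0]}, {s.wavelengths[-1]}] nm)"
        )
    return s.copy_with(wavelengths=s.wavelengths[mask], reflectance=s.reflectance[mask])


def average_replicates(
    sset: SpectrumSet,
    group_key: Sequence[str] = ("species", "dryness"),
) -> SpectrumSet:
    """Pointwise-average replicate spectra within each label group.

    ``group_key`` names Spectrum label fields (``species``, ``dryness``).
    Returns one spectrum per group; the group size is recorded in the
    sample id suffix (``...|n=K``).
    """
    if len(sset) == 0:
        raise SpectraError("empty SpectrumSet")
    grid = sset.grid
    if grid is None:
        raise GridError("average_replicates requires a common wavelength grid")
    for key in group_key:
        if key not in ("species", "dryness", "sample_id"):
            raise SpectraError(f"unknown group key {key!r}")
    groups: dict[tuple, list[Spectrum]] = {}
    for s in sset:
        k = tuple(getattr(s, key) for key in group_key)
        groups.setdefault(k, []).append(s)
    out = []
    for k, members in groups.items():
        mean = np.mean([m.reflectance for m in members], axis=0)
        first = members[0]
        out.append(
            Spectrum(
                sample_id="|".join(map(str, k)) + f"|n={len(members)}",
                species=first.species,
                dryness=first.dryness,
                wavelengths=grid.copy(),
                reflectance=mean,
            )
        )
    return SpectrumSet(out)


def resample_to_grid(s: Spectrum, step: float = 1.0) -> Spectrum:
    """Linearly interpolate onto the integer-nm grid spanned by the data.

    The grid runs from ceil(min wavelength) to floor(max wavelength) in
    ``step`` nm increments; no extrapolation is performed.  Data already on
    the target grid pass through exactly.
    """
    if len(s) < 2:
        raise GridError("resampling needs at least 2 points")
    lo = math.ceil(s.wavelengths[0])
    hi = math.floor(s.wavelengths[-1])
    if hi < lo:
        raise GridError("data range contains no integer wavelength")
    grid = np.arange(lo, hi + step / 2, step, dtype=float)
    if grid.size == 0:
        raise GridError("empty target grid")
    values = np.interp(grid, s.wavelengths, s.reflectance)
    return s.copy_with(wavelengths=grid, reflectance=values)
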