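"""File-format adapters: MGF and CSV peak lists, profile and report CSVs.

MGF is read and written through :mod:`pyteomics.mgf` (the
``BEGIN IONS``/``PEPMASS``/``END IONS`` dialect).  The CSV spectrum dialect
is long-form with columns ``spectrum_id, precursor_mz, fragment_mz,
intensity``; profiles are ``congener, fraction_percent``.  All writers are
deterministic for identical inputs -- no timestamps inside data files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
from pyteomics import mgf

from .congeners import CongenerSpec, parse_name
from .msms import Peak, Spectrum
from .profiles import CongenerProfile

__all__ = [
    "read_spectra",
    "write_spectra",
    "read_profile",
    "write_profile",
    "write_report",
]

_CSV_COLUMNS = ["spectrum_id", "precursor_mz", "fragment_mz", "intensity"]


def read_spectra(path: str | Path) -> list[Spectrum]:
    """Read spectra from an MGF or CSV peak-list file (by extension)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".mgf":
        return _read_mgf(path)
    if path.suffix.lower() == ".csv":
        return _read_csv(path)
    raise ValueError(f"unsupported spectrum format {path.suffix!r} (use .mgf or .csv)")


def _read_mgf(path: Path) -> list[Spectrum]:
    spectra = []
    with mgf.read(str(path)) as reader:
        for i, entry in enumerate(reader):
            params = entry.get("params", {})
            pepmass = params.get("pepmass")
            if not pepmass or pepmass[0] is None:
                raise ValueError(f"{path}: spectrum {i + 1} has no PEPMASS")
            peaks = tuple(
                Peak(float(mz), float(inten))
                for mz, inten in zip(entry["m/z array"], entry["intensity array"])
            )
            spectra.append(
                Spectrum(
                    precursor_mz=float(pepmass[0]),
                    peaks=peaks,
                    identifier=params.get("title") or f"scan_{i + 1}",
                    retention_time=(
                        float(params["rtinseconds"]) if "rtinseconds" in params else None
                    ),
                )
            )
    return spectra


def _read_csv(path: Path) -> list[Spectrum]:
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns and c != "intensity"]
    if "intensity" not in df.columns:
        raise ValueError(f"{path}: missing required column 'intensity'")
    if missing:
        raise ValueError(f"{path}: missing required column(s) {', '.join(missing)}")
    spectra = []
    for sid, group in df.groupby("spectrum_id", sort=True):
        prec = group["precursor_mz"].unique()
        if len(prec) != 1:
            raise ValueError(
                f"{path}: spectrum {sid!r} has {len(prec)} distinct precursor values"
            )
        peaks = tuple(
            Peak(float(r.fragment_mz), float(r.intensity))
            for r in group.itertuples()
            if pd.notna(r.fragment_mz)
        )
        spectra.append(
            Spectrum(precursor_mz=float(prec[0]), peaks=peaks, identifier=str(sid))
        )
    return spectra


def write_spectra(spectra: Iterable[Spectrum], path: str | Path) -> Path:
    """Write spectra as MGF or CSV (by extension)."""
    path = Path(path)
    spectra = list(spectra)
    if path.suffix.lower() == ".mgf":
        entries = [
            {
                "m/z array": [p.mz for p in s.peaks],
                "intensity array": [p.intensity for p in s.peaks],
                "params": {
                    "title": s.identifier or f"scan_{i + 1}",
                    "pepmass": s.precursor_mz,
                    "charge": "1-",
                },
            }
            for i, s in enumerate(spectra)
        ]
        mgf.write(entries, str(path), file_mode="w")
        return path
    if path.suffix.lower() == ".csv":
        rows = [
            {
                "spectrum_id": s.identifier or f"scan_{i + 1}",
                "precursor_mz": s.precursor_mz,
                "fragment_mz": p.mz,
                "intensity": p.intensity,
            }
            for i, s in enumerate(spectra)
            for p in s.peaks
        ]
        pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)
        return path
    raise ValueError(f"unsupported spectrum format {path.suffix!r} (use .mgf or .csv)")


def read_profile(path: str | Path, label: str | None = None) -> CongenerProfile:
    """Read a ``congener, fraction_percent`` CSV as a profile."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("congener", "fraction_percent"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    entries: dict[CongenerSpec, float] = {}
    for row in df.itertuples():
        try:
            cong = parse_name(str(row.congener))
        except ValueError as e:
            raise ValueError(f"{path}: row {row.Index + 2}: {e}") from None
        if cong in entries:
            raise ValueError(
                f"{path}: row {row.Index + 2}: duplicate congener {cong.name}"
            )
        entries[cong] = float(row.fraction_percent)
    return CongenerProfile(label or path.stem, entries)


def write_profile(p: CongenerProfile, path: str | Path) -> Path:
    path = Path(path)
    rows = sorted(((c.name, f) for c, f in p.items()), key=lambda r: (-r[1], r[0]))
    pd.DataFrame(rows, columns=["congener", "fraction_percent"]).to_csv(
        path, index=False
    )
    return path


def write_report(report: pd.DataFrame, path: str | Path) -> Path:
    """Write a profile report (as built by ``profile_report``) to CSV.

    Profile-level statistics carried in ``report.attrs`` are emitted as
    ``#``-prefixed header comment lines so the table itself round-trips
    with any CSV reader.
    """
    path = Path(path)
    lines = [f"# {key}: {val}" for key, val in sorted(report.attrs.items())]
    body = report.to_csv(index=False)
    path.write_text("\n".join(lines) + ("\n" if lines else "") + body)
    return path
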