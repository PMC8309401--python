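"""Reading and writing the package's delimited text formats.

Spectra travel as long-format tables with columns
``species,replicate,part,wavelength_nm,reflectance``; scent data as
``sample,species,compound,area`` (with an optional ``compound,class``
map); vision-context curves as two-column ``wavelength_nm,value``
files; square matrices as delimited files with a label header row and
column.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from floracues.colorvision import ReflectanceSpectrum
from floracues.scent import CompoundTable

SPECTRA_COLUMNS = ["species", "replicate", "part", "wavelength_nm",
                   "reflectance"]


def read_spectra(path) -> list[ReflectanceSpectrum]:
    """Read a long-format spectra file into per-measurement spectra."""
    df = pd.read_csv(path)
    missing = set(SPECTRA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"spectra file lacks columns {sorted(missing)}")
    out = []
    for (sp, rid, part), grp in df.groupby(
        ["species", "replicate", "part"], sort=False
    ):
        grp = grp.sort_values("wavelength_nm")
        out.append(ReflectanceSpectrum(
            species=str(sp), replicate_id=str(rid), part=str(part),
            wavelengths_nm=grp["wavelength_nm"].to_numpy(dtype=float),
            reflectance=grp["reflectance"].to_numpy(dtype=float),
        ))
    return out


def write_spectra(spectra: list[ReflectanceSpectrum], path) -> None:
    rows = []
    for sp in spectra:
        for wl, rf in zip(sp.wavelengths_nm, sp.reflectance):
            rows.append((sp.species, sp.replicate_id, sp.part, wl, rf))
    pd.DataFrame(rows, columns=SPECTRA_COLUMNS).to_csv(path, index=False)


def read_curve(path) -> tuple[np.ndarray, np.ndarray]:
    """Two-column curve file ``wavelength_nm,value``."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("curve file needs wavelength and value columns")
    wl = df.iloc[:, 0].to_numpy(dtype=float)
    val = df.iloc[:, 1].to_numpy(dtype=float)
    return wl, val


def read_scent(path, class_map_path=None) -> CompoundTable:
    """Read a long-format scent table, optionally with a class map."""
    df = pd.read_csv(path)
    classes = None
    if class_map_path is not None:
        cm = pd.read_csv(class_map_path)
        classes = cm.set_index(cm.columns[0])[cm.columns[1]]
    return CompoundTable.from_long(df, classes=classes)


def write_scent(table: CompoundTable, path) -> None:
    table.to_long().to_csv(path, index=False)


def write_matrix(values: pd.DataFrame, path) -> None:
    values.to_csv(path, index_label="label")


def read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    df.columns = [str(c) for c in df.columns]
    df.index = [str(i) for i in df.index]
    return df
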