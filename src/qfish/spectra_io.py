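"""Reading and writing MS/MS peak lists and per-spectrum sample labels.

MGF (Mascot Generic Format) is the canonical carrier: one ``BEGIN IONS``
block per scan with ``PEPMASS``, optional ``CHARGE``, and a retention time
(``RTINSECONDS`` or ``RTINMINUTES``).  Sample and replicate labels come
from a sidecar tab-separated sample sheet keyed by source file name (one
file per LC run), with a title-regex fallback for mixed files.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

logger = logging.getLogger(__name__)

__all__ = [
    "MgfParseError",
    "LabelingError",
    "RawSpectrum",
    "SampleSheet",
    "read_mgf",
    "write_mgf",
    "write_clusters_tsv",
    "read_clusters_tsv",
]


class MgfParseError(ValueError):
    """A BEGIN IONS block could not be interpreted."""


class LabelingError(ValueError):
    """A spectrum could not be mapped to exactly one (sample, replicate)."""


@dataclass
class RawSpectrum:
    """One acquired MS/MS scan.

    ``mz``/``intensity`` are parallel arrays sorted strictly ascending in
    m/z (duplicate m/z entries are merged by summing intensity on ingest).
    ``sample`` is the biological group label (e.g. ``"HCC"``/``"Normal"``)
    and ``replicate`` the LC run within that group.
    """

    spectrum_id: str
    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: float
    retention_time: float
    sample: str
    replicate: str
    precursor_charge: int | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays differ in length")
        if np.any(self.intensity < 0):
            raise ValueError("negative peak intensity")
        if self.precursor_mz <= 0:
            raise ValueError("precursor m/z must be positive")
        if self.retention_time < 0:
            raise ValueError("retention time must be non-negative")

    @property
    def peaks(self) -> list[tuple[float, float]]:
        return list(zip(self.mz.tolist(), self.intensity.tolist()))

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    @property
    def replicate_key(self) -> tuple[str, str]:
        return (self.sample, self.replicate)


@dataclass
class SampleSheet:
    """Maps spectra to (sample, replicate) labels.

    Rows are (pattern, sample, replicate).  A pattern that equals the
    source file's base name labels every spectrum of that file; otherwise
    it is treated as a regular expression matched against the spectrum
    TITLE.  Every admitted spectrum must resolve to exactly one label.
    """

    rows: list[tuple[str, str, str]]

    @classmethod
    def read(cls, path: str | Path) -> "SampleSheet":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"pattern", "sample", "replicate"}
        if not required.issubset(df.columns):
            raise ValueError(f"sample sheet needs columns {sorted(required)}")
        return cls([(r.pattern, r.sample, r.replicate) for r in df.itertuples()])

    def write(self, path: str | Path) -> None:
        pd.DataFrame(self.rows, columns=["pattern", "sample", "replicate"]).to_csv(
            path, sep="\t", index=False
        )

    def resolve(self, source_file: str, title: str) -> tuple[str, str]:
        base = Path(source_file).name
        labels = {
            (s, r)
            for pat, s, r in self.rows
            if pat == base or (title and re.search(pat, title))
        }
        if len(labels) != 1:
            raise LabelingError(
                f"spectrum (file={base!r}, title={title!r}) matched "
                f"{len(labels)} sample-sheet labels; need exactly 1"
            )
        return labels.pop()


def _merge_duplicate_mz(mz: np.ndarray, intensity: np.ndarray):
    """Sort peaks by m/z and sum intensities at identical m/z values."""
    order = np.argsort(mz, kind="stable")
    mz, intensity = mz[order], intensity[order]
    uniq, inverse = np.unique(mz, return_inverse=True)
    if uniq.size == mz.size:
        return mz, intensity
    summed = np.zeros(uniq.size)
    np.add.at(summed, inverse, intensity)
    return uniq, summed


def read_mgf(path: str | Path, sample_sheet: SampleSheet) -> list[RawSpectrum]:
    """Read one MGF file into labeled :class:`RawSpectrum` records.

    Peaks are sorted ascending with duplicate m/z merged; blocks with an
    empty peak list are dropped and counted in the log.  RTINMINUTES is
    converted to seconds.
    """
    path = Path(path)
    spectra: list[RawSpectrum] = []
    n_dropped = 0
    with _mgf.MGF(str(path)) as reader:
        for idx, entry in enumerate(reader):
            params = entry.get("params", {})
            title = str(params.get("title", ""))
            mz = np.asarray(entry.get("m/z array", []), dtype=float)
            intensity = np.asarray(entry.get("intensity array", []), dtype=float)
            if mz.size == 0 or not np.any(intensity > 0):
                n_dropped += 1
                continue
            try:
                pepmass = params["pepmass"]
                precursor_mz = float(pepmass[0] if np.iterable(pepmass) else pepmass)
                if "rtinseconds" in params:
                    rt = float(params["rtinseconds"])
                elif "rtinminutes" in params:
                    rt = 60.0 * float(params["rtinminutes"])
                else:
                    raise KeyError("RTINSECONDS/RTINMINUTES")
            except (KeyError, TypeError, ValueError) as exc:
                raise MgfParseError(f"block {idx} of {path.name}: {exc}") from exc
            charge = params.get("charge")
            if charge:
                charge = int(charge[0])
            else:
                charge = None
            sample, replicate = sample_sheet.resolve(str(path), title)
            mz, intensity = _merge_duplicate_mz(mz, intensity)
            spectra.append(
                RawSpectrum(
                    spectrum_id=title or f"{path.stem}.{idx}",
                    mz=mz,
                    intensity=intensity,
                    precursor_mz=precursor_mz,
                    retention_time=rt,
                    sample=sample,
                    replicate=replicate,
                    precursor_charge=charge,
                )
            )
    if n_dropped:
        logger.info("%s: dropped %d empty spectrum block(s)", path.name, n_dropped)
    return spectra


def write_mgf(spectra: list[RawSpectrum], path: str | Path) -> None:
    """Write spectra to MGF with PEPMASS, CHARGE, RTINSECONDS and TITLE."""
    entries = []
    for s in spectra:
        params = {
            "title": s.spectrum_id,
            "pepmass": s.precursor_mz,
            "rtinseconds": s.retention_time,
        }
        if s.precursor_charge is not None:
            params["charge"] = s.precursor_charge
        entries.append(
            {"params": params, "m/z array": s.mz, "intensity array": s.intensity}
        )
    _mgf.write(entries, str(path), file_mode="w")


_CLUSTER_COLUMNS = [
    "cluster_id",
    "spectrum_id",
    "sample",
    "replicate",
    "retention_time",
    "precursor_mz",
    "q_score",
]


def write_clusters_tsv(clusters, path: str | Path) -> None:
    """One row per member spectrum: cluster id, labels, RT, precursor, Q score."""
    rows = []
    for cl in clusters:
        for member in cl.members:
            rows.append(
                (
                    cl.cluster_id,
                    member.spectrum_id,
                    member.sample,
                    member.replicate,
                    member.retention_time,
                    member.precursor_mz,
                    cl.q_score,
                )
            )
    pd.DataFrame(rows, columns=_CLUSTER_COLUMNS).to_csv(path, sep="\t", index=False)


def read_clusters_tsv(path: str | Path) -> pd.DataFrame:
    """Companion reader for :func:`write_clusters_tsv` (lossless round trip)."""
    return pd.read_csv(
        path,
        sep="\t",
        dtype={
            "cluster_id": str,
            "spectrum_id": str,
            "sample": str,
            "replicate": str,
        },
    )
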