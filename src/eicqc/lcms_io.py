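"""Reading and writing of LC/MS runs, peak lists, EIC tables and configuration.

The raw substrate is a centroided MS1 mzML file.  Internally a run is a
sequence of scans, each a pair of (m/z, intensity) arrays, plus a strictly
increasing retention-time axis in **seconds** (the canonical time unit
throughout the package; files declaring minutes are converted on read).
Scan indices are 0-based and contiguous.

Peak lists travel as plain CSV with a fixed documented header
(``eic_id, mz_apex, rt_apex_s, scan_apex, scan_left, scan_right, source``
plus optional metric columns); third-party exports are adapted with a
user-supplied column map rather than per-tool parsers.
"""

from __future__ import annotations

import base64
import struct
import zlib
from dataclasses import dataclass, fields, asdict
from pathlib import Path
from xml.sax.saxutils import escape

import numpy as np
import pandas as pd
from lxml import etree


class LCMSIOError(ValueError):
    """Malformed or unsupported LC/MS input."""


class ProfileModeError(LCMSIOError):
    """Raised when spectra are profile-mode; only centroid data is supported."""


@dataclass
class LCMSRun:
    """A centroided LC/MS run: per-scan centroid arrays plus an RT axis.

    Attributes
    ----------
    mz_arrays, intensity_arrays:
        One pair of 1-D float arrays per scan, equal lengths within a scan.
    rts:
        Retention time of each scan in seconds, strictly increasing.
    """

    mz_arrays: list[np.ndarray]
    intensity_arrays: list[np.ndarray]
    rts: np.ndarray

    def __post_init__(self) -> None:
        self.rts = np.asarray(self.rts, dtype=float)
        if len(self.mz_arrays) != len(self.intensity_arrays) or len(self.mz_arrays) != len(self.rts):
            raise LCMSIOError("scan arrays and RT axis must have equal length")
        if len(self.rts) > 1 and not np.all(np.diff(self.rts) > 0):
            raise LCMSIOError("retention times must be strictly increasing")
        for mz, inten in zip(self.mz_arrays, self.intensity_arrays):
            if len(mz) != len(inten):
                raise LCMSIOError("mz and intensity arrays differ in length within a scan")
            if len(inten) and (np.min(inten) < 0 or np.min(mz) <= 0):
                raise LCMSIOError("require intensity >= 0 and mz > 0")

    @property
    def n_scans(self) -> int:
        return len(self.rts)

    @property
    def n_points(self) -> int:
        return int(sum(len(a) for a in self.mz_arrays))

    @property
    def scan_rate(self) -> float:
        """Median scan-to-scan spacing in seconds."""
        if self.n_scans < 2:
            return float("nan")
        return float(np.median(np.diff(self.rts)))


@dataclass
class PeakRecord:
    """One chromatographic peak as exchanged between tools.

    ``scan_left <= scan_apex <= scan_right``; boundaries collapse onto the
    apex when a source file carries no boundary columns.
    """

    eic_id: int
    mz_apex: float
    rt_apex: float  # seconds
    scan_apex: int = 0
    scan_left: int | None = None
    scan_right: int | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.scan_left is None:
            self.scan_left = self.scan_apex
        if self.scan_right is None:
            self.scan_right = self.scan_apex
        if not (self.scan_left <= self.scan_apex <= self.scan_right):
            raise LCMSIOError(
                f"scan_left <= scan_apex <= scan_right violated: "
                f"{self.scan_left}, {self.scan_apex}, {self.scan_right}"
            )


@dataclass
class PipelineConfig:
    """Flat bag of every tunable in the four-stage pipeline.

    Defaults follow the conventions used throughout the package: a 40 ppm
    mass-shift tolerance for trace extension, window-5 smoothing, CWT scales
    1..16, 5–50-scan peak widths, 0.05 Da / 5 s match tolerances, and the
    combined peak-filter thresholds (sharpness >= 2.0, Gaussian similarity
    >= 0.6, SNR >= 1.3, significance >= 1.2, TPASR <= 0.8, zigzag <= 0.9).
    """

    # extraction
    ppm_tolerance: float = 40.0
    min_trace_points: int = 5
    max_gap: int = 2
    # EIC quality filter
    smooth_window: int = 5
    mcq_min: float = 0.6
    eic_zigzag_max: float = 0.9
    eic_filter_mode: str = "zigzag"  # mcq | zigzag | either
    # peak detection
    cwt_scale_min: int = 1
    cwt_scale_max: int = 16
    min_peak_width: int = 5
    max_peak_width: int = 50
    snr_floor: float = 0.0
    # peak quality filter
    sharpness_min: float | None = 2.0
    gauss_min: float | None = 0.6
    snr_min: float | None = 1.3
    signif_min: float | None = 1.2
    tpasr_max: float | None = 0.8
    peak_zigzag_max: float | None = 0.9
    # benchmarking tolerances
    mz_tol: float = 0.05  # Daltons
    rt_tol: float = 5.0  # seconds
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ppm_tolerance", "mz_tol", "rt_tol"):
            if getattr(self, name) <= 0:
                raise LCMSIOError(f"{name} must be > 0")
        if self.eic_filter_mode not in ("mcq", "zigzag", "either"):
            raise LCMSIOError(f"unknown eic_filter_mode {self.eic_filter_mode!r}")


_PEAKLIST_COLUMNS = ["eic_id", "mz_apex", "rt_apex_s", "scan_apex", "scan_left", "scan_right", "source"]


# mzML controlled-vocabulary accessions used by the reader
_CV_MS_LEVEL = "MS:1000511"
_CV_CENTROID = "MS:1000127"
_CV_PROFILE = "MS:1000128"
_CV_SCAN_START = "MS:1000016"
_CV_F32 = "MS:1000521"
_CV_F64 = "MS:1000523"
_CV_ZLIB = "MS:1000574"
_CV_MZ_ARRAY = "MS:1000514"
_CV_INT_ARRAY = "MS:1000515"
_UNIT_MINUTE = ("minute", "min", "UO:0000031")


def _localname(elem) -> str:
    return etree.QName(elem).localname


def _decode_binary_array(bda_elem) -> tuple[str | None, np.ndarray]:
    """Decode one <binaryDataArray>: returns (array-type accession, values)."""
    dtype = "<f8"
    compressed = False
    kind = None
    b64 = ""
    for child in bda_elem.iter():
        name = _localname(child)
        if name == "cvParam":
            acc = child.get("accession")
            if acc == _CV_F32:
                dtype = "<f4"
            elif acc == _CV_F64:
                dtype = "<f8"
            elif acc == _CV_ZLIB:
                compressed = True
            elif acc in (_CV_MZ_ARRAY, _CV_INT_ARRAY):
                kind = acc
        elif name == "binary":
            b64 = child.text or ""
    raw = base64.b64decode(b64)
    if compressed and raw:
        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml_centroid(path: str | Path) -> LCMSRun:
    """Read all MS1 centroid spectra of an mzML file into an :class:`LCMSRun`.

    A deliberately small, streaming mzML reader (lxml iterparse): it
    understands centroid MS1 spectra with base64 32/64-bit float arrays,
    optionally zlib-compressed, and scan start times in seconds or minutes
    (always converted to seconds).  Profile-mode spectra are rejected
    outright: centroiding is out of scope and silently treating profile
    points as centroids corrupts every downstream trace.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    mzs: list[np.ndarray] = []
    intens: list[np.ndarray] = []
    rts: list[float] = []
    for _, spectrum in etree.iterparse(str(path), events=("end",),
                                       tag=("{*}spectrum", "spectrum")):
        ms_level = None
        profile = False
        rt_s = None
        arrays: dict[str, np.ndarray] = {}
        for child in spectrum.iter():
            name = _localname(child)
            if name == "cvParam":
                acc = child.get("accession")
                if acc == _CV_MS_LEVEL:
                    ms_level = int(child.get("value"))
                elif acc == _CV_PROFILE:
                    profile = True
                elif acc == _CV_SCAN_START:
                    value = float(child.get("value"))
                    unit = child.get("unitName") or child.get("unitAccession") or "second"
                    rt_s = value * 60.0 if unit in _UNIT_MINUTE else value
            elif name == "binaryDataArray":
                kind, values = _decode_binary_array(child)
                if kind is not None:
                    arrays[kind] = values
        if ms_level == 1:
            if profile:
                raise ProfileModeError(
                    f"{path.name}: profile-mode spectrum {spectrum.get('id')!r}; "
                    "only centroided MS1 data is supported"
                )
            if rt_s is None:
                raise LCMSIOError(f"{path.name}: spectrum {spectrum.get('id')!r} has no scan start time")
            mzs.append(arrays.get(_CV_MZ_ARRAY, np.empty(0)))
            intens.append(arrays.get(_CV_INT_ARRAY, np.empty(0)))
            rts.append(rt_s)
        spectrum.clear()
    if not rts:
        raise LCMSIOError(f"{path.name}: no MS1 spectra found")
    return LCMSRun(mzs, intens, np.array(rts))


# mzML serialization -----------------------------------------------------

_MZML_HEADER = (
    '<?xml version="1.0" encoding="utf-8"?>\n'
    '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">\n'
    '  <cvList count="2">\n'
    '    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology"'
    ' URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>\n'
    '    <cv id="UO" fullName="Unit Ontology" URI="http://obo.cvs.sourceforge.net/*checkout*/obo/obo/ontology/phenotype/unit.obo"/>\n'
    "  </cvList>\n"
)


def _encode_f64(values: np.ndarray) -> str:
    raw = struct.pack("<%dd" % len(values), *np.asarray(values, dtype=float))
    return base64.b64encode(raw).decode("ascii")


def _binary_array(values: np.ndarray, accession: str, name: str) -> str:
    b64 = _encode_f64(values)
    return (
        f'          <binaryDataArray encodedLength="{len(b64)}">\n'
        '            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>\n'
        '            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>\n'
        f'            <cvParam cvRef="MS" accession="{accession}" name="{name}" value=""/>\n'
        f"            <binary>{b64}</binary>\n"
        "          </binaryDataArray>\n"
    )


def write_mzml(run: LCMSRun, path: str | Path, run_id: str = "synthetic_run") -> None:
    """Serialize a run as minimal centroid-MS1 mzML readable by pyteomics.

    Arrays are stored as uncompressed little-endian 64-bit floats; retention
    times are written in seconds.
    """
    path = Path(path)
    parts = [_MZML_HEADER, f'  <run id="{escape(run_id)}">\n',
             f'    <spectrumList count="{run.n_scans}">\n']
    for i in range(run.n_scans):
        mz = run.mz_arrays[i]
        parts.append(
            f'      <spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{len(mz)}">\n'
            '        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>\n'
            '        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>\n'
            '        <scanList count="1">\n'
            "          <scan>\n"
            f'            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{float(run.rts[i])!r}"'
            ' unitCvRef="UO" unitAccession="UO:0000010" unitName="second"/>\n'
            "          </scan>\n"
            "        </scanList>\n"
            '        <binaryDataArrayList count="2">\n'
        )
        parts.append(_binary_array(mz, "MS:1000514", "m/z array"))
        parts.append(_binary_array(run.intensity_arrays[i], "MS:1000515", "intensity array"))
        parts.append("        </binaryDataArrayList>\n      </spectrum>\n")
    parts.append("    </spectrumList>\n  </run>\n</mzML>\n")
    Path(path).write_text("".join(parts))


# peak lists -------------------------------------------------------------


def write_peaklist(records: list[PeakRecord], path: str | Path,
                   metrics: pd.DataFrame | dict | None = None) -> None:
    """Write peak records (plus optional per-peak metric columns) as CSV.

    Rows are sorted by (eic_id, scan_apex) so output is deterministic for a
    given record set; an empty record list yields a header-only file.
    """
    frame = pd.DataFrame(
        [
            {
                "eic_id": r.eic_id,
                "mz_apex": r.mz_apex,
                "rt_apex_s": r.rt_apex,
                "scan_apex": r.scan_apex,
                "scan_left": r.scan_left,
                "scan_right": r.scan_right,
                "source": r.source,
            }
            for r in records
        ],
        columns=_PEAKLIST_COLUMNS,
    )
    if metrics is not None:
        extra = pd.DataFrame(metrics)
        if len(extra) != len(frame):
            raise LCMSIOError("metrics must have one row per record")
        frame = pd.concat([frame.reset_index(drop=True), extra.reset_index(drop=True)], axis=1)
    order = np.lexsort((frame["scan_apex"].to_numpy(), frame["eic_id"].to_numpy())) if len(frame) else []
    frame = frame.iloc[list(order)] if len(frame) else frame
    frame.to_csv(path, index=False)


def read_peaklist(path: str | Path, column_map: dict[str, str] | None = None,
                  source: str | None = None, rt_unit: str = "s") -> list[PeakRecord]:
    """Read a delimited peak list into :class:`PeakRecord` objects.

    ``column_map`` maps file headers onto canonical names (``mz_apex``,
    ``rt_apex_s``, ``scan_apex``, ``scan_left``, ``scan_right``, ``eic_id``);
    only apex m/z and RT are mandatory.  ``rt_unit`` may be ``"s"`` or
    ``"min"`` for files that report minutes.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    if column_map:
        frame = frame.rename(columns=column_map)
    for col in ("mz_apex", "rt_apex_s"):
        if col not in frame.columns:
            raise LCMSIOError(f"{path.name}: missing mandatory column {col!r}")
    if rt_unit not in ("s", "min"):
        raise LCMSIOError(f"unknown rt_unit {rt_unit!r}")
    scale = 60.0 if rt_unit == "min" else 1.0
    label = source if source is not None else path.stem
    records = []
    for _, row in frame.iterrows():
        apex = int(row["scan_apex"]) if "scan_apex" in frame.columns else 0
        left = int(row["scan_left"]) if "scan_left" in frame.columns else apex
        right = int(row["scan_right"]) if "scan_right" in frame.columns else apex
        records.append(
            PeakRecord(
                eic_id=int(row["eic_id"]) if "eic_id" in frame.columns else -1,
                mz_apex=float(row["mz_apex"]),
                rt_apex=float(row["rt_apex_s"]) * scale,
                scan_apex=apex,
                scan_left=left,
                scan_right=right,
                source=str(row["source"]) if "source" in frame.columns and not pd.isna(row["source"]) else label,
            )
        )
    return records


# EIC tables -------------------------------------------------------------


def write_eic_table(eics, path: str | Path) -> None:
    """Write extracted EICs as long-format CSV: eic_id, scan, rt_s, mz, intensity."""
    rows = []
    for eic in eics:
        for i in range(eic.N):
            rows.append(
                (eic.eic_id, eic.scan_first + i, eic.rts[i],
                 eic.mz_trace[i] if np.isfinite(eic.mz_trace[i]) else "",
                 eic.intensities[i])
            )
    frame = pd.DataFrame(rows, columns=["eic_id", "scan", "rt_s", "mz", "intensity"])
    frame.to_csv(path, index=False)


def read_eic_table(path: str | Path):
    """Read a long-format EIC table back into EIC objects."""
    from .eic_extraction import EIC  # local import to avoid a cycle

    frame = pd.read_csv(path)
    eics = []
    for eic_id, grp in frame.groupby("eic_id", sort=True):
        grp = grp.sort_values("scan")
        scans = grp["scan"].to_numpy(dtype=int)
        inten = grp["intensity"].to_numpy(dtype=float)
        mz = grp["mz"].to_numpy(dtype=float)
        weights = np.where(np.isfinite(mz), inten, 0.0)
        center = float(np.average(np.nan_to_num(mz), weights=weights)) if weights.sum() > 0 else float("nan")
        eics.append(
            EIC(
                eic_id=int(eic_id),
                mz_center=center,
                scan_first=int(scans[0]),
                scan_last=int(scans[-1]),
                intensities=inten,
                mz_trace=mz,
                rts=grp["rt_s"].to_numpy(dtype=float),
            )
        )
    return eics


# config files -----------------------------------------------------------


def load_config(path: str | Path) -> PipelineConfig:
    """Load a flat ``key = value`` config file; unknown keys are rejected."""
    known = {f.name: f for f in fields(PipelineConfig)}
    kwargs = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise LCMSIOError(f"line {lineno}: expected 'key = value'")
        key, value = (s.strip() for s in line.split("=", 1))
        if key not in known:
            raise LCMSIOError(f"line {lineno}: unknown config key {key!r}")
        typ = known[key].type
        if value.lower() == "none":
            kwargs[key] = None
        elif "int" in str(typ) and "float" not in str(typ):
            kwargs[key] = int(value)
        elif "float" in str(typ):
            kwargs[key] = float(value)
        else:
            kwargs[key] = value
    return PipelineConfig(**kwargs)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    lines = [f"{k} = {v}" for k, v in asdict(config).items()]
    Path(path).write_text("\n".join(lines) + "\n")
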