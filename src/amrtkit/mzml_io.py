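"""Minimal mzML reading and writing for MS1 scan data.

Both directions are intentionally small: the writer emits a well-formed
mzML document with uncompressed 64-bit base64 binary arrays; the reader
handles centroided MS1 spectra with 32/64-bit float arrays, with or without
zlib compression.  Enough to exchange simulated runs and small extracted
datasets — not a full-featured mzML implementation.
"""

from __future__ import annotations

import base64
import struct
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union
from xml.etree import ElementTree
from xml.sax.saxutils import escape

import numpy as np

__all__ = ["Scan", "InMemoryRun", "read_ms1_run", "write_mzml"]

_NS = "{http://psi.hupo.org/ms/mzml}"


@dataclass(frozen=True)
class Scan:
    """One centroided MS1 scan: start time (seconds) and peak arrays."""

    time_s: float
    mz: np.ndarray
    intensity: np.ndarray


@dataclass
class InMemoryRun:
    """An MS1 run held in memory; satisfies the MS1Run protocol."""

    scans: list[Scan]
    polarity: str = "positive"

    def ms1_scans(self):
        return [(s.time_s, s.mz, s.intensity) for s in self.scans]


def _decode_binary_array(array_elem) -> Optional[tuple[str, np.ndarray]]:
    """Decode one <binaryDataArray>; returns (kind, values) or None."""
    dtype = np.float64
    compressed = False
    kind = None
    for cv in array_elem.iter(f"{_NS}cvParam"):
        name = cv.get("name", "")
        if name == "32-bit float":
            dtype = np.float32
        elif name == "64-bit float":
            dtype = np.float64
        elif name == "zlib compression":
            compressed = True
        elif name == "m/z array":
            kind = "mz"
        elif name == "intensity array":
            kind = "intensity"
    binary = array_elem.find(f"{_NS}binary")
    if kind is None or binary is None or not (binary.text or "").strip():
        return (kind, np.array([], dtype=float)) if kind else None
    raw = base64.b64decode(binary.text.strip())
    if compressed:
        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype).astype(float)


def _scan_time_seconds(spectrum_elem) -> float:
    for scan in spectrum_elem.iter(f"{_NS}scan"):
        for cv in scan.iter(f"{_NS}cvParam"):
            if cv.get("name") == "scan start time":
                value = float(cv.get("value", "0"))
                unit = (cv.get("unitName") or "").lower()
                return value * 60.0 if "minute" in unit else value
    return 0.0


def read_ms1_run(path: Union[str, Path], polarity: str = "positive") -> InMemoryRun:
    """Load the MS1 scans of an mzML file into memory."""
    scans: list[Scan] = []
    for _, elem in ElementTree.iterparse(str(path)):
        if elem.tag != f"{_NS}spectrum":
            continue
        ms_level = None
        for cv in elem.findall(f"{_NS}cvParam"):
            if cv.get("name") == "ms level":
                ms_level = int(cv.get("value", "0"))
        if ms_level != 1:
            elem.clear()
            continue
        arrays = {}
        for array_elem in elem.iter(f"{_NS}binaryDataArray"):
            decoded = _decode_binary_array(array_elem)
            if decoded:
                arrays[decoded[0]] = decoded[1]
        if "mz" in arrays and "intensity" in arrays:
            scans.append(
                Scan(
                    time_s=_scan_time_seconds(elem),
                    mz=arrays["mz"],
                    intensity=arrays["intensity"],
                )
            )
        elem.clear()
    if not scans:
        raise ValueError(f"no MS1 scans found in {path}")
    scans.sort(key=lambda s: s.time_s)
    return InMemoryRun(scans=scans, polarity=polarity)


def _b64(values: np.ndarray) -> str:
    arr = np.asarray(values, dtype=float)
    packed = struct.pack(f"<{arr.size}d", *arr)
    return base64.b64encode(packed).decode("ascii")


_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="1">
    <cv id="MS" fullName="PSI-MS" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
    </fileContent>
  </fileDescription>
  <run id="{run_id}">
    <spectrumList count="{count}">
"""

_SPECTRUM = """      <spectrum index="{index}" id="scan={scan}" defaultArrayLength="{n}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
        <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
        <scanList count="1">
          <scan>
            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{time}" unitCvRef="UO" unitAccession="UO:0000010" unitName="second"/>
          </scan>
        </scanList>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{mz_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
            <binary>{mz_b64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{int_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
            <binary>{int_b64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
"""

_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def write_mzml(
    scans: Sequence[Scan], path: Union[str, Path], run_id: str = "synthetic_run"
) -> None:
    """Write MS1 scans as a minimal mzML document."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(_HEADER.format(run_id=escape(run_id), count=len(scans)))
        for i, scan in enumerate(scans):
            mz_b64 = _b64(scan.mz)
            int_b64 = _b64(scan.intensity)
            handle.write(
                _SPECTRUM.format(
                    index=i,
                    scan=i + 1,
                    n=scan.mz.size,
                    time=f"{scan.time_s:.6f}",
                    mz_len=len(mz_b64),
                    mz_b64=mz_b64,
                    int_len=len(int_b64),
                    int_b64=int_b64,
                )
            )
        handle.write(_FOOTER)
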