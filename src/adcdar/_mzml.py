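"""Minimal mzML reading and writing for single, uncompressed profile spectra.

Only the subset of mzML this package emits is supported on read: 32/64-bit
float arrays, zlib or no compression, one or more <spectrum> elements with
m/z and intensity binary arrays identified by their PSI-MS accessions.
"""

from __future__ import annotations

import base64
import struct
import zlib
from pathlib import Path
from typing import Union
from xml.etree import ElementTree as ET

import numpy as np

from .errors import SpectrumParseError

_NS = "http://psi.hupo.org/ms/mzml"

# PSI-MS controlled-vocabulary accessions.
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INTENSITY_ARRAY = "MS:1000515"
_ACC_FLOAT64 = "MS:1000523"
_ACC_FLOAT32 = "MS:1000521"
_ACC_NO_COMPRESSION = "MS:1000576"
_ACC_ZLIB = "MS:1000574"

_TEMPLATE = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="{ns}" version="1.1.0">
  <cvList count="1">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  </cvList>
  <run id="run1">
    <spectrumList count="1">
      <spectrum id="spectrum=1" index="0" defaultArrayLength="{n}">
        <cvParam cvRef="MS" accession="MS:1000128" name="profile spectrum" value=""/>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{len_mz}">
            <cvParam cvRef="MS" accession="{acc64}" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="{acc_none}" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="{acc_mz}" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
            <binary>{b64_mz}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{len_int}">
            <cvParam cvRef="MS" accession="{acc64}" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="{acc_none}" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="{acc_int}" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
            <binary>{b64_int}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
    </spectrumList>
  </run>
</mzML>
"""


def _encode(values: np.ndarray) -> str:
    raw = struct.pack("<%dd" % len(values), *np.asarray(values, dtype=float))
    return base64.b64encode(raw).decode("ascii")


def write_mzml(path: Union[str, Path], mz: np.ndarray, intensity: np.ndarray) -> None:
    """Write one profile spectrum as uncompressed 64-bit mzML."""
    b64_mz = _encode(mz)
    b64_int = _encode(intensity)
    Path(path).write_text(
        _TEMPLATE.format(
            ns=_NS,
            n=len(mz),
            len_mz=len(b64_mz),
            len_int=len(b64_int),
            acc64=_ACC_FLOAT64,
            acc_none=_ACC_NO_COMPRESSION,
            acc_mz=_ACC_MZ_ARRAY,
            acc_int=_ACC_INTENSITY_ARRAY,
            b64_mz=b64_mz,
            b64_int=b64_int,
        )
    )


def _decode_array(elem: ET.Element) -> tuple[str, np.ndarray]:
    """Decode one <binaryDataArray>; returns (kind, values)."""
    accessions = {
        cv.get("accession") for cv in elem.findall(f"{{{_NS}}}cvParam")
    }
    if _ACC_MZ_ARRAY in accessions:
        kind = "mz"
    elif _ACC_INTENSITY_ARRAY in accessions:
        kind = "intensity"
    else:
        kind = "other"
    binary = elem.find(f"{{{_NS}}}binary")
    if binary is None or binary.text is None:
        raise SpectrumParseError("binaryDataArray without <binary> payload")
    raw = base64.b64decode(binary.text)
    if _ACC_ZLIB in accessions:
        raw = zlib.decompress(raw)
    dtype = "<f4" if _ACC_FLOAT32 in accessions else "<f8"
    return kind, np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml(path: Union[str, Path]) -> tuple[np.ndarray, np.ndarray]:
    """Read the first spectrum of an mzML file as (mz, intensity)."""
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise SpectrumParseError(f"not well-formed mzML: {exc}") from exc
    spectrum = tree.getroot().find(f".//{{{_NS}}}spectrum")
    if spectrum is None:
        raise SpectrumParseError(f"no <spectrum> element in {path}")
    arrays: dict[str, np.ndarray] = {}
    for elem in spectrum.iter(f"{{{_NS}}}binaryDataArray"):
        kind, values = _decode_array(elem)
        arrays[kind] = values
    if "mz" not in arrays or "intensity" not in arrays:
        raise SpectrumParseError(f"{path} lacks m/z or intensity arrays")
    return arrays["mz"], arrays["intensity"]
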