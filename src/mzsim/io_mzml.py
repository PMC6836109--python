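"""mzML input/output.

Reading parses centroided mzML (namespace-agnostic, controlled-vocabulary
accession driven) into RT-ordered :class:`~mzsim.virtual_ms.Scan` objects
with MS levels, RTs in seconds, double-precision peak arrays and
precursor metadata for MS2 scans. Binary arrays may be 32- or 64-bit,
zlib-compressed or not; RT units of minutes are converted to seconds.

Writing produces standards-conformant centroided mzML (PSI-MS controlled
vocabulary, 64-bit zlib-compressed arrays, positive polarity by default):
enough for the round trip ``read_run(write_run(log))`` to preserve scan
counts, levels, RT order, peak arrays and precursor metadata, and for the
files to open in standard viewers.
"""

from __future__ import annotations

import base64
import struct
import zlib
from pathlib import Path
from typing import Sequence
from xml.etree import ElementTree as ET

import numpy as np

from .virtual_ms import Precursor, Scan

__all__ = ["read_run", "write_run"]

_NS = "http://psi.hupo.org/ms/mzml"
_SECOND = {
    "unitCvRef": "UO",
    "unitAccession": "UO:0000010",
    "unitName": "second",
}

# cvParam accessions
_ACC_MS_LEVEL = "MS:1000511"
_ACC_SCAN_START = "MS:1000016"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INTENSITY_ARRAY = "MS:1000515"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_NO_COMPRESSION = "MS:1000576"
_ACC_ISO_TARGET = "MS:1000827"
_ACC_ISO_LO = "MS:1000828"
_ACC_ISO_HI = "MS:1000829"
_ACC_SELECTED_MZ = "MS:1000744"
_ACC_PEAK_INTENSITY = "MS:1000042"


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _cv_params(element: ET.Element) -> dict[str, dict]:
    out = {}
    for child in element:
        if _local(child.tag) == "cvParam":
            out[child.get("accession", "")] = child.attrib
    return out


def _children(element: ET.Element, name: str) -> list[ET.Element]:
    return [c for c in element.iter() if _local(c.tag) == name]


def _decode_array(array_el: ET.Element) -> np.ndarray:
    params = _cv_params(array_el)
    binary = next((c for c in array_el if _local(c.tag) == "binary"), None)
    text = (binary.text or "") if binary is not None else ""
    raw = base64.b64decode(text)
    if _ACC_ZLIB in params:
        raw = zlib.decompress(raw)
    dtype = "<f4" if _ACC_F32 in params else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _parse_spectrum(spectrum: ET.Element):
    params = _cv_params(spectrum)
    ms_level = int(float(params[_ACC_MS_LEVEL]["value"])) if _ACC_MS_LEVEL in params else 1

    rt = None
    for scan_el in _children(spectrum, "scan"):
        scan_params = _cv_params(scan_el)
        if _ACC_SCAN_START in scan_params:
            attrs = scan_params[_ACC_SCAN_START]
            rt = float(attrs["value"])
            unit = (attrs.get("unitName") or "").lower()
            if "minute" in unit:
                rt *= 60.0
            break
    if rt is None:
        raise ValueError(
            f"spectrum {spectrum.get('id')!r} has no scan start time"
        )

    mzs = np.empty(0)
    intens = np.empty(0)
    for array_el in _children(spectrum, "binaryDataArray"):
        arr_params = _cv_params(array_el)
        if _ACC_MZ_ARRAY in arr_params:
            mzs = _decode_array(array_el)
        elif _ACC_INTENSITY_ARRAY in arr_params:
            intens = _decode_array(array_el)

    precursor = None
    prec_els = _children(spectrum, "precursor")
    if prec_els:
        prec = prec_els[0]
        window = None
        for iso in _children(prec, "isolationWindow"):
            iso_params = _cv_params(iso)
            if _ACC_ISO_TARGET in iso_params:
                target = float(iso_params[_ACC_ISO_TARGET]["value"])
                lo_off = float(iso_params.get(_ACC_ISO_LO, {}).get("value", 0.0))
                hi_off = float(iso_params.get(_ACC_ISO_HI, {}).get("value", 0.0))
                window = (target - lo_off, target + hi_off)
        sel_mz, sel_int = 0.0, 0.0
        for ion in _children(prec, "selectedIon"):
            ion_params = _cv_params(ion)
            if _ACC_SELECTED_MZ in ion_params:
                sel_mz = float(ion_params[_ACC_SELECTED_MZ]["value"])
            if _ACC_PEAK_INTENSITY in ion_params:
                sel_int = float(ion_params[_ACC_PEAK_INTENSITY]["value"])
        parent = None
        ref = prec.get("spectrumRef")
        if ref and "scan=" in ref:
            try:
                parent = int(ref.rsplit("scan=", 1)[1])
            except ValueError:
                parent = None
        precursor = Precursor(
            mz=sel_mz, intensity=sel_int, parent_scan_id=parent, isolation_window=window
        )
    return rt, ms_level, mzs, intens, precursor


def read_run(path: str | Path) -> list[Scan]:
    """Read a centroided mzML run as an RT-ordered list of scans.

    Each scan's ``duration`` is the RT gap to the next scan (the final
    scan reuses the previous gap), the only observable proxy for scan
    time in an mzML file.
    """
    records = []
    try:
        for event, element in ET.iterparse(str(path), events=("end",)):
            if _local(element.tag) == "spectrum":
                records.append(_parse_spectrum(element))
                element.clear()
    except ET.ParseError as exc:
        raise ValueError(
            f"malformed mzML file {path}: {exc} (line, column) = {exc.position}"
        ) from exc

    records.sort(key=lambda r: r[0])
    gaps = [b[0] - a[0] for a, b in zip(records, records[1:])]
    scans = []
    for i, (rt, level, mzs, intens, precursor) in enumerate(records):
        if i < len(gaps):
            duration = gaps[i]
        else:
            duration = gaps[-1] if gaps else 0.0
        scans.append(
            Scan(
                scan_id=i,
                ms_level=level,
                rt=rt,
                duration=duration,
                mzs=mzs,
                intensities=intens,
                precursor=precursor,
            )
        )
    return scans


def _cv(parent: ET.Element, accession: str, name: str, value: str = "", **extra) -> None:
    ET.SubElement(
        parent,
        "cvParam",
        {"cvRef": "MS", "accession": accession, "name": name, "value": value, **extra},
    )


def _binary_array(
    parent: ET.Element, values: np.ndarray, accession: str, name: str
) -> None:
    raw = struct.pack(f"<{values.size}d", *values.astype(float))
    encoded = base64.b64encode(zlib.compress(raw)).decode("ascii")
    arr = ET.SubElement(parent, "binaryDataArray", {"encodedLength": str(len(encoded))})
    _cv(arr, _ACC_F64, "64-bit float")
    _cv(arr, _ACC_ZLIB, "zlib compression")
    _cv(arr, accession, name)
    ET.SubElement(arr, "binary").text = encoded


def write_run(
    scan_log: Sequence[Scan], path: str | Path, polarity: str = "positive"
) -> None:
    """Write a scan log as a centroided mzML file (RT unit: seconds)."""
    scans = list(scan_log)
    if not scans:
        raise ValueError("cannot write an empty scan log")
    if polarity not in ("positive", "negative"):
        raise ValueError("polarity must be 'positive' or 'negative'")
    pol_acc, pol_name = (
        ("MS:1000130", "positive scan")
        if polarity == "positive"
        else ("MS:1000129", "negative scan")
    )

    # plain tags with a default xmlns: every element lands in the mzML
    # namespace without ElementTree prefixing
    root = ET.Element("mzML", {"xmlns": _NS, "version": "1.1.0"})
    cv_list = ET.SubElement(root, "cvList", {"count": "2"})
    ET.SubElement(
        cv_list,
        "cv",
        {
            "id": "MS",
            "fullName": "Proteomics Standards Initiative Mass Spectrometry Ontology",
            "URI": "https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo",
        },
    )
    ET.SubElement(
        cv_list,
        "cv",
        {
            "id": "UO",
            "fullName": "Unit Ontology",
            "URI": "https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo",
        },
    )
    file_desc = ET.SubElement(root, "fileDescription")
    content = ET.SubElement(file_desc, "fileContent")
    _cv(content, "MS:1000579", "MS1 spectrum")
    if any(s.ms_level == 2 for s in scans):
        _cv(content, "MS:1000580", "MSn spectrum")
    _cv(content, "MS:1000127", "centroid spectrum")

    software_list = ET.SubElement(root, "softwareList", {"count": "1"})
    software = ET.SubElement(software_list, "software", {"id": "mzsim", "version": "0"})
    _cv(software, "MS:1000799", "custom unreleased software tool", "mzsim")

    ic_list = ET.SubElement(root, "instrumentConfigurationList", {"count": "1"})
    ic = ET.SubElement(ic_list, "instrumentConfiguration", {"id": "IC1"})
    _cv(ic, "MS:1000031", "instrument model")

    dp_list = ET.SubElement(root, "dataProcessingList", {"count": "1"})
    dp = ET.SubElement(dp_list, "dataProcessing", {"id": "DP1"})
    pm = ET.SubElement(dp, "processingMethod", {"order": "1", "softwareRef": "mzsim"})
    _cv(pm, "MS:1000544", "Conversion to mzML")

    run = ET.SubElement(
        root, "run", {"id": "simulated_run", "defaultInstrumentConfigurationRef": "IC1"}
    )
    spec_list = ET.SubElement(
        run, "spectrumList", {"count": str(len(scans)), "defaultDataProcessingRef": "DP1"}
    )
    for index, scan in enumerate(scans):
        spectrum = ET.SubElement(
            spec_list,
            "spectrum",
            {
                "index": str(index),
                "id": f"scan={scan.scan_id}",
                "defaultArrayLength": str(scan.mzs.size),
            },
        )
        _cv(spectrum, _ACC_MS_LEVEL, "ms level", str(scan.ms_level))
        _cv(
            spectrum,
            "MS:1000579" if scan.ms_level == 1 else "MS:1000580",
            "MS1 spectrum" if scan.ms_level == 1 else "MSn spectrum",
        )
        _cv(spectrum, "MS:1000127", "centroid spectrum")
        _cv(spectrum, pol_acc, pol_name)
        scan_list = ET.SubElement(spectrum, "scanList", {"count": "1"})
        _cv(scan_list, "MS:1000795", "no combination")
        scan_el = ET.SubElement(scan_list, "scan")
        _cv(scan_el, _ACC_SCAN_START, "scan start time", repr(float(scan.rt)), **_SECOND)

        if scan.ms_level == 2 and scan.precursor is not None:
            p = scan.precursor
            plist = ET.SubElement(spectrum, "precursorList", {"count": "1"})
            attrs = {}
            if p.parent_scan_id is not None:
                attrs["spectrumRef"] = f"scan={p.parent_scan_id}"
            prec = ET.SubElement(plist, "precursor", attrs)
            if p.isolation_window is not None:
                lo, hi = p.isolation_window
                target = (lo + hi) / 2
                iso = ET.SubElement(prec, "isolationWindow")
                _cv(iso, _ACC_ISO_TARGET, "isolation window target m/z", repr(float(target)))
                _cv(iso, _ACC_ISO_LO, "isolation window lower offset", repr(float(target - lo)))
                _cv(iso, _ACC_ISO_HI, "isolation window upper offset", repr(float(hi - target)))
            ion_list = ET.SubElement(prec, "selectedIonList", {"count": "1"})
            ion = ET.SubElement(ion_list, "selectedIon")
            _cv(ion, _ACC_SELECTED_MZ, "selected ion m/z", repr(float(p.mz)))
            _cv(ion, _ACC_PEAK_INTENSITY, "peak intensity", repr(float(p.intensity)))
            activation = ET.SubElement(prec, "activation")
            _cv(activation, "MS:1000422", "beam-type collision-induced dissociation")

        arrays = ET.SubElement(spectrum, "binaryDataArrayList", {"count": "2"})
        _binary_array(arrays, scan.mzs, _ACC_MZ_ARRAY, "m/z array")
        _binary_array(arrays, scan.intensities, _ACC_INTENSITY_ARRAY, "intensity array")

    ET.ElementTree(root).write(path, xml_declaration=True, encoding="utf-8")
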