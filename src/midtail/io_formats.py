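"""Readers and writers for spectra, PSM tables, run designs and result tables.

Formats handled here:

* **mzML** (centroided MS2) — read through :mod:`pyteomics.mzml`; a minimal
  writer is provided so the synthetic-data generator can emit standard files
  (uncompressed, base64-encoded 64-bit float arrays).
* **peak-list TSV** — a simple block dialect: a ``#SCAN`` header line per
  scan followed by two-column ``mz<TAB>intensity`` rows.
* **PSM TSV** — our documented search-export schema with columns
  ``scan_id, base_id, mods, pep, delta_mod``; mod strings look like
  ``K9(Acetyl);K14(Acetyl)`` with 1-based H3 coordinates.  A column-mapping
  config adapts other exports.
* **run-design YAML** — TMT channel order, channel→condition map, reporter
  m/z values and the label isotopic-impurity matrix.
* **result TSVs** — proteoform and differential tables with deterministic
  column order and row sort.
"""

from __future__ import annotations

import base64
import logging
import re
import struct
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from lxml import etree

from .mass_model import (
    H3_SEQUENCES,
    ModificationDelta,
    Proteoform,
    ProteoformError,
    default_modification_registry,
    modification_delta,
)

logger = logging.getLogger("midtail")

__all__ = [
    "Spectrum",
    "PSMRecord",
    "RunDesign",
    "SpectrumFormatError",
    "read_spectra",
    "write_spectra_mzml",
    "write_spectra_tsv",
    "parse_mod_string",
    "format_mod_string",
    "read_psm_table",
    "write_psm_table",
    "default_run_design",
    "write_results",
]


class SpectrumFormatError(ValueError):
    """Raised for malformed or unsupported spectrum files."""


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------


@dataclass
class Spectrum:
    """One centroided MS2 scan: precursor, peak list, scan id.

    Peaks are kept as parallel arrays sorted ascending by m/z.
    """

    scan_id: str
    precursor_mz: float
    precursor_charge: int
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise SpectrumFormatError(f"scan {self.scan_id}: mz/intensity length mismatch")
        if np.any(self.intensity < 0):
            raise SpectrumFormatError(f"scan {self.scan_id}: negative intensity")
        if self.precursor_charge < 1:
            raise SpectrumFormatError(f"scan {self.scan_id}: precursor charge < 1")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)


def read_spectra(path, fmt: str | None = None) -> list[Spectrum]:
    """Read centroided MS2 spectra from mzML or the peak-list TSV dialect.

    ``fmt`` is ``"mzml"`` or ``"tsv"``; inferred from the file extension when
    omitted.  Profile-mode mzML scans raise with an instruction to centroid.
    """
    path = Path(path)
    if fmt is None:
        fmt = "mzml" if path.suffix.lower() == ".mzml" else "tsv"
    if fmt == "mzml":
        return _read_mzml(path)
    if fmt == "tsv":
        return _read_peaklist_tsv(path)
    raise ValueError(f"unknown spectrum format {fmt!r}")


# cvParam accessions used by the mzML reader
_ACC_MS_LEVEL = "MS:1000511"
_ACC_CENTROID = "MS:1000127"
_ACC_PROFILE = "MS:1000128"
_ACC_SELECTED_MZ = "MS:1000744"
_ACC_CHARGE = "MS:1000041"
_ACC_FLOAT64 = "MS:1000523"
_ACC_FLOAT32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INTENSITY_ARRAY = "MS:1000515"


def _cv_accessions(elem) -> dict[str, str]:
    """accession -> value for every cvParam below ``elem``."""
    return {
        cv.get("accession"): cv.get("value", "")
        for cv in elem.iter("{*}cvParam")
    }


def _decode_binary_array(bda) -> tuple[str | None, np.ndarray]:
    acc = _cv_accessions(bda)
    node = bda.find("{*}binary")
    raw = base64.b64decode(node.text or "") if node is not None else b""
    if _ACC_ZLIB in acc:
        raw = zlib.decompress(raw)
    dtype = "<f4" if _ACC_FLOAT32 in acc else "<f8"
    values = np.frombuffer(raw, dtype=dtype).astype(float)
    if _ACC_MZ_ARRAY in acc:
        return "mz", values
    if _ACC_INTENSITY_ARRAY in acc:
        return "intensity", values
    return None, values


def _read_mzml(path: Path) -> list[Spectrum]:
    """Parse centroided MS2 scans from mzML (plain or indexed, zlib or raw).

    Implemented directly on lxml; handles the subset of mzML 1.1.0 the
    pipeline needs (64/32-bit float peak arrays, precursor charge and m/z).
    """
    spectra: list[Spectrum] = []
    for _, elem in etree.iterparse(str(path), events=("end",), tag="{*}spectrum"):
        scan_id = elem.get("id", "")
        acc = {
            cv.get("accession"): cv.get("value", "")
            for cv in elem.findall("{*}cvParam")
        }
        if acc.get(_ACC_MS_LEVEL) != "2":
            elem.clear()
            continue
        if _ACC_PROFILE in acc:
            raise SpectrumFormatError(
                f"scan {scan_id}: profile-mode data; centroid the file first"
            )
        ion = elem.find("{*}precursorList/{*}precursor/{*}selectedIonList/{*}selectedIon")
        if ion is None:
            raise SpectrumFormatError(f"scan {scan_id}: missing precursor info")
        ion_acc = _cv_accessions(ion)
        if _ACC_SELECTED_MZ not in ion_acc:
            raise SpectrumFormatError(f"scan {scan_id}: missing selected ion m/z")
        pmz = float(ion_acc[_ACC_SELECTED_MZ])
        pcharge = int(ion_acc.get(_ACC_CHARGE, "1"))
        arrays: dict[str, np.ndarray] = {}
        for bda in elem.iter("{*}binaryDataArray"):
            kind, values = _decode_binary_array(bda)
            if kind is not None:
                arrays[kind] = values
        mz = arrays.get("mz", np.empty(0))
        inten = arrays.get("intensity", np.empty(0))
        if mz.size == 0:
            logger.info("scan %s: empty peak list", scan_id)
        try:
            spectra.append(Spectrum(scan_id, pmz, pcharge, mz, inten))
        except SpectrumFormatError:
            raise
        except Exception as exc:
            raise SpectrumFormatError(f"scan {scan_id}: {exc}") from exc
        elem.clear()
    return spectra


_SCAN_HEADER = re.compile(
    r"^#SCAN\tid=(?P<id>\S+)\tprecursor_mz=(?P<mz>\S+)\tprecursor_charge=(?P<z>\d+)\s*$"
)


def _read_peaklist_tsv(path: Path) -> list[Spectrum]:
    spectra: list[Spectrum] = []
    current: dict | None = None

    def flush() -> None:
        if current is not None:
            mzs = np.array(current["mz"], dtype=float)
            if mzs.size == 0:
                logger.info("scan %s: empty peak list", current["id"])
            spectra.append(
                Spectrum(current["id"], current["pmz"], current["pz"],
                         mzs, np.array(current["inten"], dtype=float))
            )

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#SCAN"):
                m = _SCAN_HEADER.match(line)
                if not m:
                    raise SpectrumFormatError(f"{path}:{lineno}: malformed scan header")
                flush()
                current = {
                    "id": m.group("id"),
                    "pmz": float(m.group("mz")),
                    "pz": int(m.group("z")),
                    "mz": [],
                    "inten": [],
                }
            else:
                if current is None:
                    raise SpectrumFormatError(f"{path}:{lineno}: peak row before any #SCAN header")
                fields = line.split("\t")
                if len(fields) != 2:
                    raise SpectrumFormatError(
                        f"{path}:{lineno} (scan {current['id']}): expected 2 columns"
                    )
                current["mz"].append(float(fields[0]))
                current["inten"].append(float(fields[1]))
    flush()
    return spectra


def write_spectra_tsv(spectra: Iterable[Spectrum], path) -> None:
    with open(path, "w") as fh:
        for s in spectra:
            fh.write(
                f"#SCAN\tid={s.scan_id}\tprecursor_mz={s.precursor_mz:.6f}"
                f"\tprecursor_charge={s.precursor_charge}\n"
            )
            for mz, inten in zip(s.mz, s.intensity):
                fh.write(f"{mz:.6f}\t{inten:.4f}\n")


def _b64_doubles(values: np.ndarray) -> str:
    raw = struct.pack(f"<{values.size}d", *values.astype(float))
    return base64.b64encode(raw).decode("ascii")


_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="Unit Ontology" URI="http://ontologies.berkeleybop.org/uo.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000580" name="MSn spectrum" value=""/>
      <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
    </fileContent>
  </fileDescription>
  <run id="run">
    <spectrumList count="{count}">
"""

_MZML_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def write_spectra_mzml(spectra: Sequence[Spectrum], path) -> None:
    """Write centroided MS2 spectra as minimal mzML 1.1.0.

    Uncompressed little-endian 64-bit float arrays; readable by any
    mzML-aware tool (round-trips through :mod:`pyteomics.mzml`).
    """
    with open(path, "w") as fh:
        fh.write(_MZML_HEADER.format(count=len(spectra)))
        for idx, s in enumerate(spectra):
            mz_b64 = _b64_doubles(s.mz)
            inten_b64 = _b64_doubles(s.intensity)
            fh.write(
                f'      <spectrum index="{idx}" id="{s.scan_id}" defaultArrayLength="{s.n_peaks}">\n'
                '        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="2"/>\n'
                '        <cvParam cvRef="MS" accession="MS:1000580" name="MSn spectrum" value=""/>\n'
                '        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>\n'
                '        <precursorList count="1">\n'
                "          <precursor>\n"
                '            <selectedIonList count="1">\n'
                "              <selectedIon>\n"
                f'                <cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="{s.precursor_mz:.6f}" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>\n'
                f'                <cvParam cvRef="MS" accession="MS:1000041" name="charge state" value="{s.precursor_charge}"/>\n'
                "              </selectedIon>\n"
                "            </selectedIonList>\n"
                "          </precursor>\n"
                "        </precursorList>\n"
                '        <binaryDataArrayList count="2">\n'
                f'          <binaryDataArray encodedLength="{len(mz_b64)}">\n'
                '            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>\n'
                '            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>\n'
                '            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>\n'
                f"            <binary>{mz_b64}</binary>\n"
                "          </binaryDataArray>\n"
                f'          <binaryDataArray encodedLength="{len(inten_b64)}">\n'
                '            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>\n'
                '            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>\n'
                '            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>\n'
                f"            <binary>{inten_b64}</binary>\n"
                "          </binaryDataArray>\n"
                "        </binaryDataArrayList>\n"
                "      </spectrum>\n"
            )
        fh.write(_MZML_FOOTER)


# ---------------------------------------------------------------------------
# PSM tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PSMRecord:
    """One peptide-spectrum match from a search-engine export."""

    scan_id: str
    proteoform: Proteoform
    pep: float
    delta_mod: float
    n_psms_on_scan: int = 1


_MOD_TOKEN = re.compile(r"^([A-Z])(\d+)\(([^)]+)\)$")


def parse_mod_string(
    mods: str,
    sequence: str,
    registry: Mapping[str, ModificationDelta] | None = None,
) -> tuple[tuple[int, str], ...]:
    """Parse ``"K9(Acetyl);K14(Acetyl)"`` into positioned mods.

    Each token's residue letter must match the sequence at that 1-based
    position and the modification's target set.
    """
    registry = registry if registry is not None else default_modification_registry()
    mods = mods.strip()
    if not mods or mods.lower() in ("none", "unmodified", "-"):
        return ()
    out = []
    for token in mods.split(";"):
        token = token.strip()
        m = _MOD_TOKEN.match(token)
        if not m:
            raise ProteoformError(f"unparseable mod token {token!r}")
        res, pos, name = m.group(1), int(m.group(2)), m.group(3)
        if not 1 <= pos <= len(sequence):
            raise ProteoformError(f"mod position {pos} outside sequence")
        if sequence[pos - 1] != res:
            raise ProteoformError(
                f"mod token {token!r}: sequence has {sequence[pos - 1]!r} at position {pos}"
            )
        mod = modification_delta(name, registry)
        if res not in mod.targets:
            raise ProteoformError(f"{name} does not target residue {res!r}")
        out.append((pos, name))
    return tuple(out)


def format_mod_string(p: Proteoform) -> str:
    return ";".join(f"{p.sequence[pos - 1]}{pos}({name})" for pos, name in p.mods)


#: Default column names of the PSM TSV schema.
PSM_COLUMNS = {
    "scan_id": "scan_id",
    "base_id": "base_id",
    "mods": "mods",
    "pep": "pep",
    "delta_mod": "delta_mod",
}


def read_psm_table(
    path,
    registry: Mapping[str, ModificationDelta] | None = None,
    column_map: Mapping[str, str] | None = None,
) -> tuple[list[PSMRecord], list[tuple[int, str]]]:
    """Read a PSM TSV into records, parsing mod strings into proteoforms.

    Returns ``(accepted, rejected)`` where ``rejected`` holds
    ``(row_number, reason)`` for rows that failed validation; accepted +
    rejected always account for every input row.  ``n_psms_on_scan`` is
    computed by grouping accepted rows on scan id.
    """
    registry = registry if registry is not None else default_modification_registry()
    cols = dict(PSM_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype={cols["scan_id"]: str})
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise ValueError(f"PSM table missing required columns: {missing}")

    accepted: list[PSMRecord] = []
    rejected: list[tuple[int, str]] = []
    for i, row in df.iterrows():
        try:
            base_id = str(row[cols["base_id"]])
            if base_id not in H3_SEQUENCES:
                raise ProteoformError(f"unknown base sequence id {base_id!r}")
            seq = H3_SEQUENCES[base_id]
            mods = parse_mod_string(str(row[cols["mods"]]) if pd.notna(row[cols["mods"]]) else "",
                                    seq, registry)
            p = Proteoform(base_id=base_id, mods=mods)
            p.validate(registry)
            pep = float(row[cols["pep"]])
            if not 0.0 <= pep <= 1.0:
                raise ProteoformError(f"PEP {pep} outside [0, 1]")
            delta = float(row[cols["delta_mod"]])
            if delta < 0:
                raise ProteoformError(f"negative delta-mod score {delta}")
            accepted.append(
                PSMRecord(scan_id=str(row[cols["scan_id"]]), proteoform=p, pep=pep, delta_mod=delta)
            )
        except (ProteoformError, ValueError) as exc:
            rejected.append((int(i), str(exc)))
    if rejected:
        logger.warning("PSM table: rejected %d of %d rows", len(rejected), len(df))

    counts: dict[str, int] = {}
    for r in accepted:
        counts[r.scan_id] = counts.get(r.scan_id, 0) + 1
    accepted = [
        PSMRecord(r.scan_id, r.proteoform, r.pep, r.delta_mod, counts[r.scan_id])
        for r in accepted
    ]
    return accepted, rejected


def write_psm_table(records: Iterable[PSMRecord], path) -> None:
    rows = [
        {
            "scan_id": r.scan_id,
            "base_id": r.proteoform.base_id,
            "mods": format_mod_string(r.proteoform),
            "pep": r.pep,
            "delta_mod": r.delta_mod,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=["scan_id", "base_id", "mods", "pep", "delta_mod"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Run design
# ---------------------------------------------------------------------------

#: Standard TMT 6-plex reporter ion m/z values (singly charged).
TMT6_REPORTER_MZ = {
    "126": 126.127726,
    "127": 127.124761,
    "128": 128.134436,
    "129": 129.131471,
    "130": 130.141145,
    "131": 131.138180,
}


@dataclass
class RunDesign:
    """TMT channel layout: order, condition map, reporter m/z, impurity matrix.

    ``impurity_matrix`` column j gives the isotopic distribution of label j
    across the observed channels; the identity matrix means no bleed-through.
    """

    channels: list[str]
    channel_condition: dict[str, str]
    reporter_mz: dict[str, float]
    impurity_matrix: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.impurity_matrix is None:
            self.impurity_matrix = np.eye(len(self.channels))
        self.impurity_matrix = np.asarray(self.impurity_matrix, dtype=float)
        k = len(self.channels)
        if self.impurity_matrix.shape != (k, k):
            raise ValueError("impurity matrix must be square over the channels")
        if np.any(self.impurity_matrix < 0):
            raise ValueError("impurity matrix entries must be non-negative")
        if np.any(self.impurity_matrix.sum(axis=0) > 1 + 1e-9):
            raise ValueError("impurity matrix columns must sum to <= 1")
        for ch in self.channels:
            if ch not in self.channel_condition or ch not in self.reporter_mz:
                raise ValueError(f"channel {ch} missing condition or reporter m/z")

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for ch in self.channels:
            cond = self.channel_condition[ch]
            if cond not in seen:
                seen.append(cond)
        return seen

    def condition_channels(self, condition: str) -> list[str]:
        return [ch for ch in self.channels if self.channel_condition[ch] == condition]

    def to_yaml(self, path) -> None:
        data = {
            "channels": list(self.channels),
            "channel_condition": dict(self.channel_condition),
            "reporter_mz": {k: float(v) for k, v in self.reporter_mz.items()},
            "impurity_matrix": self.impurity_matrix.tolist(),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunDesign":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        try:
            return cls(
                channels=[str(c) for c in data["channels"]],
                channel_condition={str(k): v for k, v in data["channel_condition"].items()},
                reporter_mz={str(k): float(v) for k, v in data["reporter_mz"].items()},
                impurity_matrix=np.asarray(data["impurity_matrix"], dtype=float)
                if "impurity_matrix" in data
                else None,
            )
        except (KeyError, ValueError) as exc:
            raise ValueError(f"bad run-design file {path}: {exc}") from exc


def default_run_design(
    vehicle: str = "vehicle", treated: str = "treated"
) -> RunDesign:
    """The 6-plex layout used throughout: 126-128 vehicle, 129-131 treated."""
    channels = list(TMT6_REPORTER_MZ)
    cond = {ch: (vehicle if ch in ("126", "127", "128") else treated) for ch in channels}
    return RunDesign(channels=channels, channel_condition=cond, reporter_mz=dict(TMT6_REPORTER_MZ))


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------


def write_results(quant, diff, out_dir) -> tuple[Path, Path]:
    """Write the proteoform and differential TSVs with deterministic layout.

    Rows sort by abundance descending, ties broken by id; float formatting is
    fixed so identical inputs give byte-identical files.
    """
    from .quantify import ProteoformQuant  # local import to avoid cycle
    from .diff_stats import DifferentialResult

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    qrows = []
    for q in quant:
        row = {
            "proteoform": q.proteoform_id,
            "abundance": q.abundance,
            "attributed_intensity": q.attributed_intensity,
            "n_scans": q.n_scans,
        }
        for ch in sorted(q.channel_log2):
            vals = q.channel_log2[ch]
            row[f"log2_{ch}"] = np.mean(vals) if len(vals) else np.nan
        qrows.append(row)
    qdf = pd.DataFrame(qrows)
    if not qdf.empty:
        qdf = qdf.sort_values(
            ["abundance", "proteoform"], ascending=[False, True], kind="stable"
        )
    else:
        qdf = pd.DataFrame(
            columns=["proteoform", "abundance", "attributed_intensity", "n_scans"]
        )
    qpath = out_dir / "proteoforms.tsv"
    qdf.to_csv(qpath, sep="\t", index=False, float_format="%.6g")

    drows = [
        {
            "proteoform": d.proteoform_id,
            "log2fc": d.log2fc,
            "p_value": d.p_value,
            "q_value": d.q_value,
            "n_reference": d.n_reference,
            "n_treatment": d.n_treatment,
            "significant": d.significant,
        }
        for d in diff
    ]
    ddf = pd.DataFrame(
        drows,
        columns=["proteoform", "log2fc", "p_value", "q_value",
                 "n_reference", "n_treatment", "significant"],
    )
    if not ddf.empty:
        ddf = ddf.sort_values(["p_value", "proteoform"], kind="stable")
    dpath = out_dir / "differential.tsv"
    ddf.to_csv(dpath, sep="\t", index=False, float_format="%.6g")
    return qpath, dpath
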