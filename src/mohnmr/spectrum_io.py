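"""Read and write 1D NMR data as JCAMP-DX.

Reading handles AFFN and the compressed ASDF encodings (SQZ/DIF/DUP) used by
TopSpin exports, both plain ``##XYDATA`` blocks and ``##NTUPLES`` real/
imaginary page tables; compound (link) files are flattened and the first
data-carrying block is returned.  Writing always emits AFFN.

Time-domain blocks come back as :class:`~mohnmr.model.FidRecord`, processed
real spectra as :class:`~mohnmr.model.Spectrum1D`.
"""

from __future__ import annotations

import csv
import logging
import os
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import yaml

from . import _jcamp
from ._jcamp import JcampParseError, normalize_label
from .model import FidRecord, SamplePrep, Spectrum1D

__all__ = [
    "JcampParseError",
    "MetadataError",
    "UnsupportedBlockError",
    "read_jcamp",
    "write_jcamp",
    "write_fid_jcamp",
    "load_prep_sidecar",
]

log = logging.getLogger(__name__)


class MetadataError(ValueError):
    """A required metadata label (e.g. observe frequency) is missing."""


class UnsupportedBlockError(ValueError):
    """The block's data layout is not supported (e.g. imaginary-only)."""


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------


def _first_float(labels: dict, *names: str) -> Optional[float]:
    for name in names:
        if name in labels:
            try:
                return float(labels[name].split()[0].replace(",", "."))
            except (ValueError, IndexError):
                continue
    return None


def _block_labels(block) -> dict:
    return {label: value for label, value, _ in block}


def _decode_table(lines: List[str], yfactor: float) -> np.ndarray:
    return _jcamp.decode_asdf_lines(lines) * yfactor


def _parse_ntuples(block) -> Dict[str, Tuple[dict, np.ndarray]]:
    """Collect NTUPLES pages keyed by ordinate symbol (``R``, ``I``, ``Y``)."""
    symbols: List[str] = []
    attrs: Dict[str, List[str]] = {}
    pages: Dict[str, Tuple[dict, np.ndarray]] = {}
    for label, value, lines in block:
        if label == "SYMBOL":
            symbols = [s.strip() for s in value.split(",")]
        elif label in ("VARNAME", "VARTYPE", "VARFORM", "VARDIM", "UNITS",
                       "FIRST", "LAST", "FACTOR", "MIN", "MAX"):
            attrs[label] = [s.strip() for s in value.split(",")]
        elif label == "DATATABLE":
            # value like "(X++(R..R)), XYDATA"
            sym = None
            inner = value[value.find("(") + 1 : value.rfind(")")]
            for cand in ("R", "I", "Y"):
                if f"({cand}.." in inner or f"({cand})" in inner:
                    sym = cand
                    break
            if sym is None:
                raise JcampParseError(f"cannot identify ordinate in {value!r}")
            col = symbols.index(sym) if sym in symbols else None
            yfac = 1.0
            if col is not None and "FACTOR" in attrs:
                try:
                    yfac = float(attrs["FACTOR"][col])
                except (IndexError, ValueError):
                    pass
            meta = {}
            if col is not None:
                for key in ("FIRST", "LAST", "VARDIM"):
                    if key in attrs:
                        try:
                            meta[key] = float(attrs[key][col])
                        except (IndexError, ValueError):
                            pass
            # abscissa metadata lives in column of symbol X
            if "X" in symbols:
                xcol = symbols.index("X")
                for key in ("FIRST", "LAST", "VARDIM", "FACTOR"):
                    if key in attrs:
                        try:
                            meta["X" + key] = float(attrs[key][xcol])
                        except (IndexError, ValueError):
                            pass
            pages[sym] = (meta, _decode_table(lines, yfac))
    return pages


def _read_block(block, path: str) -> Union[FidRecord, Spectrum1D]:
    labels = _block_labels(block)
    datatype = labels.get("DATATYPE", "").upper()
    is_fid = "FID" in datatype or "TIME" in labels.get("XUNITS", "").upper()

    freq = _first_float(labels, ".OBSERVEFREQUENCY", "$SFO1", "$SF", "$BF1")
    if freq is None:
        raise MetadataError(
            f"{path}: no observe frequency label "
            "(##.OBSERVE FREQUENCY / ##$SFO1) in block "
            f"{labels.get('TITLE', '?')!r}"
        )
    scans = _first_float(labels, "$NS", ".AVERAGES")
    rg = _first_float(labels, "$RG", ".RECEIVERGAIN")
    if scans is None or rg is None:
        log.warning(
            "%s: scans/receiver gain missing, defaulting to 1; PULCON assumes "
            "constant acquisition parameters across the series", path
        )
    scans = int(scans) if scans is not None else 1
    rg = rg if rg is not None else 1.0
    series_id = labels.get("$SERIESID", "")
    sample_id = labels.get("$SAMPLEID", labels.get("TITLE", ""))

    prep = None
    mass = _first_float(labels, "$SAMPLEMASSMG")
    vol = _first_float(labels, "$SOLUTIONVOLUMEML")
    if mass is not None and vol is not None:
        prep = SamplePrep(sample_mass=mass, solution_volume=vol)

    has_xydata = any(label == "XYDATA" for label, _, _ in block)
    has_ntuples = any(label == "NTUPLES" for label, _, _ in block)

    if has_ntuples:
        pages = _parse_ntuples(block)
        if is_fid:
            if "R" not in pages:
                raise UnsupportedBlockError(f"{path}: FID block lacks a real page")
            meta, real = pages["R"]
            imag = pages["I"][1] if "I" in pages else np.zeros_like(real)
            n = len(real)
            if "XLAST" in meta and "XFIRST" in meta and n > 1:
                xfac = meta.get("XFACTOR", 1.0)
                dwell = (meta["XLAST"] - meta["XFIRST"]) * xfac / (n - 1)
            else:
                dwell = _first_float(labels, "$DW") or 0.0
            if dwell <= 0:
                raise MetadataError(f"{path}: cannot determine FID dwell time")
            return FidRecord(real + 1j * imag, dwell, freq, scans, rg,
                             series_id, sample_id)
        # processed spectrum pages
        if "R" not in pages and "Y" not in pages:
            raise UnsupportedBlockError(
                f"{path}: spectrum block has no real ordinate page "
                "(imaginary-only data is not supported)"
            )
        meta, real = pages.get("R", pages.get("Y"))
        n = len(real)
        xfac = meta.get("XFACTOR", 1.0)
        firstx, lastx = meta["XFIRST"] * xfac, meta["XLAST"] * xfac
        axis = np.linspace(firstx, lastx, n)
        xunits = labels.get("UNITS", labels.get("XUNITS", "")).upper()
        if "HZ" in xunits:
            axis = axis / freq
        return _make_spectrum(axis, real, freq, scans, rg, prep,
                              series_id, sample_id, path)

    if not has_xydata:
        raise UnsupportedBlockError(f"{path}: block carries no XYDATA/NTUPLES")

    firstx = _first_float(labels, "FIRSTX")
    lastx = _first_float(labels, "LASTX")
    npoints = _first_float(labels, "NPOINTS")
    if firstx is None or lastx is None or npoints is None:
        raise MetadataError(f"{path}: FIRSTX/LASTX/NPOINTS required for XYDATA")
    xfactor = _first_float(labels, "XFACTOR") or 1.0
    yfactor = _first_float(labels, "YFACTOR") or 1.0
    lines = next(ln for label, _, ln in block if label == "XYDATA")
    y = _decode_table(lines, yfactor)
    if len(y) != int(npoints):
        raise JcampParseError(
            f"{path}: decoded {len(y)} points, header says {int(npoints)}"
        )
    axis = np.linspace(firstx * xfactor, lastx * xfactor, int(npoints))
    if is_fid:
        dwell = abs(axis[1] - axis[0]) if len(axis) > 1 else 0.0
        if dwell <= 0:
            raise MetadataError(f"{path}: cannot determine FID dwell time")
        return FidRecord(y.astype(complex), dwell, freq, scans, rg,
                         series_id, sample_id)
    xunits = labels.get("XUNITS", "").upper()
    if "HZ" in xunits:
        axis = axis / freq
    return _make_spectrum(axis, y, freq, scans, rg, prep,
                          series_id, sample_id, path)


def _make_spectrum(axis, y, freq, scans, rg, prep, series_id, sample_id,
                   path) -> Spectrum1D:
    if axis[0] < axis[-1]:  # store descending, NMR display convention
        axis, y = axis[::-1].copy(), y[::-1].copy()
    spec = Spectrum1D(
        ppm_axis=axis, intensity=y, spectrometer_freq=freq, scans=scans,
        receiver_gain=rg, prep=prep, series_id=series_id, sample_id=sample_id,
    )
    spec.log(f"read_jcamp:{os.path.basename(path)}")
    return spec


def read_jcamp(path: str) -> Union[FidRecord, Spectrum1D]:
    """Read a JCAMP-DX file; return a :class:`FidRecord` for time-domain
    blocks or a :class:`Spectrum1D` for processed real spectra.

    Compound files are flattened; the first data-carrying block wins.
    """
    with open(path, "r", errors="replace") as fh:
        text = fh.read()
    records = _jcamp.split_records(text)
    blocks = _jcamp.split_blocks(records)
    if not blocks:
        raise JcampParseError(f"{path}: no JCAMP blocks found")
    last_err: Optional[Exception] = None
    for block in blocks:
        if not any(label in ("XYDATA", "DATATABLE") for label, _, _ in block):
            continue
        try:
            return _read_block(block, path)
        except UnsupportedBlockError as exc:
            last_err = exc
    if last_err is not None:
        raise last_err
    raise UnsupportedBlockError(f"{path}: no data-carrying block found")


# ---------------------------------------------------------------------------
# writing (AFFN only)
# ---------------------------------------------------------------------------


def _common_header(title: str, datatype: str, freq: float, scans: int,
                   rg: float, series_id: str, sample_id: str) -> List[str]:
    return [
        f"##TITLE={title}",
        "##JCAMP-DX=5.01",
        f"##DATA TYPE={datatype}",
        "##ORIGIN=mohnmr",
        "##OWNER=",
        "##.OBSERVE NUCLEUS=^1H",
        f"##.OBSERVE FREQUENCY={freq:.8G}",
        f"##$NS={scans}",
        f"##$RG={rg:.8G}",
        f"##$SERIESID={series_id}",
        f"##$SAMPLEID={sample_id}",
    ]


def write_jcamp(spec: Spectrum1D, path: str) -> None:
    """Write a processed real spectrum as an AFFN ``##XYDATA`` block."""
    if not isinstance(spec, Spectrum1D):
        raise TypeError("write_jcamp expects a Spectrum1D")
    if spec.intensity.size == 0:
        raise ValueError("refusing to write an empty spectrum")
    axis, y = spec.ppm_axis, spec.intensity
    lines = _common_header(spec.sample_id or "spectrum", "NMR SPECTRUM",
                           spec.spectrometer_freq, spec.scans,
                           spec.receiver_gain, spec.series_id, spec.sample_id)
    lines += [
        "##DATA CLASS=XYDATA",
        "##XUNITS=PPM",
        "##YUNITS=ARBITRARY UNITS",
        "##XFACTOR=1.0",
        "##YFACTOR=1.0",
        f"##FIRSTX={axis[0]:.12G}",
        f"##LASTX={axis[-1]:.12G}",
        f"##NPOINTS={axis.size}",
        f"##FIRSTY={y[0]:.10G}",
        f"##MAXY={y.max():.10G}",
        f"##MINY={y.min():.10G}",
    ]
    if spec.prep is not None:
        lines.append(f"##$SAMPLEMASSMG={spec.prep.sample_mass:.8G}")
        lines.append(f"##$SOLUTIONVOLUMEML={spec.prep.solution_volume:.8G}")
    lines.append("##XYDATA=(X++(Y..Y))")
    lines += _jcamp.format_affn_xydata(axis, y)
    lines.append("##END=")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_fid_jcamp(fid: FidRecord, path: str) -> None:
    """Write a complex FID as an AFFN ``##NTUPLES`` block (real + imag pages)."""
    n = fid.points.size
    t = np.arange(n) * fid.dwell_time
    lines = _common_header(fid.sample_id or "fid", "NMR FID",
                           fid.spectrometer_freq, fid.scans,
                           fid.receiver_gain, fid.series_id, fid.sample_id)
    lines += [
        "##DATA CLASS=NTUPLES",
        "##NTUPLES=NMR FID",
        "##VAR_NAME=TIME, FID/REAL, FID/IMAG",
        "##SYMBOL=X, R, I",
        "##VAR_TYPE=INDEPENDENT, DEPENDENT, DEPENDENT",
        "##VAR_FORM=AFFN, AFFN, AFFN",
        f"##VAR_DIM={n}, {n}, {n}",
        "##UNITS=SECONDS, ARBITRARY UNITS, ARBITRARY UNITS",
        f"##FIRST=0, {fid.points.real[0]:.10G}, {fid.points.imag[0]:.10G}",
        f"##LAST={t[-1]:.12G}, {fid.points.real[-1]:.10G}, {fid.points.imag[-1]:.10G}",
        "##FACTOR=1.0, 1.0, 1.0",
        "##PAGE=N=1",
        "##DATA TABLE=(X++(R..R)), XYDATA",
    ]
    lines += _jcamp.format_affn_xydata(t, fid.points.real)
    lines.append("##PAGE=N=2")
    lines.append("##DATA TABLE=(X++(I..I)), XYDATA")
    lines += _jcamp.format_affn_xydata(t, fid.points.imag)
    lines.append("##END=")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# sidecar sample-prep metadata
# ---------------------------------------------------------------------------


def load_prep_sidecar(path: str) -> Dict[str, SamplePrep]:
    """Load per-sample preparation metadata from a YAML or CSV sidecar.

    YAML layout: ``{sample_id: {sample_mass_mg: .., solution_volume_ml: ..}}``.
    CSV columns: ``sample_id, sample_mass_mg, solution_volume_ml``.
    """
    preps: Dict[str, SamplePrep] = {}
    if path.endswith((".yaml", ".yml")):
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        for sid, entry in doc.items():
            preps[str(sid)] = SamplePrep(
                sample_mass=float(entry["sample_mass_mg"]),
                solution_volume=float(entry["solution_volume_ml"]),
            )
    else:
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                preps[str(row["sample_id"])] = SamplePrep(
                    sample_mass=float(row["sample_mass_mg"]),
                    solution_volume=float(row["solution_volume_ml"]),
                )
    return preps
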