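"""Photon-stream containers and I/O.

The universal input of the package is a time-tagged photon record per molecule:
a *macrotime* (seconds since the start of the trace) and a *microtime*
(nanoseconds since the preceding excitation pulse, the TCSPC nanotime),
together with instrument metadata (excitation repetition period, microtime
resolution, IRF width).

Two on-disk dialects are supported:

* an HDF5 container (one group per molecule, file-level metadata attributes) —
  the default for anything large;
* a plain CSV table with a ``# key = value`` header comment block — convenient
  for small fixtures and interoperable with spreadsheet tools.

Vendor TTTR formats (PTU/SPC/HT3) are deliberately not parsed; convert first.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "InstrumentMeta",
    "PhotonStream",
    "ValidationReport",
    "validate_stream",
    "read_photon_streams",
    "write_photon_streams",
]

#: Columns of the documented photon-table schema.
TABLE_COLUMNS = ("molecule_id", "macrotime_s", "microtime_ns")

#: Metadata keys of the documented schema.
META_KEYS = ("excitation_period_ns", "microtime_resolution_ns", "irf_fwhm_ns", "label")


@dataclass(frozen=True)
class InstrumentMeta:
    """Acquisition metadata shared by all photons of a stream.

    Parameters
    ----------
    excitation_period_ns
        Pulse-to-pulse period of the excitation laser in ns (12.5 ns for the
        common 80 MHz repetition rate).
    microtime_resolution_ns
        TCSPC bin width in ns.
    irf_fwhm_ns
        Full width at half maximum of the instrument response function in ns.
    excitation_wavelength_nm
        Optional excitation wavelength.
    label
        Free-text sample/condition label.
    """

    excitation_period_ns: float = 12.5
    microtime_resolution_ns: float = 0.016
    irf_fwhm_ns: float = 0.38
    excitation_wavelength_nm: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if not self.excitation_period_ns > 0:
            raise ValueError("excitation_period_ns must be > 0")
        if not (0 < self.microtime_resolution_ns < self.excitation_period_ns):
            raise ValueError(
                "microtime_resolution_ns must lie in (0, excitation_period_ns)"
            )
        if self.irf_fwhm_ns < 0:
            raise ValueError("irf_fwhm_ns must be >= 0")


@dataclass
class PhotonStream:
    """One molecule's time-tagged photon records.

    ``macrotimes`` are seconds since trace start and must be non-decreasing;
    ``microtimes`` are nanoseconds since the excitation pulse and must lie in
    ``[0, meta.excitation_period_ns)``.
    """

    molecule_id: str
    macrotimes: np.ndarray
    microtimes: np.ndarray
    meta: InstrumentMeta = field(default_factory=InstrumentMeta)

    def __post_init__(self) -> None:
        self.macrotimes = np.asarray(self.macrotimes, dtype=np.float64)
        self.microtimes = np.asarray(self.microtimes, dtype=np.float64)

    @property
    def n_photons(self) -> int:
        return int(self.macrotimes.size)

    @property
    def duration_s(self) -> float:
        """Span of the trace; 0 for streams with fewer than 2 photons."""
        if self.n_photons < 2:
            return 0.0
        return float(self.macrotimes[-1] - self.macrotimes[0])

    def validate(self) -> "ValidationReport":
        return validate_stream(self)

    def require_valid(self) -> "PhotonStream":
        report = validate_stream(self)
        if not report.ok:
            raise ValueError(
                f"invalid photon stream {self.molecule_id!r}: "
                + "; ".join(report.messages)
            )
        return self


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of :func:`validate_stream`: an ok flag plus messages."""

    ok: bool
    messages: tuple[str, ...] = ()


def validate_stream(stream: PhotonStream) -> ValidationReport:
    """Check every stream invariant; never raises on malformed content.

    A zero-photon stream is valid.
    """
    msgs: list[str] = []
    mac, mic = stream.macrotimes, stream.microtimes
    if mac.ndim != 1 or mic.ndim != 1:
        msgs.append("macrotimes/microtimes must be 1-D")
        return ValidationReport(False, tuple(msgs))
    if mac.size != mic.size:
        msgs.append(
            f"length mismatch: {mac.size} macrotimes vs {mic.size} microtimes"
        )
    if mac.size and not np.all(np.isfinite(mac)):
        msgs.append("non-finite macrotimes")
    if mic.size and not np.all(np.isfinite(mic)):
        msgs.append("non-finite microtimes")
    if mac.size > 1 and np.any(np.diff(mac) < 0):
        msgs.append(f"unsorted macrotimes (molecule {stream.molecule_id!r})")
    period = stream.meta.excitation_period_ns
    if mic.size and (np.any(mic < 0) or np.any(mic >= period)):
        msgs.append(
            f"microtime out of range [0, {period}) ns (molecule "
            f"{stream.molecule_id!r})"
        )
    return ValidationReport(not msgs, tuple(msgs))


# ---------------------------------------------------------------------------
# container I/O
# ---------------------------------------------------------------------------


def _meta_to_dict(meta: InstrumentMeta) -> dict:
    d = {
        "excitation_period_ns": meta.excitation_period_ns,
        "microtime_resolution_ns": meta.microtime_resolution_ns,
        "irf_fwhm_ns": meta.irf_fwhm_ns,
        "label": meta.label,
    }
    if meta.excitation_wavelength_nm is not None:
        d["excitation_wavelength_nm"] = meta.excitation_wavelength_nm
    return d


def _meta_from_dict(d: dict) -> InstrumentMeta:
    return InstrumentMeta(
        excitation_period_ns=float(d["excitation_period_ns"]),
        microtime_resolution_ns=float(d["microtime_resolution_ns"]),
        irf_fwhm_ns=float(d["irf_fwhm_ns"]),
        excitation_wavelength_nm=(
            float(d["excitation_wavelength_nm"])
            if d.get("excitation_wavelength_nm") is not None
            else None
        ),
        label=str(d.get("label", "")),
    )


def _infer_format(path: str | os.PathLike, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("container", "table"):
            raise ValueError(f"unknown format {fmt!r}; use 'container' or 'table'")
        return fmt
    ext = os.path.splitext(str(path))[1].lower()
    if ext in (".h5", ".hdf5", ".hdf"):
        return "container"
    if ext in (".csv", ".txt", ".tsv"):
        return "table"
    raise ValueError(f"cannot infer format from extension {ext!r}; pass format=")


def write_photon_streams(
    streams: Sequence[PhotonStream],
    path: str | os.PathLike,
    format: str | None = None,
) -> None:
    """Write streams to an HDF5 container or a CSV table.

    Round-trips bit-exactly with :func:`read_photon_streams` (times are stored
    as 64-bit floats). An empty sequence yields a valid file with zero photon
    rows; per-stream metadata is preserved.
    """
    fmt = _infer_format(path, format)
    for s in streams:
        s.require_valid()
    if fmt == "container":
        _write_h5(streams, path)
    else:
        _write_table(streams, path)


def _write_h5(streams: Sequence[PhotonStream], path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["photonflc_schema"] = 1
        f.require_group("molecules")
        for i, s in enumerate(streams):
            g = f.create_group(f"molecules/{i:06d}")
            g.attrs["molecule_id"] = s.molecule_id
            for k, v in _meta_to_dict(s.meta).items():
                g.attrs[k] = v
            g.create_dataset("macrotime_s", data=s.macrotimes, dtype="f8")
            g.create_dataset("microtime_ns", data=s.microtimes, dtype="f8")


def _read_h5(path) -> list[PhotonStream]:
    out: list[PhotonStream] = []
    with h5py.File(path, "r") as f:
        mols = f.get("molecules")
        if mols is None:
            raise ValueError(f"{path}: not a photonflc container (no 'molecules')")
        for key in sorted(mols):
            g = mols[key]
            attrs = dict(g.attrs)
            missing = [k for k in META_KEYS[:3] if k not in attrs]
            if missing:
                raise ValueError(f"{path}: missing metadata keys {missing}")
            meta = _meta_from_dict(attrs)
            s = PhotonStream(
                molecule_id=str(attrs["molecule_id"]),
                macrotimes=g["macrotime_s"][()],
                microtimes=g["microtime_ns"][()],
                meta=meta,
            )
            out.append(s)
    return out


def _write_table(streams: Sequence[PhotonStream], path) -> None:
    # A single metadata block is written per distinct label; the common case
    # (one condition per file) keeps the header short.
    with open(path, "w") as fh:
        metas: dict[str, dict] = {}
        for s in streams:
            metas.setdefault(s.molecule_id, _meta_to_dict(s.meta))
        if streams:
            shared = _meta_to_dict(streams[0].meta)
            for k, v in shared.items():
                if k == "label":
                    continue
                fh.write(f"# {k} = {v!r}\n")
            for s in streams:
                fh.write(f"# label[{s.molecule_id}] = {s.meta.label!r}\n")
        fh.write(",".join(TABLE_COLUMNS) + "\n")
        for s in streams:
            for mac, mic in zip(s.macrotimes, s.microtimes):
                fh.write(f"{s.molecule_id},{float(mac)!r},{float(mic)!r}\n")


def _read_table(path) -> list[PhotonStream]:
    header: dict[str, object] = {}
    labels: dict[str, str] = {}
    n_comment = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_comment += 1
            body = line[1:].strip()
            if "=" not in body:
                continue
            key, _, val = body.partition("=")
            key, val = key.strip(), val.strip()
            try:
                parsed = eval(val, {"__builtins__": {}})  # repr'd scalars only
            except Exception:
                parsed = val
            if key.startswith("label[") and key.endswith("]"):
                labels[key[6:-1]] = str(parsed)
            else:
                header[key] = parsed
    df = pd.read_csv(
        path,
        skiprows=n_comment,
        dtype={"molecule_id": str},
        float_precision="round_trip",
    )
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    for k in META_KEYS[:3]:
        if k not in header:
            raise ValueError(f"{path}: missing metadata key {k!r} in header block")
    base_meta = _meta_from_dict(header)
    out: list[PhotonStream] = []
    # preserve first-appearance order of molecules
    for mol_id in dict.fromkeys(df["molecule_id"]):
        sub = df[df["molecule_id"] == mol_id]
        meta = (
            replace(base_meta, label=labels[mol_id]) if mol_id in labels else base_meta
        )
        out.append(
            PhotonStream(
                molecule_id=str(mol_id),
                macrotimes=sub["macrotime_s"].to_numpy(np.float64),
                microtimes=sub["microtime_ns"].to_numpy(np.float64),
                meta=meta,
            )
        )
    return out


def read_photon_streams(
    path: str | os.PathLike, format: str | None = None
) -> list[PhotonStream]:
    """Read photon streams, one per distinct molecule_id, in file order.

    Raises ``FileNotFoundError`` for a missing path, ``ValueError`` for schema
    violations (missing column/metadata key) and for streams that fail
    validation (unsorted macrotimes, microtime outside the excitation period).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(str(path))
    fmt = _infer_format(path, format)
    streams = _read_h5(path) if fmt == "container" else _read_table(path)
    for s in streams:
        report = validate_stream(s)
        if not report.ok:
            raise ValueError(f"{path}: " + "; ".join(report.messages))
    return streams
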