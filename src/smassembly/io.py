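"""Plain-text trace, manifest and results IO plus run configuration.

All formats are tab-separated text, one row per frame/record:

* TPM traces: columns ``time_s, x_nm, y_nm, valid``;
* FRET traces: columns ``time_s, donor, acceptor``;
* cohort manifest: columns ``trace_path, modality, protein_label, ssdna_nt,
  group_id, window_s`` (paths relative to the manifest file);
* results: a TSV table preceded by ``#`` header comments recording the
  package version, config hash and seed, so every output can be regenerated.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .traces import BeadTrace, FretTrace

TPM_COLUMNS = ["time_s", "x_nm", "y_nm", "valid"]
FRET_COLUMNS = ["time_s", "donor", "acceptor"]
MANIFEST_COLUMNS = [
    "trace_path", "modality", "protein_label", "ssdna_nt", "group_id", "window_s",
]


class TraceParseError(ValueError):
    pass


def _read_table(path, required, what):
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:  # noqa: BLE001 — report file context
        raise TraceParseError(f"{path}: cannot parse {what}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TraceParseError(f"{path}: missing column(s) {', '.join(missing)}")
    for col in required:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad) and col != "valid":
            # +2: header line plus 1-based numbering
            raise TraceParseError(
                f"{path}: malformed value in column '{col}' at line {bad[0] + 2}"
            )
    return df


def _check_monotone(path, time):
    dt = np.diff(time)
    if np.any(dt <= 0):
        line = int(np.argmax(dt <= 0)) + 3  # header + 1-based + offset row
        raise TraceParseError(f"{path}: non-monotone time at line {line}")


def read_trace(path, modality):
    """Read one trace file; ``modality`` is ``'tpm'`` or ``'fret'``.

    Validates the column schema and the uniform, strictly increasing time
    grid (tolerance 1e-6 s); malformed rows are reported with line numbers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if modality == "tpm":
        df = _read_table(path, TPM_COLUMNS, "TPM trace")
        _check_monotone(path, df["time_s"].to_numpy(float))
        return BeadTrace(
            time=df["time_s"].to_numpy(float),
            x=df["x_nm"].to_numpy(float),
            y=df["y_nm"].to_numpy(float),
            valid=df["valid"].to_numpy().astype(bool),
            trace_id=path.stem,
        )
    if modality == "fret":
        df = _read_table(path, FRET_COLUMNS, "FRET trace")
        _check_monotone(path, df["time_s"].to_numpy(float))
        return FretTrace(
            time=df["time_s"].to_numpy(float),
            donor=df["donor"].to_numpy(float),
            acceptor=df["acceptor"].to_numpy(float),
            trace_id=path.stem,
        )
    raise ValueError(f"unknown modality: {modality!r}")


def write_trace(trace, path):
    """Write a trace as TSV (schema chosen from the trace type)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(trace, BeadTrace):
        df = pd.DataFrame({
            "time_s": trace.time, "x_nm": trace.x, "y_nm": trace.y,
            "valid": trace.valid.astype(int),
        })
    elif isinstance(trace, FretTrace):
        df = pd.DataFrame({
            "time_s": trace.time, "donor": trace.donor, "acceptor": trace.acceptor,
        })
    else:
        raise TypeError(f"cannot write trace of type {type(trace).__name__}")
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def read_manifest(path):
    """Read a cohort manifest; trace paths are resolved relative to it."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise TraceParseError(f"{path}: missing column(s) {', '.join(missing)}")
    df["trace_path"] = [str((path.parent / p).resolve()) for p in df["trace_path"]]
    return df


def write_manifest(records, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(records, columns=MANIFEST_COLUMNS).to_csv(path, sep="\t", index=False)
    return path


@dataclass
class RunConfig:
    """All analysis tunables with their defaults, plus provenance fields.

    Hash-stable: any change to a tunable changes :meth:`config_hash`.
    """

    # TPM analysis
    bm_window: int = 20
    rise_k: float = 3.0
    plateau_frac: float = 0.9
    min_run: int = 5
    # HMM / idealization
    hmm_tol: float = 1e-6
    hmm_max_iter: int = 500
    sigma_floor: float = 1e-3
    min_separation: float = 0.2
    bound_threshold: float = 0.45
    min_dwell_frames: int = 2
    # cohort statistics
    window_s: float = 200.0
    n_boot: int = 1000
    # provenance
    seed: int = 0
    out_dir: str = "."

    def to_dict(self):
        return asdict(self)

    def config_hash(self):
        payload = {k: v for k, v in self.to_dict().items()
                   if k not in ("seed", "out_dir")}
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
        return Path(path)


def write_results(rows, path, config: RunConfig = None, seed=None):
    """Write a results table as TSV with a provenance header.

    ``rows``: list of dicts (or objects with ``as_dict``).  An empty list
    yields a header-only file.
    """
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    dicts = [r.as_dict() if hasattr(r, "as_dict") else dict(r) for r in rows]
    df = pd.DataFrame(dicts)
    buf = _io.StringIO()
    buf.write(f"# smassembly {__version__}\n")
    if config is not None:
        buf.write(f"# config_hash={config.config_hash()}\n")
    if seed is not None or (config is not None):
        buf.write(f"# seed={seed if seed is not None else config.seed}\n")
    if not df.empty:
        df.to_csv(buf, sep="\t", index=False, float_format="%.12g")
    path.write_text(buf.getvalue())
    return path


def read_results(path):
    try:
        return pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame()
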