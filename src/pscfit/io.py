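"""File readers/writers: trace files, parameter configs, fit records.

Trace files are delimited text with a mandatory header ``time_ms,value``
(comma- or whitespace-separated).  An optional JSON sidecar ``<stem>.json``
next to the trace file may carry ``stim_time_ms``, ``holding_mV`` and
``units``.

Parameter configs are flat key-value text (``key = value`` or
``key: value`` lines, ``#`` comments) or JSON objects, with the keys
tau_rise/tau_decay (bi-exponential) or tau_r/tau_f/tau_s/i_f/i_s
(tri-exponential) plus gbar, t0, e_rev, mg_a, mg_b, mg_conc.
"""

from __future__ import annotations

import json
import re
from dataclasses import asdict
from pathlib import Path
from typing import Dict, Optional, Union

import numpy as np
import pandas as pd

from .errors import TraceFormatError
from .kinetics import BiExpKinetics, MgBlockParams, SynapseModel, TriExpKinetics
from .trace import SampledTrace

__all__ = [
    "read_trace",
    "write_trace",
    "load_params",
    "parse_params",
    "build_synapse_model",
    "write_fit_record",
]

_HEADER_RE = re.compile(r"^\s*time_ms[\s,;\t]+value\s*$", re.IGNORECASE)

TRIEXP_KEYS = {"tau_r", "tau_f", "tau_s", "i_f", "i_s"}
BIEXP_KEYS = {"tau_rise", "tau_decay"}


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json") if path.suffix != ".json" \
        else path


def read_trace(path: Union[str, Path]) -> SampledTrace:
    """Parse a two-column trace file; merge sidecar metadata if present."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not _HEADER_RE.match(header.replace(",", " ")):
            raise TraceFormatError(
                f"{path}: missing or malformed header; expected columns "
                f"'time_ms,value', got {header.strip()!r}"
            )
        times, values = [], []
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = re.split(r"[\s,;\t]+", line)
            if len(parts) != 2:
                raise TraceFormatError(
                    f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            try:
                times.append(float(parts[0]))
                values.append(float(parts[1]))
            except ValueError as exc:
                raise TraceFormatError(
                    f"{path}:{lineno}: non-numeric row {line!r}") from exc
    meta: Dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists() and sidecar != path:
        meta = json.loads(sidecar.read_text())
    return SampledTrace(
        np.asarray(times), np.asarray(values),
        units_label=meta.get("units", "pA"),
        stim_time=meta.get("stim_time_ms"),
    )


def write_trace(trace: SampledTrace, path: Union[str, Path],
                meta: Optional[Dict] = None) -> None:
    """Write the two-column format plus a JSON sidecar with metadata."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("time_ms,value\n")
        for t, v in zip(trace.times, trace.values):
            fh.write(f"{t:.17g},{v:.17g}\n")
    sidecar = {"units": trace.units_label, "stim_time_ms": trace.stim_time}
    if meta:
        sidecar.update(meta)
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def parse_params(text: str) -> Dict[str, float]:
    """Parse flat key-value parameter text (or a JSON object)."""
    text = text.strip()
    if text.startswith("{"):
        return {k: float(v) for k, v in json.loads(text).items()}
    out: Dict[str, float] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        m = re.match(r"^(\w+)\s*[:=]\s*(\S+)$", line)
        if not m:
            raise TraceFormatError(f"line {lineno}: expected 'key = value', "
                                   f"got {line!r}")
        out[m.group(1)] = float(m.group(2))
    return out


def load_params(path: Union[str, Path]) -> Dict[str, float]:
    return parse_params(Path(path).read_text())


def build_synapse_model(params: Dict[str, float]) -> SynapseModel:
    """Assemble a SynapseModel from a flat parameter dict.

    Tri-exponential if tau_r/tau_f/tau_s present, else bi-exponential.
    Mg-block keys (mg_a, mg_b, mg_conc) make it NMDA-type.
    """
    common = {"gbar": params.get("gbar", 1.0), "t0": params.get("t0", 0.0)}
    if TRIEXP_KEYS & params.keys():
        missing = TRIEXP_KEYS - params.keys()
        if missing:
            raise TraceFormatError(f"incomplete tri-exponential parameters; "
                                   f"missing {sorted(missing)}")
        kin = TriExpKinetics(params["tau_r"], params["tau_f"], params["tau_s"],
                             params["i_f"], params["i_s"], **common)
    elif BIEXP_KEYS <= params.keys():
        kin = BiExpKinetics(params["tau_rise"], params["tau_decay"], **common)
    else:
        raise TraceFormatError(
            "parameters must define tau_r/tau_f/tau_s/i_f/i_s or "
            "tau_rise/tau_decay")
    mg = None
    if any(k in params for k in ("mg_a", "mg_b", "mg_conc")):
        mg = MgBlockParams(params.get("mg_a", MgBlockParams.a),
                           params.get("mg_b", MgBlockParams.b),
                           params.get("mg_conc", MgBlockParams.mg_conc))
    return SynapseModel(kin, e_rev=params.get("e_rev", 0.0), mg=mg)


def write_fit_record(record: Dict, path: Union[str, Path]) -> None:
    """Serialize a fit result (params, window, rmse, provenance) as JSON."""

    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "__dataclass_fields__"):
            return asdict(o)
        if isinstance(o, pd.Series):
            return o.to_dict()
        raise TypeError(f"not serializable: {type(o)}")

    Path(path).write_text(json.dumps(record, indent=1, default=default))
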