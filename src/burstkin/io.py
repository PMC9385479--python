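"""Readers and writers for the package's plain-text dialects.

Units are encoded in column names (``time_min``, ``product_nM``, ``conc_nM``,
``rate_per_min``); no unit inference is performed.  Progress-curve CSVs carry
metadata as ``# key: value`` header comments, with replicate columns named
``product_nM_2``, ``product_nM_3``, …  Fit results are serialized as JSON
carrying the seed and a config hash so deterministic reruns are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .fitting import ProgressCurve, TitrationSeries


class ParseError(ValueError):
    """Malformed input file; message includes the offending line."""


_META_KEYS = {"e_nominal_nM": float, "s_total_nM": float}


def _parse_header(lines: list[str], path) -> tuple[dict, int]:
    meta: dict = {}
    i = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            break
        body = line.lstrip("#").strip()
        if ":" in body:
            key, _, val = body.partition(":")
            key, val = key.strip(), val.strip()
            conv = _META_KEYS.get(key)
            try:
                meta[key] = conv(val) if conv else val
            except ValueError as exc:
                raise ParseError(f"{path}:{i + 1}: bad metadata value {val!r}") from exc
    return meta, i


def read_progress_csv(path, average_replicates: bool = True) -> ProgressCurve:
    """Read a progress-curve CSV (header ``time_min,product_nM[,product_nM_2…]``).

    Metadata comes from ``# key: value`` comments or a ``<stem>.meta.json``
    sidecar (sidecar wins).  Replicate columns are averaged into ``product``
    and retained in ``replicate_products``.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    meta, start = _parse_header(lines, path)

    sidecar = path.with_suffix(".meta.json")
    if sidecar.exists():
        meta.update(json.loads(sidecar.read_text()))

    header = [h.strip() for h in lines[start].split(",")]
    if not header or header[0] != "time_min" or len(header) < 2 or not header[1].startswith("product_nM"):
        raise ParseError(f"{path}:{start + 1}: expected header 'time_min,product_nM…', got {lines[start]!r}")

    times, rows = [], []
    for ln_no, line in enumerate(lines[start + 1:], start=start + 2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != len(header):
            raise ParseError(f"{path}:{ln_no}: expected {len(header)} fields, got {len(parts)}")
        try:
            vals = [float(p) for p in parts]
        except ValueError as exc:
            raise ParseError(f"{path}:{ln_no}: non-numeric value in {line!r}") from exc
        times.append(vals[0])
        rows.append(vals[1:])

    times = np.asarray(times)
    rows = np.asarray(rows)
    bad = np.nonzero(np.diff(times) <= 0)[0]
    if len(bad):
        raise ParseError(f"{path}:{start + 2 + bad[0] + 1}: times out of order at t={times[bad[0] + 1]}")
    if np.any(rows < 0):
        i, j = np.argwhere(rows < 0)[0]
        raise ParseError(f"{path}:{start + 2 + i}: negative product in column {header[1 + j]!r}")

    reps = rows.T
    product = reps.mean(axis=0) if average_replicates else reps[0]
    return ProgressCurve(
        times=times,
        product=product,
        e_nominal=float(meta.get("e_nominal_nM", 0.0)),
        s_total=float(meta.get("s_total_nM", np.inf)),
        condition={k: v for k, v in meta.items() if k not in _META_KEYS},
        replicate_products=reps if reps.shape[0] > 1 else None,
    )


def write_progress_csv(path, curve: ProgressCurve, float_fmt: str = "%.17g") -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# e_nominal_nM: {curve.e_nominal}\n")
        if np.isfinite(curve.s_total):
            fh.write(f"# s_total_nM: {curve.s_total}\n")
        for k, v in curve.condition.items():
            fh.write(f"# {k}: {v}\n")
        if curve.replicate_products is not None:
            n_rep = curve.replicate_products.shape[0]
            cols = ["product_nM"] + [f"product_nM_{i + 1}" for i in range(1, n_rep)]
            fh.write("time_min," + ",".join(cols) + "\n")
            for t, row in zip(curve.times, curve.replicate_products.T):
                fh.write(",".join([float_fmt % t] + [float_fmt % v for v in row]) + "\n")
        else:
            fh.write("time_min,product_nM\n")
            for t, p in zip(curve.times, curve.product):
                fh.write(f"{float_fmt % t},{float_fmt % p}\n")


def read_titration_csv(path) -> TitrationSeries:
    """Read a titration CSV with header ``conc_nM,rate_per_min``."""
    path = Path(path)
    lines = path.read_text().splitlines()
    meta, start = _parse_header(lines, path)
    header = [h.strip() for h in lines[start].split(",")]
    if header[:2] != ["conc_nM", "rate_per_min"]:
        raise ParseError(f"{path}:{start + 1}: expected header 'conc_nM,rate_per_min'")
    concs, rates = [], []
    for ln_no, line in enumerate(lines[start + 1:], start=start + 2):
        if not line.strip():
            continue
        try:
            c, r = (float(p) for p in line.split(",")[:2])
        except ValueError as exc:
            raise ParseError(f"{path}:{ln_no}: non-numeric value in {line!r}") from exc
        concs.append(c)
        rates.append(r)
    return TitrationSeries(np.asarray(concs), np.asarray(rates), labels=meta)


def write_titration_csv(path, series: TitrationSeries, float_fmt: str = "%.17g") -> None:
    with Path(path).open("w") as fh:
        for k, v in series.labels.items():
            fh.write(f"# {k}: {v}\n")
        fh.write("conc_nM,rate_per_min\n")
        for c, r in zip(series.concs, series.k_burst_obs):
            fh.write(f"{float_fmt % c},{float_fmt % r}\n")


def read_fasta(path) -> dict[str, str]:
    """Read single- or multi-record FASTA into {id: sequence}."""
    records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable config."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_result_json(path, payload: dict, config: dict | None = None, seed=None) -> None:
    """Write a result record with provenance (config hash, seed)."""
    out = dict(payload)
    out["_provenance"] = {
        "config_hash": config_hash(config or {}),
        "seed": seed,
    }
    Path(path).write_text(json.dumps(out, indent=2, sort_keys=True, default=_jsonify) + "\n")


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
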