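"""Plain-text I/O: two-column curves, 2D intensity maps, YAML manifests."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml


def write_curve(path, x, y, yerr=None, header: dict | None = None) -> None:
    """Write a two/three-column ASCII curve with '#'-prefixed metadata."""
    cols = [np.asarray(x, float), np.asarray(y, float)]
    if yerr is not None:
        cols.append(np.asarray(yerr, float))
    lines = [f"# {k}: {v}" for k, v in (header or {}).items()]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))
        np.savetxt(fh, np.column_stack(cols))


def read_curve(path) -> tuple[np.ndarray, dict]:
    """Read an ASCII curve; returns (columns array, metadata dict)."""
    meta = {}
    with open(path) as fh:
        rows = []
        for line in fh:
            if line.startswith("#"):
                if ":" in line:
                    k, _, v = line[1:].partition(":")
                    meta[k.strip()] = v.strip()
                continue
            if line.strip():
                rows.append([float(t) for t in line.split()])
    return np.asarray(rows), meta


def write_map(path, q_xy, q_z, intensity, header: dict | None = None) -> None:
    """Write a 2D map as a plain-text grid; q axes stored in the header."""
    meta = dict(header or {})
    meta["q_xy"] = " ".join(f"{v:.6g}" for v in np.asarray(q_xy, float))
    meta["q_z"] = " ".join(f"{v:.6g}" for v in np.asarray(q_z, float))
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        np.savetxt(fh, np.asarray(intensity, float))


def read_map(path) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """Read a 2D map written by :func:`write_map`."""
    data, meta = read_curve(path)
    q_xy = np.array([float(t) for t in meta.pop("q_xy").split()])
    q_z = np.array([float(t) for t in meta.pop("q_z").split()])
    return q_xy, q_z, data, meta


def write_manifest(path, manifest: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def read_manifest(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
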