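"""File formats and run manifests.

Formats are deliberately simple and lossless at double precision:

* pattern file — plain text: ``#pattern_id``, ``#n_units``, ``#frequency_hz``
  header lines, then one phase (radians) per line;
* weight matrix — NumPy binary ``.npy`` plus a JSON sidecar recording N,
  dtype and provenance (and an optional gzipped ``i<TAB>j<TAB>J`` export);
* spike train — TSV with columns ``time_ms``, ``unit``, ``source`` and an
  optional JSON metadata sidecar;
* manifest — JSON snapshot of the configuration, seeds, package version and
  SHA-256 checksums of every output file, written only on completion.
"""

from __future__ import annotations

import gzip
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import SOURCE_CODES, SOURCE_NAMES, SpikeTrain
from .patterns import TWO_PI, PhasePattern
from .plasticity import SynapticMatrix

FORMAT_VERSION = 1


# -- patterns ---------------------------------------------------------------

def write_pattern(path, pattern: PhasePattern) -> Path:
    path = Path(path)
    lines = [
        f"#pattern_id {pattern.pattern_id}",
        f"#n_units {pattern.n_units}",
        f"#frequency_hz {pattern.frequency_hz!r}",
    ]
    lines += [f"{float(phi)!r}" for phi in pattern.phases]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_pattern(path) -> PhasePattern:
    path = Path(path)
    header: dict[str, str] = {}
    phases: list[float] = []
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            try:
                key, value = line[1:].split(None, 1)
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: malformed header line {raw!r}") from exc
            header[key] = value
        else:
            phases.append(float(line))
    for key in ("pattern_id", "n_units", "frequency_hz"):
        if key not in header:
            raise ValueError(f"{path}: missing header line #{key}")
    arr = np.asarray(phases, dtype=float)
    if np.any((arr < 0) | (arr >= TWO_PI)):
        bad = arr[(arr < 0) | (arr >= TWO_PI)][0]
        raise ValueError(f"{path}: phase {bad!r} outside [0, 2*pi)")
    return PhasePattern(
        pattern_id=int(header["pattern_id"]),
        n_units=int(header["n_units"]),
        phases=arr,
        frequency_hz=float(header["frequency_hz"]),
    )


# -- weight matrices --------------------------------------------------------

def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_weights(path, J: SynapticMatrix) -> Path:
    """Write ``<path>.npy`` plus a JSON sidecar with shape/dtype/provenance."""
    path = Path(path)
    if path.suffix != ".npy":
        path = path.with_suffix(".npy")
    np.save(path, J.weights)
    meta = {
        "format_version": FORMAT_VERSION,
        "n_units": J.n_units,
        "dtype": str(J.weights.dtype),
        "provenance": J.provenance,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_weights(path) -> SynapticMatrix:
    path = Path(path)
    if path.suffix != ".npy":
        path = path.with_suffix(".npy")
    weights = np.load(path)
    sidecar = _sidecar(path)
    provenance: dict = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if meta.get("format_version", 0) != FORMAT_VERSION:
            import warnings

            warnings.warn(
                f"{sidecar}: schema version {meta.get('format_version')} "
                f"differs from current {FORMAT_VERSION}"
            )
        if meta.get("n_units") != weights.shape[0]:
            raise ValueError(f"{sidecar}: n_units does not match array shape")
        provenance = meta.get("provenance", {})
    return SynapticMatrix(
        n_units=weights.shape[0], weights=weights, provenance=provenance
    )


def export_weights_tsv(path, J: SynapticMatrix) -> Path:
    """Gzipped TSV ``i<TAB>j<TAB>J_ij`` of the nonzero entries."""
    path = Path(path)
    ii, jj = np.nonzero(J.weights)
    with gzip.open(path, "wt") as fh:
        fh.write("i\tj\tweight\n")
        for i, j in zip(ii, jj):
            fh.write(f"{i}\t{j}\t{float(J.weights[i, j])!r}\n")
    return path


# -- spike trains -----------------------------------------------------------

def write_spike_train(path, train: SpikeTrain, metadata: dict | None = None) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_ms": train.times,
            "unit": train.units,
            "source": [SOURCE_NAMES[s] for s in train.sources],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    meta = {
        "format_version": FORMAT_VERSION,
        "n_units": train.n_units,
        "duration": train.duration,
    }
    if metadata:
        meta.update(metadata)
    _sidecar(path).write_text(json.dumps(meta, indent=1, default=str))
    return path


def read_spike_train(path, n_units: int | None = None, duration: float | None = None) -> SpikeTrain:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    for col in ("time_ms", "unit", "source"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    sidecar = _sidecar(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        n_units = n_units or meta.get("n_units")
        duration = duration or meta.get("duration")
    if n_units is None:
        n_units = int(df["unit"].max()) + 1 if len(df) else 1
    if duration is None:
        duration = float(df["time_ms"].max()) if len(df) else 0.0
    try:
        sources = np.array([SOURCE_CODES[s] for s in df["source"]], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"{path}: unknown source tag {exc}") from exc
    return SpikeTrain(
        times=df["time_ms"].to_numpy(dtype=float),
        units=df["unit"].to_numpy(dtype=np.int64),
        sources=sources,
        n_units=int(n_units),
        duration=float(duration),
    )


# -- manifests --------------------------------------------------------------

def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, config: dict, seeds: dict, files: list) -> Path:
    """JSON manifest sufficient to re-run the experiment bit-identically."""
    from . import __version__

    out_dir = Path(out_dir)
    manifest = {
        "format_version": FORMAT_VERSION,
        "package_version": __version__,
        "config": config,
        "seeds": seeds,
        "outputs": {
            str(Path(f).name): _checksum(Path(f)) for f in files
        },
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, default=str))
    return path
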